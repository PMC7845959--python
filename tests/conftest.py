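import numpy as np
import pytest

from top2track.core_io import Genome, GenomicInterval, IntervalSet
from top2track.synthetic_world import SimulationConfig, simulate_world


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced world for fast unit tests (2 chromosomes, 100 sites)."""
    return SimulationConfig(n_chroms=2, chrom_length=150_000, n_sites=100)


@pytest.fixture(scope="session")
def small_world(small_config):
    return simulate_world(small_config)


@pytest.fixture(scope="session")
def fixture_config() -> SimulationConfig:
    """The liver-like fixture world at its default study conditions."""
    return SimulationConfig()


@pytest.fixture(scope="session")
def fixture_world(fixture_config):
    return simulate_world(fixture_config)


@pytest.fixture()
def toy_genome() -> Genome:
    rng = np.random.default_rng(99)
    bases = np.array(list("ACGT"))
    seqs = {
        "chr1": "".join(rng.choice(bases, size=5000)),
        "chr2": "".join(rng.choice(bases, size=3000)),
    }
    return Genome(seqs)


def brute_force_overlaps(intervals, query: GenomicInterval):
    """O(n) oracle for IntervalSet overlap queries."""
    return [iv for iv in intervals if iv.overlaps(query)]
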