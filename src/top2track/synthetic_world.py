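"""Synthetic genome, binding sites, read libraries and methylation.

Generates a fully specified toy world whose statistical structure mimics the
chromatin landscape around TOP2B binding sites: accessibility (DNase) and
architectural-factor (CTCF, RAD21) intervals colocalize with sites at high
frequency and appear only sparsely in the background; read pileups are
Poisson with a fold enrichment over background inside feature sites; sites
have elevated G+C and hypomethylated CpGs.  Every generator is deterministic
given the configuration seed, so the whole downstream pipeline is testable
offline against known ground truth.

The background G+C level varies between large blocks (isochore-like
heterogeneity), which both resembles mammalian genomes and provides the GC
diversity required for GC-matched background sampling.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from .core_io import (
    Genome,
    GenomicInterval,
    IntervalSet,
    MethylationTable,
    ReadLibrary,
    write_bed,
    write_fasta,
    write_methylation,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genome",
    "place_sites",
    "simulate_reads",
    "simulate_methylation",
    "simulate_world",
    "write_world",
    "simulate_selection_matrix",
]

# Stage offsets: each generator derives its own stream from (seed, offset)
# so stages are independently reproducible.
_SEED_SITES = 1
_SEED_GENOME = 2
_SEED_FEATURES = 3
_SEED_READS = 4
_SEED_METH = 5


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic world.

    Defaults are the "liver-like" fixture: colocalization probabilities of
    (0.89, 0.11) for DNase at sites vs background as reported for mouse
    liver, (0.85, 0.05) for the architectural factors, and an 8-fold read
    enrichment over a Poisson background.
    """

    n_chroms: int = 4
    chrom_length: int = 500_000
    n_sites: int = 400
    site_width: int = 300
    coloc_probs: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {
            "dnase": (0.89, 0.11),
            "ctcf": (0.85, 0.05),
            "rad21": (0.85, 0.05),
        }
    )
    enrichment_fold: Dict[str, float] = field(
        default_factory=lambda: {"dnase": 8.0, "ctcf": 8.0, "rad21": 8.0}
    )
    background_rate: float = 0.02  # reads per bp
    read_length: int = 50
    gc_site: float = 0.50
    gc_background: float = 0.40
    gc_background_sd: float = 0.10  # isochore-like block-level spread
    gc_block_bp: int = 5_000
    meth_site: float = 25.0
    meth_background: float = 75.0
    meth_sd: float = 10.0
    jitter_bp: int = 50  # feature-site offset from the TOP2B center
    seed: int = 1729

    def __post_init__(self) -> None:
        for name, (p_site, p_bg) in self.coloc_probs.items():
            if not (0.0 <= p_site <= 1.0 and 0.0 <= p_bg <= 1.0):
                raise ValueError(f"colocalization probabilities for {name} not in [0,1]")
        for name, fold in self.enrichment_fold.items():
            if fold < 0:
                raise ValueError(f"negative enrichment fold for {name}")
        if self.background_rate < 0:
            raise ValueError("negative background read rate")
        for frac in (self.gc_site, self.gc_background):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("G+C fractions must lie in [0, 1]")
        if not (0.0 <= self.meth_site <= 100.0 and 0.0 <= self.meth_background <= 100.0):
            raise ValueError("methylation means must lie in [0, 100]")

    @property
    def chrom_names(self) -> List[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["coloc_probs"] = {k: list(v) for k, v in self.coloc_probs.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "coloc_probs" in d:
            d["coloc_probs"] = {k: tuple(v) for k, v in d["coloc_probs"].items()}
        return cls(**d)


@dataclass
class GroundTruth:
    """True site locations for the synthetic world."""

    top2b_sites: IntervalSet
    feature_sites: Dict[str, IntervalSet]

    def label_of(self, region: GenomicInterval) -> int:
        return 1 if self.top2b_sites.overlaps_any(region) else 0


def _rng(config: SimulationConfig, offset: int, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng([config.seed, offset, extra])


def _site_starts(config: SimulationConfig) -> Dict[str, np.ndarray]:
    """Non-overlapping TOP2B site starts per chromosome, derived from the seed.

    Both the genome simulator (which plants elevated G+C at sites) and
    ``place_sites`` use this shared layout.  Sites keep a margin of one site
    width plus twice the jitter from chromosome ends and from each other so
    that jittered feature placements never collide or run off the end.
    """
    rng = _rng(config, _SEED_SITES)
    w = config.site_width
    margin = w + 2 * config.jitter_bp
    per_chrom = np.full(config.n_chroms, config.n_sites // config.n_chroms)
    per_chrom[: config.n_sites % config.n_chroms] += 1
    out: Dict[str, np.ndarray] = {}
    for chrom, n in zip(config.chrom_names, per_chrom):
        n = int(n)
        lo, hi = margin, config.chrom_length - margin - w
        if hi <= lo or n * 2 * margin > (hi - lo):
            raise ValueError(
                f"genome too small to place {n} non-overlapping sites on {chrom}"
            )
        starts: List[int] = []
        attempts = 0
        while len(starts) < n:
            attempts += 1
            if attempts > 1000 * n:
                raise ValueError(f"could not place sites on {chrom}")
            s = int(rng.integers(lo, hi))
            if all(abs(s - t) >= w + margin for t in starts):
                starts.append(s)
        out[chrom] = np.sort(np.array(starts))
    return out


def simulate_genome(config: SimulationConfig) -> Genome:
    """Simulate the toy genome with elevated G+C at TOP2B site positions.

    Each base is drawn independently with a position-specific G+C
    probability: ``gc_site`` inside sites and a block-level value around
    ``gc_background`` elsewhere.  G vs C and A vs T are equiprobable.
    """
    rng = _rng(config, _SEED_GENOME)
    starts = _site_starts(config)
    sequences: Dict[str, str] = {}
    n_blocks = -(-config.chrom_length // config.gc_block_bp)
    for chrom in config.chrom_names:
        block_gc = np.clip(
            rng.normal(config.gc_background, config.gc_background_sd, n_blocks),
            0.05,
            0.95,
        )
        p_gc = np.repeat(block_gc, config.gc_block_bp)[: config.chrom_length]
        for s in starts[chrom]:
            p_gc[s : s + config.site_width] = config.gc_site
        u = rng.random(config.chrom_length)
        is_gc = u < p_gc
        second = rng.random(config.chrom_length) < 0.5
        # A=65 C=67 G=71 T=84
        codes = np.where(is_gc, np.where(second, 71, 67), np.where(second, 84, 65))
        sequences[chrom] = codes.astype(np.uint8).tobytes().decode("ascii")
    return Genome(sequences)


def place_sites(config: SimulationConfig, genome: Genome) -> GroundTruth:
    """Place TOP2B sites and colocalized / background feature intervals.

    For each feature a site-width interval is centered (with uniform
    +/- ``jitter_bp`` offset) on every TOP2B site with probability
    ``p_at_site``.  Additional background feature intervals are scattered
    uniformly outside TOP2B sites at the density that makes a random
    site-width region overlap the feature with probability about
    ``p_at_background``.
    """
    for chrom in config.chrom_names:
        if chrom not in genome or genome.lengths[chrom] < config.chrom_length:
            raise ValueError("genome does not match simulation config")
    starts = _site_starts(config)
    w = config.site_width
    top2b = IntervalSet(
        GenomicInterval(chrom, int(s), int(s) + w)
        for chrom, arr in starts.items()
        for s in arr
    )
    total_bp = config.n_chroms * config.chrom_length
    feature_sites: Dict[str, IntervalSet] = {}
    for fi, (feature, (p_site, p_bg)) in enumerate(sorted(config.coloc_probs.items())):
        rng = _rng(config, _SEED_FEATURES, fi)
        placed: List[GenomicInterval] = []
        for iv in top2b:
            if rng.random() < p_site:
                off = int(rng.integers(-config.jitter_bp, config.jitter_bp + 1))
                placed.append(GenomicInterval(iv.chrom, iv.start + off, iv.end + off))
        # a random w-bp region overlaps a w-bp feature iff their starts are
        # within w of each other: footprint ~ 2w per background feature
        n_bg = int(round(p_bg * total_bp / (2 * w)))
        accepted = 0
        attempts = 0
        while accepted < n_bg:
            attempts += 1
            if attempts > 100 * max(n_bg, 1):
                break
            chrom = config.chrom_names[int(rng.integers(config.n_chroms))]
            s = int(rng.integers(0, config.chrom_length - w))
            cand = GenomicInterval(chrom, s, s + w)
            if top2b.overlaps_any(cand):
                continue
            placed.append(cand)
            accepted += 1
        feature_sites[feature] = IntervalSet(placed)
    return GroundTruth(top2b_sites=top2b, feature_sites=feature_sites)


def simulate_reads(
    feature: str, truth: GroundTruth, config: SimulationConfig
) -> Tuple[ReadLibrary, ReadLibrary]:
    """Simulate a (test, input) pair of read libraries for one feature.

    Background reads are Poisson with ``background_rate`` per bp of start
    positions; inside feature sites the rate is multiplied by
    ``enrichment_fold``.  The input library has no site enrichment.  Reads
    are fixed-length with uniform starts; ``library_size`` equals the number
    of reads emitted.
    """
    fold = config.enrichment_fold.get(feature, 1.0)
    if fold < 0 or config.background_rate < 0:
        raise ValueError("negative rates")
    fi = sorted(config.coloc_probs).index(feature) if feature in config.coloc_probs else 99
    rng = _rng(config, _SEED_READS, fi)
    rl = config.read_length

    def _background(r: np.random.Generator) -> List[GenomicInterval]:
        reads = []
        for chrom in config.chrom_names:
            n = r.poisson(config.background_rate * config.chrom_length)
            starts = r.integers(0, config.chrom_length - rl, n)
            reads.extend(GenomicInterval(chrom, int(s), int(s) + rl) for s in starts)
        return reads

    test_reads = _background(rng)
    sites = truth.feature_sites.get(feature, IntervalSet())
    for iv in sites:
        extra = rng.poisson(config.background_rate * (fold - 1.0) * iv.width)
        if extra > 0:
            hi = max(iv.start + 1, iv.end - rl)
            starts = rng.integers(iv.start, hi, extra)
            test_reads.extend(
                GenomicInterval(iv.chrom, int(s), int(s) + rl) for s in starts
            )
    input_reads = _background(rng)
    test = ReadLibrary(IntervalSet(test_reads))
    inp = ReadLibrary(IntervalSet(input_reads))
    return test, inp


def simulate_methylation(
    genome: Genome, truth: GroundTruth, config: SimulationConfig
) -> MethylationTable:
    """Assign every genomic CpG a percent methylation: hypomethylated at sites.

    Values are normal around ``meth_site`` inside TOP2B sites and
    ``meth_background`` elsewhere, clamped to [0, 100].
    """
    rng = _rng(config, _SEED_METH)
    records: List[Tuple[str, int, float]] = []
    for chrom, seq in sorted(genome.sequences.items()):
        positions = _find_cpg(seq)
        if len(positions) == 0:
            continue
        site_ivs = truth.top2b_sites.by_chrom(chrom)
        in_site = np.zeros(len(positions), dtype=bool)
        for iv in site_ivs:
            lo = np.searchsorted(positions, iv.start)
            hi = np.searchsorted(positions, iv.end)
            in_site[lo:hi] = True
        means = np.where(in_site, config.meth_site, config.meth_background)
        pct = np.clip(rng.normal(means, config.meth_sd), 0.0, 100.0)
        records.extend(
            (chrom, int(p), float(v)) for p, v in zip(positions, pct)
        )
    return MethylationTable(records)


def _find_cpg(seq: str) -> np.ndarray:
    """0-based positions of the C of every CpG dinucleotide."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))


def simulate_world(config: Optional[SimulationConfig] = None):
    """Run all generators; returns (genome, truth, libraries, methylation).

    ``libraries`` maps feature name -> (test ReadLibrary, input ReadLibrary).
    """
    config = config or SimulationConfig()
    genome = simulate_genome(config)
    truth = place_sites(config, genome)
    libraries = {
        feature: simulate_reads(feature, truth, config)
        for feature in sorted(config.coloc_probs)
    }
    methylation = simulate_methylation(genome, truth, config)
    return genome, truth, libraries, methylation


def write_world(outdir, config: Optional[SimulationConfig] = None) -> dict:
    """Materialize the world as FASTA + BED + TSV files; returns the paths.

    The pipeline can then consume synthetic and real data through the same
    readers.  A full-genome mappability BED and an empty blacklist are
    written so the filtering stages run unchanged.
    """
    config = config or SimulationConfig()
    os.makedirs(outdir, exist_ok=True)
    genome, truth, libraries, methylation = simulate_world(config)
    paths = {"genome": os.path.join(outdir, "genome.fa")}
    write_fasta(genome, paths["genome"])
    paths["top2b_sites"] = os.path.join(outdir, "top2b_sites.bed")
    write_bed(truth.top2b_sites, paths["top2b_sites"])
    for feature, sites in truth.feature_sites.items():
        p = os.path.join(outdir, f"{feature}_sites.bed")
        write_bed(sites, p)
        paths[f"{feature}_sites"] = p
    for feature, (test, inp) in libraries.items():
        pt = os.path.join(outdir, f"{feature}_test_reads.bed")
        pi = os.path.join(outdir, f"{feature}_input_reads.bed")
        write_bed(test.reads, pt)
        write_bed(inp.reads, pi)
        paths[f"{feature}_test_reads"] = pt
        paths[f"{feature}_input_reads"] = pi
    paths["methylation"] = os.path.join(outdir, "methylation.tsv")
    write_methylation(methylation, paths["methylation"])
    mappable = IntervalSet(
        GenomicInterval(c, 0, length) for c, length in genome.lengths.items()
    )
    paths["mappability"] = os.path.join(outdir, "mappability.bed")
    write_bed(mappable, paths["mappability"])
    paths["blacklist"] = os.path.join(outdir, "blacklist.bed")
    open(paths["blacklist"], "w").close()
    paths["config"] = os.path.join(outdir, "world.yaml")
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(config.to_dict(), fh)
    return paths


def simulate_selection_matrix(
    n_rows: int = 800,
    n_informative: int = 3,
    n_features: int = 20,
    n_redundant: int = 4,
    seed: int = 7,
):
    """Simulated feature matrix for feature-selection benchmarks.

    Balanced binary labels; ``n_informative`` mutually independent features
    carry the class signal (Gaussian class shifts of 2.6, 2.3 and 2.0 SD so
    each has symmetrical uncertainty with the class of at least about 0.3);
    ``n_redundant`` features are attenuated noisy copies of informative ones
    (they share signal with an informative feature but carry little class
    information of their own); the rest are pure standard-normal noise.
    Returns ``(X, feature_names, labels)``.
    """
    if n_informative + n_redundant > n_features:
        raise ValueError("n_informative + n_redundant exceeds n_features")
    rng = np.random.default_rng([seed, 11])
    y = np.zeros(n_rows, dtype=int)
    y[n_rows // 2 :] = 1
    shifts = [2.6, 2.3, 2.0, 1.8, 1.6][:n_informative]
    cols = []
    names = []
    for i, shift in enumerate(shifts):
        cols.append(rng.normal(0.0, 1.0, n_rows) + shift * y)
        names.append(f"signal_{i + 1}")
    for j in range(n_redundant):
        src = j % n_informative
        cols.append(0.4 * cols[src] + rng.normal(0.0, 1.2, n_rows))
        names.append(f"redundant_{j + 1}")
    for j in range(n_features - n_informative - n_redundant):
        cols.append(rng.normal(0.0, 1.0, n_rows))
        names.append(f"noise_{j + 1}")
    X = np.column_stack(cols)
    return X, names, y
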