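"""Genome-wide tiling, virtual probability tracks and their evaluation.

The genome is tiled into 300-bp windows advanced by 50 bp; each window is
scored for the model's features and assigned a binding probability,
producing a virtual track that can be serialized as bedGraph.  Windows
exceeding a probability threshold (default 0.95) are merged into predicted
binding sites, which are then compared with experimental peak sets by
overlap fractions and log-scale signal correlation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .classification import FeatureMatrix, Model
from .core_io import Genome, GenomicInterval, IntervalSet
from .region_ops import DEFAULT_MAX_BAD_FRAC, LabeledRegions
from .signal_scoring import FeatureSpec, build_feature_matrix

__all__ = [
    "ProbabilityTrack",
    "tile_genome",
    "predict_track",
    "track_to_peaks",
    "overlap_fractions",
    "track_correlation",
]


@dataclass
class ProbabilityTrack:
    """Tiled windows with one class-1 probability each."""

    windows: IntervalSet
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.probs) != len(self.windows):
            raise ValueError("probs length must match window count")
        keys = [iv.sort_key() for iv in self.windows]
        if keys != sorted(keys):
            raise ValueError("track windows must be sorted")

    def __len__(self) -> int:
        return len(self.windows)

    def mean_prob_in(self, region: GenomicInterval) -> float:
        """Mean probability over windows overlapping a region; NaN if none."""
        idx = [
            i
            for i, iv in enumerate(self.windows)
            if iv.overlaps(region)
        ]
        if not idx:
            return float("nan")
        return float(self.probs[idx].mean())


def tile_genome(
    genome: Genome,
    nonmappable: Optional[IntervalSet] = None,
    width: int = 300,
    step: int = 50,
    max_bad_frac: float = DEFAULT_MAX_BAD_FRAC,
) -> IntervalSet:
    """Sliding windows of ``width`` bp advanced by ``step`` bp per chromosome.

    Windows start at 0 and the last window satisfies start + width <= length
    (chromosomes shorter than the width yield zero windows, with a warning).
    Windows with more than ``max_bad_frac`` of their bases on non-mappable
    intervals are dropped.
    """
    if width < step:
        raise ValueError("width must be >= step")
    out: List[GenomicInterval] = []
    for chrom, length in sorted(genome.lengths.items()):
        if length < width:
            warnings.warn(f"chromosome {chrom} shorter than window width", stacklevel=2)
            continue
        for s in range(0, length - width + 1, step):
            iv = GenomicInterval(chrom, s, s + width)
            if (
                nonmappable is not None
                and nonmappable.overlap_bases(iv) / width > max_bad_frac
            ):
                continue
            out.append(iv)
    return IntervalSet(out)


def predict_track(
    model: Model,
    windows: IntervalSet,
    specs: Sequence[FeatureSpec],
    genome: Optional[Genome] = None,
) -> ProbabilityTrack:
    """Score every window under the model's features and predict probabilities.

    The spec names must match the model's feature-name manifest in order.
    """
    regions = LabeledRegions(
        regions=windows,
        labels=np.zeros(len(windows), dtype=int),
        provenance="observed",
    )
    matrix = build_feature_matrix(regions, specs, genome=genome)
    if matrix.feature_names != model.feature_names:
        raise ValueError(
            f"manifest mismatch: model expects {model.feature_names}, "
            f"specs produce {matrix.feature_names}"
        )
    probs = model.predict_proba(matrix.values)[:, 1]
    return ProbabilityTrack(windows=windows, probs=probs)


def track_to_peaks(track: ProbabilityTrack, threshold: float = 0.95) -> IntervalSet:
    """Merge windows with probability strictly above ``threshold`` into peaks.

    Overlapping or book-ended qualifying windows form one peak whose score
    is the maximum constituent probability.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    peaks: List[GenomicInterval] = []
    cur: Optional[Tuple[str, int, int, float]] = None
    for iv, p in zip(track.windows, track.probs):
        if p <= threshold:
            continue
        if cur is not None and iv.chrom == cur[0] and iv.start <= cur[2]:
            cur = (cur[0], cur[1], max(cur[2], iv.end), max(cur[3], float(p)))
        else:
            if cur is not None:
                peaks.append(GenomicInterval(cur[0], cur[1], cur[2], score=cur[3]))
            cur = (iv.chrom, iv.start, iv.end, float(p))
    if cur is not None:
        peaks.append(GenomicInterval(cur[0], cur[1], cur[2], score=cur[3]))
    return IntervalSet(peaks)


def overlap_fractions(sets: Dict[str, IntervalSet]) -> dict:
    """Pairwise overlap fractions and joint membership counts for Venn export.

    For every ordered pair (A, B), ``fractions[A][B]`` is the fraction of
    A's members overlapping >= 1 bp with B (each member counted once).
    ``patterns`` counts, per set, how many members overlap each combination
    of the other sets.
    """
    names = list(sets)
    fractions: Dict[str, Dict[str, float]] = {}
    patterns: Dict[str, Dict[str, int]] = {}
    for a in names:
        fractions[a] = {}
        pattern_counts: Dict[str, int] = {}
        others = [b for b in names if b != a]
        hit_counts = {b: 0 for b in others}
        for iv in sets[a]:
            hits = tuple(b for b in others if sets[b].overlaps_any(iv))
            for b in hits:
                hit_counts[b] += 1
            key = "&".join(hits) if hits else "none"
            pattern_counts[key] = pattern_counts.get(key, 0) + 1
        n = len(sets[a])
        for b in others:
            fractions[a][b] = 100.0 * hit_counts[b] / n if n else 0.0
        patterns[a] = pattern_counts
    return {"fractions": fractions, "patterns": patterns}


def track_correlation(
    track: ProbabilityTrack,
    reads,
    regions: IntervalSet,
) -> float:
    """Pearson r between log2 track probability and log2 read count per region.

    Both the per-region mean probability and the read count get a log2(x+1)
    transform before correlation.  Returns NaN when either side has zero
    variance.  Requires >= 3 regions.
    """
    if len(regions) < 3:
        raise ValueError("need at least 3 regions")
    from .signal_scoring import count_reads

    probs = []
    counts = []
    for iv in regions:
        p = track.mean_prob_in(iv)
        if np.isnan(p):
            continue
        probs.append(p)
        counts.append(count_reads(reads, iv))
    a = np.log2(np.asarray(probs) + 1.0)
    b = np.log2(np.asarray(counts, dtype=float) + 1.0)
    if len(a) < 3 or a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])
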