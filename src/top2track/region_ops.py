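"""Peak filtering, replicate intersection, backgrounds and region annotation.

Background generation follows the training-set construction used for the
binding model: one random region per observed peak, with the same
per-chromosome distribution, avoiding peaks, blacklisted and non-mappable
regions, and (optionally) windows with high test/input signal.  A second,
GC-matched background is built by iterative greedy matching of candidate
G+C content to the peak G+C distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np

from .core_io import Genome, GenomicInterval, IntervalSet

__all__ = [
    "LabeledRegions",
    "filter_peaks",
    "intersect_replicates",
    "resize_to_center",
    "random_regions",
    "gc_matched_regions",
    "gc_content",
    "annotate_open_chromatin",
]

DEFAULT_MIN_FOLD = 5.0
DEFAULT_MAX_BAD_FRAC = 0.20
DEFAULT_GC_TOLERANCE = 1.0 / 300.0  # one base equivalent at 300 bp


@dataclass
class LabeledRegions:
    """Uniform-width regions with binary labels (1 = site, 0 = background)."""

    regions: IntervalSet
    labels: np.ndarray
    provenance: str  # {"observed", "random", "gc_matched"} for the background half

    def __post_init__(self) -> None:
        widths = {iv.width for iv in self.regions}
        if len(widths) > 1:
            raise ValueError(f"regions must have uniform width, got {sorted(widths)}")
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.regions):
            raise ValueError("labels length does not match region count")

    @classmethod
    def from_sites_and_background(
        cls, sites: IntervalSet, background: IntervalSet, provenance: str
    ) -> "LabeledRegions":
        regions = IntervalSet.from_ordered(list(sites) + list(background))
        labels = np.array([1] * len(sites) + [0] * len(background))
        return cls(regions=regions, labels=labels, provenance=provenance)


def filter_peaks(
    peaks: IntervalSet,
    nonmappable: IntervalSet,
    blacklist: IntervalSet,
    min_fold: float = DEFAULT_MIN_FOLD,
    max_bad_frac: float = DEFAULT_MAX_BAD_FRAC,
) -> IntervalSet:
    """Keep peaks with fold change strictly above ``min_fold`` and at most
    ``max_bad_frac`` of their width on non-mappable or blacklisted bases.

    ``nonmappable`` holds the *excluded* (non-mappable) intervals; use
    :func:`top2track.core_io.complement_intervals` to convert a mappability
    BED.  Every peak must carry its fold change in the score field.
    """
    bad = IntervalSet(list(nonmappable) + list(blacklist)).merge()
    kept = []
    for iv in peaks:
        if iv.score is None:
            raise ValueError(f"peak without fold-change score: {iv}")
        if iv.score <= min_fold:
            continue
        if bad.overlap_bases(iv) / iv.width > max_bad_frac:
            continue
        kept.append(iv)
    return IntervalSet(kept)


def intersect_replicates(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Peaks of ``a`` overlapping >= 1 bp with some peak of ``b`` (a's coords kept)."""
    return a.intersecting(b)


def resize_to_center(regions: IntervalSet, genome: Genome, width: int = 300) -> IntervalSet:
    """Center each region on its midpoint at exactly ``width`` bp.

    Regions whose resized interval would extend past a chromosome end are
    dropped rather than truncated (widths must stay uniform).
    """
    if width <= 0:
        raise ValueError("width must be positive")
    out = []
    half = width // 2
    for iv in regions:
        mid = (iv.start + iv.end) // 2
        start = mid - half
        end = start + width
        if start < 0 or end > genome.lengths.get(iv.chrom, 0):
            continue
        out.append(GenomicInterval(iv.chrom, start, end, iv.name, iv.score))
    return IntervalSet(out)


def random_regions(
    peaks: IntervalSet,
    genome: Genome,
    nonmappable: IntervalSet,
    blacklist: IntervalSet,
    exclusion_signal: Optional[Callable[[GenomicInterval], float]] = None,
    exclusion_quantile: float = 0.95,
    width: int = 300,
    seed: int = 0,
    max_attempts_per_region: int = 2000,
    _rng: Optional[np.random.Generator] = None,
) -> IntervalSet:
    """Seeded rejection sampling of one background region per observed peak.

    Matches the per-chromosome peak counts; rejects candidates overlapping a
    peak, blacklisted/non-mappable bases, an already-accepted region, or a
    window whose ``exclusion_signal`` (e.g. the test/input log-ratio) exceeds
    the ``exclusion_quantile`` of genome-tiled windows.
    """
    rng = _rng if _rng is not None else np.random.default_rng(seed)
    bad = IntervalSet(list(nonmappable) + list(blacklist)).merge()
    threshold = None
    if exclusion_signal is not None:
        scores = []
        for chrom, length in genome.lengths.items():
            for s in range(0, length - width + 1, width):
                scores.append(exclusion_signal(GenomicInterval(chrom, s, s + width)))
        threshold = float(np.quantile(scores, exclusion_quantile))
    accepted: List[GenomicInterval] = []
    accepted_set = IntervalSet()
    for chrom, n in sorted(peaks.counts_per_chrom().items()):
        length = genome.lengths.get(chrom)
        if length is None:
            raise ValueError(f"peaks on unknown chromosome {chrom!r}")
        got = 0
        attempts = 0
        chrom_accepted: List[GenomicInterval] = []
        while got < n:
            attempts += 1
            if attempts > max_attempts_per_region * n:
                raise RuntimeError(
                    f"could not place {n} background regions on {chrom} "
                    f"after {attempts} attempts"
                )
            s = int(rng.integers(0, length - width + 1))
            cand = GenomicInterval(chrom, s, s + width)
            if peaks.overlaps_any(cand) or bad.overlaps_any(cand):
                continue
            if any(cand.overlaps(prev) for prev in chrom_accepted):
                continue
            if threshold is not None and exclusion_signal(cand) > threshold:
                continue
            chrom_accepted.append(cand)
            got += 1
        accepted.extend(chrom_accepted)
    return IntervalSet(accepted)


def gc_content(interval: GenomicInterval, genome: Genome) -> float:
    """G+C fraction of an interval, ignoring N bases; NaN if all N."""
    seq = genome.fetch(interval)
    n_n = seq.count("N")
    denom = len(seq) - n_n
    if denom == 0:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / denom


CandidateSource = Union[IntervalSet, Callable[[int, np.random.Generator], IntervalSet]]


def gc_matched_regions(
    peaks: IntervalSet,
    genome: Genome,
    candidates: CandidateSource,
    tolerance: float = DEFAULT_GC_TOLERANCE,
    max_iterations: int = 100,
    seed: int = 0,
) -> IntervalSet:
    """Iterative greedy G+C matching of background candidates to peaks.

    Each iteration draws fresh candidate regions — either from a callable
    ``candidates(n, rng) -> IntervalSet`` or by sampling without replacement
    from a pre-drawn pool — and retains a candidate iff its G+C content is
    within ``tolerance`` of some still-unmatched peak on the same
    chromosome; the matched peak (smallest |dGC|, then smallest coordinate)
    leaves the pool.  Terminates when every peak is matched, or raises after
    ``max_iterations`` listing the unmatched peaks and their G+C values.
    """
    rng = np.random.default_rng(seed)
    unmatched: Dict[str, List[tuple]] = {}
    for iv in peaks:
        unmatched.setdefault(iv.chrom, []).append((gc_content(iv, genome), iv))
    pool: Optional[List[GenomicInterval]] = None
    if isinstance(candidates, IntervalSet):
        pool = list(candidates)
        order = rng.permutation(len(pool))
        pool = [pool[i] for i in order]

    matched: List[GenomicInterval] = []
    n_target = len(peaks)
    for _ in range(max_iterations):
        remaining = sum(len(v) for v in unmatched.values())
        if remaining == 0:
            break
        batch_size = max(remaining * 20, 500)
        if pool is not None:
            if not pool:
                break
            batch, pool = pool[:batch_size], pool[batch_size:]
        else:
            batch = list(candidates(batch_size, rng))
        for cand in batch:
            peers = unmatched.get(cand.chrom)
            if not peers:
                continue
            cgc = gc_content(cand, genome)
            if np.isnan(cgc):
                continue
            best_i = None
            best_key = None
            for i, (pgc, piv) in enumerate(peers):
                d = abs(cgc - pgc)
                if d <= tolerance:
                    key = (d, piv.chrom, piv.start)
                    if best_key is None or key < best_key:
                        best_key = key
                        best_i = i
            if best_i is not None:
                peers.pop(best_i)
                matched.append(cand)
    if len(matched) < n_target:
        leftover = [
            f"{iv.chrom}:{iv.start}-{iv.end} GC={pgc:.3f}"
            for peers in unmatched.values()
            for pgc, iv in peers
        ]
        raise RuntimeError(
            "GC matching did not converge; unmatched peaks: " + "; ".join(leftover)
        )
    return IntervalSet(matched)


_OPEN_CHROMATIN_CLASSES = (
    "promoter",
    "weak_promoter",
    "enhancer",
    "weak_enhancer",
    "insulator",
)


def annotate_open_chromatin(
    dnase_peaks: IntervalSet,
    h3k4me3_scores: Sequence[float],
    h3k4me1_scores: Sequence[float],
    tss: IntervalSet,
    ctcf_peaks: IntervalSet,
    promoter_ratio: float = 1.5,
    enhancer_ratio: float = 0.67,
) -> List[str]:
    """Five-class annotation of open-chromatin (DNase) peaks.

    H3K4me3/H3K4me1 fold ratio > 1.5 -> promoter; < 0.67 -> enhancer.  The
    remaining peaks split into low-signal (both marks below their median
    over peaks) and roughly-equal-ratio groups: low-signal peaks overlapping
    CTCF are insulators, other low-signal peaks are weak enhancers;
    roughly-equal peaks overlapping a TSS are weak promoters, the rest weak
    enhancers.  A zero H3K4me1 denominator takes the low-signal path.
    """
    me3 = np.asarray(h3k4me3_scores, dtype=float)
    me1 = np.asarray(h3k4me1_scores, dtype=float)
    if len(me3) != len(dnase_peaks) or len(me1) != len(dnase_peaks):
        raise ValueError("histone score vectors must align with peaks")
    me3_med = float(np.median(me3))
    me1_med = float(np.median(me1))
    classes: List[str] = []
    for iv, s3, s1 in zip(dnase_peaks, me3, me1):
        ratio = s3 / s1 if s1 > 0 else None
        if ratio is not None and ratio > promoter_ratio:
            classes.append("promoter")
        elif ratio is not None and ratio < enhancer_ratio:
            classes.append("enhancer")
        else:
            low_signal = (s3 < me3_med and s1 < me1_med) or ratio is None
            if low_signal:
                if ctcf_peaks.overlaps_any(iv):
                    classes.append("insulator")
                else:
                    classes.append("weak_enhancer")
            else:
                if tss.overlaps_any(iv):
                    classes.append("weak_promoter")
                else:
                    classes.append("weak_enhancer")
    return classes
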