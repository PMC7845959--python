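"""Per-region scoring of sequencing signal, methylation, sequence and shape.

ChIP-seq enrichment in a window is scored by the order: count reads in the
window, normalize to library size and scale to the smaller of the test and
input libraries, add a pseudocount of 1, take the test/input ratio, and log2
transform.  Accessibility-style assays (DNase-seq, MNase-seq, RNA-seq) are
scored as window read count divided by library size, and CpG methylation as
the mean percent methylation over CpGs in the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .classification import FeatureMatrix
from .core_io import (
    Genome,
    GenomicInterval,
    IntervalSet,
    MethylationTable,
    ReadLibrary,
)
from .region_ops import LabeledRegions
from .sequence_encoding import (
    ShapeTable,
    encode_kmers,
    encode_shape,
    kmer_feature_names,
    shape_feature_names,
)

__all__ = [
    "FeatureSpec",
    "count_reads",
    "count_reads_windows",
    "score_chip",
    "score_chip_windows",
    "score_coverage",
    "score_methylation",
    "signal_profile",
    "build_feature_matrix",
]


def count_reads(
    lib: ReadLibrary, window: GenomicInterval, rule: str = "overlap"
) -> int:
    """Number of reads assigned to a window.

    ``rule='overlap'`` counts any >= 1 bp overlap (default); ``'midpoint'``
    counts reads whose midpoint falls inside the window.
    """
    if rule == "overlap":
        return int(
            lib.count_in(
                window.chrom,
                np.array([window.start]),
                np.array([window.end]),
            )[0]
        )
    if rule == "midpoint":
        n = 0
        for read in lib.reads.find_overlaps(
            GenomicInterval(window.chrom, max(0, window.start - 10_000), window.end + 10_000)
        ):
            mid = (read.start + read.end) // 2
            if window.start <= mid < window.end:
                n += 1
        return n
    raise ValueError(f"unknown counting rule {rule!r}")


def count_reads_windows(
    lib: ReadLibrary, chrom: str, starts: np.ndarray, width: int
) -> np.ndarray:
    """Vectorized any-overlap counts for same-width windows on one chromosome."""
    starts = np.asarray(starts)
    return lib.count_in(chrom, starts, starts + width)


def score_chip(
    test: ReadLibrary, input_: ReadLibrary, window: GenomicInterval
) -> float:
    """log2 test/input enrichment of a window.

    With m = min(N_test, N_input) and c the window read counts:
    log2((c_test * m / N_test + 1) / (c_input * m / N_input + 1)).
    """
    return float(
        score_chip_windows(
            test, input_, window.chrom, np.array([window.start]), window.width
        )[0]
    )


def score_chip_windows(
    test: ReadLibrary,
    input_: ReadLibrary,
    chrom: str,
    starts: np.ndarray,
    width: int,
) -> np.ndarray:
    if test.library_size <= 0 or input_.library_size <= 0:
        raise ValueError("library sizes must be positive")
    m = min(test.library_size, input_.library_size)
    ct = count_reads_windows(test, chrom, starts, width) * (m / test.library_size)
    ci = count_reads_windows(input_, chrom, starts, width) * (m / input_.library_size)
    return np.log2((ct + 1.0) / (ci + 1.0))


def score_coverage(lib: ReadLibrary, window: GenomicInterval) -> float:
    """Window read count divided by library size (RNA/DNase/MNase scoring)."""
    if lib.library_size <= 0:
        raise ValueError("library size must be positive")
    return count_reads(lib, window) / lib.library_size


def score_methylation(
    table: MethylationTable, window: GenomicInterval
) -> float:
    """Mean percent methylation over CpGs in the window; NaN when no CpG."""
    values = table.in_window(window)
    if len(values) == 0:
        return float("nan")
    return float(values.mean())


def signal_profile(
    lib: ReadLibrary,
    centers: IntervalSet,
    flank_bp: int,
    bin_bp: int = 50,
    smooth_bp: int = 0,
) -> np.ndarray:
    """Mean normalized coverage in bins within +/- ``flank_bp`` of centers.

    Returns a vector of length 2*flank/bin: per-bin read counts averaged
    over centers and divided by library size, optionally smoothed with a
    centered moving average of width ``smooth_bp``.
    """
    if len(centers) == 0:
        raise ValueError("centers must be non-empty")
    if flank_bp % bin_bp != 0:
        raise ValueError("flank_bp must be a multiple of bin_bp")
    n_bins = 2 * flank_bp // bin_bp
    total = np.zeros(n_bins)
    for iv in centers:
        mid = iv.center
        starts = mid - flank_bp + bin_bp * np.arange(n_bins)
        valid = starts >= 0
        counts = np.zeros(n_bins)
        counts[valid] = lib.count_in(iv.chrom, starts[valid], starts[valid] + bin_bp)
        total += counts
    profile = total / (len(centers) * lib.library_size)
    if smooth_bp > bin_bp:
        w = max(1, smooth_bp // bin_bp)
        kernel = np.ones(w) / w
        profile = np.convolve(profile, kernel, mode="same")
    return profile


@dataclass
class FeatureSpec:
    """Declarative description of one feature (column group) of the matrix.

    kind: one of chip | coverage | methylation | kmer | shape.
    """

    name: str
    kind: str
    test: Optional[ReadLibrary] = None
    input_: Optional[ReadLibrary] = None
    lib: Optional[ReadLibrary] = None
    methylation: Optional[MethylationTable] = None
    k: Optional[int] = None
    shape_table: Optional[ShapeTable] = None

    def __post_init__(self) -> None:
        kinds = ("chip", "coverage", "methylation", "kmer", "shape")
        if self.kind not in kinds:
            raise ValueError(f"unknown feature kind {self.kind!r}; choose {kinds}")
        if self.kind == "chip" and (self.test is None or self.input_ is None):
            raise ValueError(f"{self.name}: chip features need test and input libraries")
        if self.kind == "coverage" and self.lib is None:
            raise ValueError(f"{self.name}: coverage features need a read library")
        if self.kind == "methylation" and self.methylation is None:
            raise ValueError(f"{self.name}: methylation features need a table")
        if self.kind == "kmer" and not self.k:
            raise ValueError(f"{self.name}: kmer features need k")
        if self.kind == "shape" and self.shape_table is None:
            raise ValueError(f"{self.name}: shape features need a shape table")


def _spec_columns(spec: FeatureSpec, width: int) -> List[str]:
    if spec.kind in ("chip", "coverage", "methylation"):
        return [spec.name]
    if spec.kind == "kmer":
        return kmer_feature_names(width, spec.k)
    return shape_feature_names(width, spec.shape_table)


def build_feature_matrix(
    regions: LabeledRegions,
    specs: Sequence[FeatureSpec],
    genome: Optional[Genome] = None,
) -> FeatureMatrix:
    """Score every region under every feature spec into a dense matrix.

    Column order is deterministic: spec order, then positional sub-index
    within multi-column (kmer/shape) specs.  Missing methylation values are
    imputed by the column mean and the affected columns are recorded in
    ``metadata['imputed_columns']``.  Sequence-based specs require a genome.
    """
    widths = {iv.width for iv in regions.regions}
    width = widths.pop()
    needs_genome = any(s.kind in ("kmer", "shape") for s in specs)
    if needs_genome and genome is None:
        raise ValueError("sequence-based feature specs require a genome")
    if genome is not None:
        for iv in regions.regions:
            genome.validate(iv)
    blocks: List[np.ndarray] = []
    names: List[str] = []
    region_list = list(regions.regions)
    for spec in specs:
        cols = _spec_columns(spec, width)
        names.extend(cols)
        if spec.kind == "chip":
            col = np.array([score_chip(spec.test, spec.input_, iv) for iv in region_list])
            blocks.append(col[:, None])
        elif spec.kind == "coverage":
            col = np.array([score_coverage(spec.lib, iv) for iv in region_list])
            blocks.append(col[:, None])
        elif spec.kind == "methylation":
            col = np.array(
                [score_methylation(spec.methylation, iv) for iv in region_list]
            )
            blocks.append(col[:, None])
        elif spec.kind == "kmer":
            block = np.stack(
                [encode_kmers(genome.fetch(iv), spec.k) for iv in region_list]
            ).astype(float)
            blocks.append(block)
        else:  # shape
            rows = []
            for iv in region_list:
                vecs = encode_shape(genome.fetch(iv), spec.shape_table)
                rows.append(
                    np.concatenate(
                        [vecs[f] for f in spec.shape_table.feature_names]
                    )
                )
            blocks.append(np.stack(rows))
    values = np.hstack(blocks) if blocks else np.empty((len(region_list), 0))
    imputed: List[str] = []
    for j in range(values.shape[1]):
        col = values[:, j]
        mask = np.isnan(col)
        if mask.any():
            mean = float(np.nanmean(col)) if (~mask).any() else 0.0
            col[mask] = mean
            imputed.append(names[j])
    region_ids = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in region_list]
    return FeatureMatrix(
        values=values,
        feature_names=names,
        labels=regions.labels,
        region_ids=region_ids,
        metadata={
            "imputed_columns": imputed,
            "provenance": regions.provenance,
            "region_width": width,
        },
    )
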