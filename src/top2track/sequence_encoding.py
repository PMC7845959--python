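"""Positional k-mer one-hot encoding and pentamer-table DNA-shape features.

The k-mer encoding follows the positional scheme used for sequence-based
binding models: for a sequence of length L, each of the L-k+1 positions is
represented by a one-hot block of length 4^k marking the k-mer that starts
there, giving a binary vector of length 4^k(L-k+1).  Index order is
alphabetical (A < C < G < T).

DNA shape is encoded through a pentamer lookup table mapping each of the
1024 5-mers to a value per structural feature.  Seven features live at
base-pair resolution (assigned to the pentamer's central base) and six at
base-pair-step resolution (averaged onto the interior steps); terminal
positions and windows containing N are filled with the table's per-feature
mean so all regions yield equal-length vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core_io import Genome, GenomicInterval, IntervalSet

__all__ = [
    "BASE_ORDER",
    "SHAPE_FEATURES",
    "ShapeTable",
    "encode_kmers",
    "encode_shape",
    "dinucleotide_profile",
    "kmer_feature_names",
    "synthetic_shape_table",
    "read_shape_table",
    "write_shape_table",
]

BASE_ORDER = "ACGT"
_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(BASE_ORDER):
    _CODE[ord(_b)] = _i

#: The 13 structural features and their resolution.  Intra-base-pair
#: features (bp) describe one base pair; inter-base-pair features (step)
#: describe the geometry between adjacent base pairs.
SHAPE_FEATURES: Dict[str, str] = {
    "minor_groove_width": "bp",
    "propeller_twist": "bp",
    "shear": "bp",
    "stretch": "bp",
    "stagger": "bp",
    "buckle": "bp",
    "opening": "bp",
    "helix_twist": "step",
    "roll": "step",
    "shift": "step",
    "slide": "step",
    "rise": "step",
    "tilt": "step",
}

ALL_PENTAMERS: Tuple[str, ...] = tuple(
    "".join(p) for p in product(BASE_ORDER, repeat=5)
)


def _codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def encode_kmers(seq: str, k: int) -> np.ndarray:
    """Positional one-hot k-mer encoding of ``seq``.

    Returns a uint8 vector of length ``4**k * (L - k + 1)`` laid out as
    L-k+1 consecutive one-hot blocks; a block is all-zero when its window
    contains an N.
    """
    L = len(seq)
    if not 1 <= k <= L:
        raise ValueError(f"k={k} outside [1, {L}]")
    codes = _codes(seq)
    windows = sliding_window_view(codes, k)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1)
    idx = (np.where(windows >= 0, windows, 0) * powers).sum(axis=1)
    n_pos = L - k + 1
    block = 4**k
    vec = np.zeros(n_pos * block, dtype=np.uint8)
    positions = np.flatnonzero(valid)
    vec[positions * block + idx[positions]] = 1
    return vec


def kmer_feature_names(L: int, k: int) -> List[str]:
    """Column names ``k{k}_pos{p}_{kmer}`` matching :func:`encode_kmers` layout."""
    kmers = ["".join(t) for t in product(BASE_ORDER, repeat=k)]
    return [f"k{k}_pos{p}_{m}" for p in range(L - k + 1) for m in kmers]


@dataclass
class ShapeTable:
    """Pentamer -> value lookup for the 13 DNA shape features."""

    values: Dict[str, np.ndarray]  # feature -> array of 4^5 floats, ALL_PENTAMERS order
    resolution: Dict[str, str] = field(default_factory=lambda: dict(SHAPE_FEATURES))

    def __post_init__(self) -> None:
        for feature, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (len(ALL_PENTAMERS),):
                raise ValueError(
                    f"feature {feature!r}: expected {len(ALL_PENTAMERS)} pentamer "
                    f"values, got {arr.shape}"
                )
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite shape values for {feature!r}")
            self.values[feature] = arr

    @property
    def feature_names(self) -> List[str]:
        return list(self.values)

    def mean(self, feature: str) -> float:
        return float(self.values[feature].mean())


def _pentamer_indices(seq: str) -> Tuple[np.ndarray, np.ndarray]:
    """(index into ALL_PENTAMERS, validity mask) for each 5-bp window."""
    codes = _codes(seq)
    windows = sliding_window_view(codes, 5)
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(4, -1, -1)
    idx = (np.where(windows >= 0, windows, 0) * powers).sum(axis=1)
    return idx, valid


def encode_shape(seq: str, table: ShapeTable) -> Dict[str, np.ndarray]:
    """Per-feature shape vectors for ``seq`` (each padded to length L).

    A 5-bp window slides over the sequence (L-4 pentamers).  bp-resolution
    values are assigned to the central base (positions 2..L-3); step values
    of adjacent pentamers are averaged onto the L-5 interior steps and
    assigned to positions 2..L-4.  Remaining terminal positions, and any
    position whose pentamer contains an N, carry the per-feature table mean.
    """
    L = len(seq)
    if L < 5:
        raise ValueError("sequence shorter than a pentamer")
    idx, valid = _pentamer_indices(seq)
    out: Dict[str, np.ndarray] = {}
    for feature, arr in table.values.items():
        mean = table.mean(feature)
        vals = arr[idx]
        vals = np.where(valid, vals, mean)
        vec = np.full(L, mean)
        if table.resolution[feature] == "bp":
            vec[2 : L - 2] = vals  # L-4 central-base assignments
        else:
            step_vals = 0.5 * (vals[:-1] + vals[1:])  # L-5 interior steps
            both_ok = valid[:-1] & valid[1:]
            step_vals = np.where(both_ok, step_vals, mean)
            vec[2 : L - 3] = step_vals
        out[feature] = vec
    return out


def shape_feature_names(L: int, table: ShapeTable) -> List[str]:
    return [f"shape_{f}_pos{p}" for f in table.feature_names for p in range(L)]


def dinucleotide_profile(
    regions: IntervalSet, genome: Genome, flank_bp: int
) -> Tuple[List[str], np.ndarray]:
    """Positional dinucleotide frequencies within +/- ``flank_bp`` of centers.

    Returns (dinucleotide names, 16 x 2*flank matrix) where column j holds
    the frequency of each dinucleotide starting at offset j - flank from the
    region center; each column sums to 1 over the dinucleotides with data.
    Regions too close to a chromosome edge are dropped.
    """
    widths = {iv.width for iv in regions}
    if len(widths) > 1:
        raise ValueError("regions must have uniform width")
    dinucs = ["".join(t) for t in product(BASE_ORDER, repeat=2)]
    n_pos = 2 * flank_bp
    counts = np.zeros((16, n_pos))
    used = 0
    for iv in regions:
        mid = iv.center
        start = mid - flank_bp
        end = mid + flank_bp + 1  # one extra base for the final dinucleotide
        if start < 0 or end > genome.lengths[iv.chrom]:
            continue
        codes = _codes(genome.sequences[iv.chrom][start:end])
        first, second = codes[:-1], codes[1:]
        ok = (first >= 0) & (second >= 0)
        di = first * 4 + second
        cols = np.flatnonzero(ok)
        np.add.at(counts, (di[cols], cols), 1)
        used += 1
    if used == 0:
        raise ValueError("no region fits within the genome with the requested flank")
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        freqs = np.where(totals > 0, counts / totals, 0.0)
    return dinucs, freqs


def synthetic_shape_table(
    seed: int = 0, noise_sd: float = 0.05
) -> ShapeTable:
    """A synthetic stand-in pentamer table for testing and simulation.

    Per feature: a baseline value plus a smooth dependence on the pentamer's
    G+C count plus seeded noise.  The values are NOT the molecular-dynamics
    derived pentamer parameters of the published high-throughput tables;
    they only reproduce the lookup-table mechanics.
    """
    rng = np.random.default_rng(seed)
    gc_counts = np.array(
        [sum(b in "GC" for b in p) for p in ALL_PENTAMERS], dtype=float
    )
    values: Dict[str, np.ndarray] = {}
    for i, feature in enumerate(SHAPE_FEATURES):
        baseline = float(rng.uniform(-2.0, 2.0))
        slope = float(rng.uniform(-0.3, 0.3))
        values[feature] = (
            baseline + slope * (gc_counts - 2.5) + rng.normal(0.0, noise_sd, 1024)
        )
    return ShapeTable(values=values)


def read_shape_table(path) -> ShapeTable:
    """Read a shape-table TSV with columns pentamer, feature, value."""
    raw: Dict[str, Dict[str, float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            pentamer, feature, value = fields
            raw.setdefault(feature, {})[pentamer] = float(value)
    values: Dict[str, np.ndarray] = {}
    for feature, mapping in raw.items():
        missing = set(ALL_PENTAMERS) - set(mapping)
        if missing:
            raise ValueError(
                f"{path}: feature {feature!r} missing {len(missing)} pentamers"
            )
        values[feature] = np.array([mapping[p] for p in ALL_PENTAMERS])
    resolution = {f: SHAPE_FEATURES.get(f, "bp") for f in values}
    return ShapeTable(values=values, resolution=resolution)


def write_shape_table(table: ShapeTable, path) -> None:
    with open(path, "w") as fh:
        for feature in table.feature_names:
            for pentamer, value in zip(ALL_PENTAMERS, table.values[feature]):
                fh.write(f"{pentamer}\t{feature}\t{value:.6f}\n")
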