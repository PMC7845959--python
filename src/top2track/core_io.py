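"""Shared genomic data model and plain-text format I/O.

Coordinates are 0-based half-open (BED native) everywhere inside the
package; any 1-based input is converted at the reader boundary.  Strand is
ignored throughout: all scoring and sequence encodings operate on the
forward genome strand.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import numpy as np
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "Genome",
    "ReadLibrary",
    "MethylationTable",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "write_bedgraph",
    "read_bedgraph",
    "read_methylation",
    "write_methylation",
    "complement_intervals",
]

_VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self!r}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def sort_key(self) -> Tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


class IntervalSet:
    """An ordered, overlap-queryable collection of :class:`GenomicInterval`.

    Intervals are kept sorted by (chrom, start, end).  Overlap queries use a
    per-chromosome interval tree built lazily on first use.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._intervals: List[GenomicInterval] = sorted(
            intervals, key=GenomicInterval.sort_key
        )
        self._trees: Optional[Dict[str, IntervalTree]] = None

    @classmethod
    def from_ordered(cls, intervals: Iterable[GenomicInterval]) -> "IntervalSet":
        """Build a set that preserves the given interval order.

        Used where row order carries meaning (e.g. labeled training
        regions); overlap queries are unaffected.
        """
        obj = cls.__new__(cls)
        obj._intervals = list(intervals)
        obj._trees = None
        return obj

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self._intervals)

    def __getitem__(self, i: int) -> GenomicInterval:
        return self._intervals[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._intervals == other._intervals

    def __repr__(self) -> str:
        return f"IntervalSet(n={len(self)})"

    # -- queries ------------------------------------------------------------------
    @property
    def chroms(self) -> List[str]:
        return sorted({iv.chrom for iv in self._intervals})

    def by_chrom(self, chrom: str) -> List[GenomicInterval]:
        return [iv for iv in self._intervals if iv.chrom == chrom]

    def counts_per_chrom(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for iv in self._intervals:
            out[iv.chrom] = out.get(iv.chrom, 0) + 1
        return out

    def _ensure_trees(self) -> Dict[str, IntervalTree]:
        if self._trees is None:
            trees: Dict[str, IntervalTree] = {}
            for idx, iv in enumerate(self._intervals):
                trees.setdefault(iv.chrom, IntervalTree()).addi(
                    iv.start, iv.end, idx
                )
            self._trees = trees
        return self._trees

    def find_overlaps(self, query: GenomicInterval) -> List[GenomicInterval]:
        """All stored intervals overlapping ``query`` by >= 1 bp."""
        trees = self._ensure_trees()
        tree = trees.get(query.chrom)
        if tree is None:
            return []
        hits = sorted(tree.overlap(query.start, query.end), key=lambda h: h.data)
        return [self._intervals[h.data] for h in hits]

    def overlaps_any(self, query: GenomicInterval) -> bool:
        trees = self._ensure_trees()
        tree = trees.get(query.chrom)
        return bool(tree is not None and tree.overlaps(query.start, query.end))

    def overlap_bases(self, query: GenomicInterval) -> int:
        """Number of bases of ``query`` covered by the union of this set."""
        hits = self.find_overlaps(query)
        if not hits:
            return 0
        segs = sorted(
            (max(h.start, query.start), min(h.end, query.end)) for h in hits
        )
        covered = 0
        cur_s, cur_e = segs[0]
        for s, e in segs[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s
        return covered

    def intersecting(self, other: "IntervalSet") -> "IntervalSet":
        """Members of *this* set that overlap >= 1 bp with some member of ``other``."""
        return IntervalSet(iv for iv in self._intervals if other.overlaps_any(iv))

    def merge(self) -> "IntervalSet":
        """Union of the set: overlapping or book-ended intervals merged."""
        merged: List[GenomicInterval] = []
        for iv in sorted(self._intervals, key=GenomicInterval.sort_key):
            if (
                merged
                and merged[-1].chrom == iv.chrom
                and iv.start <= merged[-1].end
            ):
                last = merged[-1]
                merged[-1] = GenomicInterval(
                    last.chrom, last.start, max(last.end, iv.end)
                )
            else:
                merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
        return IntervalSet(merged)


@dataclass
class Genome:
    """Uppercase DNA sequences over {A, C, G, T, N}, keyed by chromosome."""

    sequences: Dict[str, str]

    def __post_init__(self) -> None:
        for chrom, seq in self.sequences.items():
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ValueError(
                    f"non-IUPAC characters {sorted(bad)} in chromosome {chrom}"
                )

    @property
    def lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def fetch(self, interval: GenomicInterval) -> str:
        seq = self.sequences.get(interval.chrom)
        if seq is None:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > len(seq):
            raise ValueError(
                f"{interval.chrom}:{interval.start}-{interval.end} exceeds "
                f"chromosome length {len(seq)}"
            )
        return seq[interval.start : interval.end]

    def validate(self, interval: GenomicInterval) -> None:
        self.fetch(interval)


class ReadLibrary:
    """Single-end alignment intervals plus the declared mapped-read count.

    ``library_size`` defaults to the number of stored reads; a larger declared
    size is allowed (sub-sampled storage).  Per-chromosome sorted start/end
    arrays support O(log n) window counting.
    """

    def __init__(self, reads: IntervalSet, library_size: Optional[int] = None):
        self.reads = reads
        self.library_size = len(reads) if library_size is None else int(library_size)
        if self.library_size <= 0 and len(reads) > 0:
            raise ValueError("library_size must be positive")
        if self.library_size < len(reads):
            raise ValueError("library_size smaller than number of stored reads")
        self._starts: Dict[str, np.ndarray] = {}
        self._ends: Dict[str, np.ndarray] = {}
        for chrom in reads.chroms:
            ivs = reads.by_chrom(chrom)
            self._starts[chrom] = np.sort(np.array([iv.start for iv in ivs]))
            self._ends[chrom] = np.sort(np.array([iv.end for iv in ivs]))

    def __len__(self) -> int:
        return len(self.reads)

    def count_in(self, chrom: str, starts: np.ndarray, ends: np.ndarray) -> np.ndarray:
        """Vectorized any-overlap read counts for windows on one chromosome."""
        s = self._starts.get(chrom)
        if s is None:
            return np.zeros(len(starts), dtype=int)
        e = self._ends[chrom]
        # overlap <=> read.start < w.end and read.end > w.start
        n_start_before = np.searchsorted(s, ends, side="left")
        n_end_at_or_before = np.searchsorted(e, starts, side="right")
        return n_start_before - n_end_at_or_before


class MethylationTable:
    """Per-CpG percent methylation: (chrom, 0-based C position, % in [0, 100])."""

    def __init__(self, records: Iterable[Tuple[str, int, float]]):
        per_chrom: Dict[str, List[Tuple[int, float]]] = {}
        for chrom, pos, pct in records:
            if not (0.0 <= pct <= 100.0):
                raise ValueError(f"percent out of [0, 100]: {pct} at {chrom}:{pos}")
            per_chrom.setdefault(chrom, []).append((int(pos), float(pct)))
        self._pos: Dict[str, np.ndarray] = {}
        self._pct: Dict[str, np.ndarray] = {}
        self._n = 0
        for chrom, rows in per_chrom.items():
            rows.sort()
            pos = np.array([r[0] for r in rows])
            if len(np.unique(pos)) != len(pos):
                raise ValueError(f"duplicate CpG positions on {chrom}")
            self._pos[chrom] = pos
            self._pct[chrom] = np.array([r[1] for r in rows])
            self._n += len(rows)

    def __len__(self) -> int:
        return self._n

    def in_window(self, interval: GenomicInterval) -> np.ndarray:
        """Percent values of CpGs whose C position lies inside the window."""
        pos = self._pos.get(interval.chrom)
        if pos is None:
            return np.empty(0)
        lo = np.searchsorted(pos, interval.start, side="left")
        hi = np.searchsorted(pos, interval.end, side="left")
        return self._pct[interval.chrom][lo:hi]

    def iter_records(self) -> Iterator[Tuple[str, int, float]]:
        for chrom in sorted(self._pos):
            for pos, pct in zip(self._pos[chrom], self._pct[chrom]):
                yield chrom, int(pos), float(pct)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_bed(path) -> IntervalSet:
    """Read a BED3/BED6-style file into an :class:`IntervalSet`.

    Columns 4 and 5, when present, map to ``name`` and ``score``.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated columns"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ValueError(f"{path}: line {lineno}: {exc}") from None
            try:
                intervals.append(GenomicInterval(chrom, start, end, name, score))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return IntervalSet(intervals)


def write_bed(intervals: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None:
                fields.append(iv.name if iv.name is not None else ".")
            if iv.score is not None:
                fields.append(repr(iv.score))
            fh.write("\t".join(fields) + "\n")


def read_fasta(path) -> Genome:
    """Read a FASTA file into a :class:`Genome` (sequences uppercased)."""
    sequences: Dict[str, List[str]] = {}
    current: Optional[str] = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                if current in sequences:
                    raise ValueError(f"duplicate FASTA header: {current!r}")
                sequences[current] = []
            else:
                if current is None:
                    raise ValueError("sequence data before first FASTA header")
                sequences[current].append(line.upper())
    if not sequences:
        raise ValueError(f"no sequences found in {path}")
    return Genome({c: "".join(parts) for c, parts in sequences.items()})


def write_fasta(genome: Genome, path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome.sequences):
            fh.write(f">{chrom}\n")
            for chunk in textwrap.wrap(genome.sequences[chrom], width):
                fh.write(chunk + "\n")


def write_bedgraph(track, path) -> None:
    """Serialize a probability track as a 4-column bedGraph (6-decimal values).

    ``track`` is any object with sorted ``windows`` (IntervalSet) and
    ``probs`` (sequence of non-negative floats).  Raises if windows are not
    sorted by (chrom, start).
    """
    windows = list(track.windows)
    keys = [iv.sort_key() for iv in windows]
    if keys != sorted(keys):
        raise ValueError("track windows must be sorted by (chrom, start, end)")
    probs = np.asarray(track.probs, dtype=float)
    if len(probs) != len(windows):
        raise ValueError("probs length does not match window count")
    if np.any(probs < 0):
        raise ValueError("bedGraph values must be non-negative")
    with open(path, "w") as fh:
        for iv, p in zip(windows, probs):
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p:.6f}\n")


def read_bedgraph(path) -> Tuple[IntervalSet, np.ndarray]:
    intervals = []
    values = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ValueError(f"{path}: line {lineno}: expected 4 columns")
            intervals.append(
                GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            )
            values.append(float(fields[3]))
    return IntervalSet(intervals), np.array(values)


def read_methylation(path, one_based: bool = False) -> MethylationTable:
    """Read a methylation TSV (chrom, position, percent methylated).

    Bisulfite callers commonly report 1-based positions; pass
    ``one_based=True`` to convert at this boundary.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            pos = int(fields[1]) - (1 if one_based else 0)
            records.append((fields[0], pos, float(fields[2])))
    return MethylationTable(records)


def write_methylation(table: MethylationTable, path) -> None:
    with open(path, "w") as fh:
        for chrom, pos, pct in table.iter_records():
            fh.write(f"{chrom}\t{pos}\t{pct:.4f}\n")


def complement_intervals(intervals: IntervalSet, genome: Genome) -> IntervalSet:
    """Genomic complement of a set (e.g. mappable regions -> non-mappable)."""
    merged = intervals.merge()
    out = []
    for chrom, length in genome.lengths.items():
        cursor = 0
        for iv in merged.by_chrom(chrom):
            if iv.start > cursor:
                out.append(GenomicInterval(chrom, cursor, iv.start))
            cursor = max(cursor, iv.end)
        if cursor < length:
            out.append(GenomicInterval(chrom, cursor, length))
    return IntervalSet(out)
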