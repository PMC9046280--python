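"""Genomic intervals, the fractional-overlap predicate, and peak-set algebra.

All coordinates are 0-based half-open (BED convention). Two peaks are deemed
overlapping when the overlapping stretch exceeds a fraction (default 50%) of
the length of *either* peak — the inclusive reading, i.e. it is enough that at
least one of the two peaks is mostly covered. A stricter reciprocal variant
("both") is available behind the ``mode`` switch.

Peak sets can be partitioned into shared/unique regions against another set,
or profiled for membership across several sets at once; both operations return
deterministically ordered output (chromosome lexicographic, then start, then
end).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

from .errors import DataFormatError, UsageError

__all__ = [
    "GenomicInterval",
    "PeakSet",
    "SetPartition",
    "overlap_length",
    "peaks_overlap",
    "partition_sets",
    "multiway_membership",
    "center_window",
    "read_bed",
    "write_bed",
    "read_narrowpeak",
    "write_narrowpeak",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """One peak or window on a chromosome, 0-based half-open.

    ``summit_offset`` is the offset of the point of maximal signal from
    ``start`` (narrowPeak column 10); ``None`` means no summit was called and
    the midpoint is used as the peak center.
    """

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    score: float | None = field(default=None, compare=False)
    strand: str = field(default=".", compare=False)
    summit_offset: int | None = field(default=None, compare=False)
    # narrowPeak signalValue/pValue/qValue kept verbatim for round-tripping
    extra: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise UsageError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise UsageError(f"invalid strand {self.strand!r}")
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise UsageError(
                f"summit offset {self.summit_offset} outside interval of "
                f"length {self.end - self.start}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        """Peak center: the summit when called, else the floor midpoint."""
        if self.summit_offset is not None:
            return self.start + self.summit_offset
        return (self.start + self.end) // 2


class PeakSet:
    """A labelled collection of intervals, queryable per chromosome."""

    def __init__(self, label: str, intervals: Iterable[GenomicInterval] = ()):
        self.label = label
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=_sort_key
        )
        self._trees: dict[str, IntervalTree] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def _tree(self, chrom: str) -> IntervalTree | None:
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for iv in self.intervals:
                trees.setdefault(iv.chrom, IntervalTree()).addi(
                    iv.start, iv.end, iv
                )
            self._trees = trees
        return self._trees.get(chrom)

    def overlapping(
        self, iv: GenomicInterval, min_frac: float = 0.5, mode: str = "either"
    ) -> list[GenomicInterval]:
        """All members satisfying :func:`peaks_overlap` with ``iv``."""
        tree = self._tree(iv.chrom)
        if tree is None:
            return []
        hits = [
            node.data
            for node in tree.overlap(iv.start, iv.end)
            if peaks_overlap(iv, node.data, min_frac, mode=mode)
        ]
        return sorted(hits, key=_sort_key)

    def any_overlap(
        self, iv: GenomicInterval, min_frac: float = 0.5, mode: str = "either"
    ) -> bool:
        tree = self._tree(iv.chrom)
        if tree is None:
            return False
        return any(
            peaks_overlap(iv, node.data, min_frac, mode=mode)
            for node in tree.overlap(iv.start, iv.end)
        )


@dataclass
class SetPartition:
    """Unique/shared split of two peak sets under the overlap rule."""

    unique_a: list[GenomicInterval]
    unique_b: list[GenomicInterval]
    shared_a: list[GenomicInterval]
    shared_b: list[GenomicInterval]


def _sort_key(iv: GenomicInterval) -> tuple[str, int, int]:
    return (iv.chrom, iv.start, iv.end)


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length in bp of the overlap of ``a`` and ``b`` (0 if disjoint)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def _check_min_frac(min_frac: float) -> None:
    if not (0.0 < min_frac <= 1.0):
        raise UsageError(f"min_frac must be in (0, 1], got {min_frac}")


def peaks_overlap(
    a: GenomicInterval,
    b: GenomicInterval,
    min_frac: float = 0.5,
    mode: str = "either",
) -> bool:
    """Fractional-overlap predicate between two peaks.

    ``mode='either'`` (default): the overlap must strictly exceed ``min_frac``
    of the length of at least one of the two peaks. ``mode='both'``: it must
    exceed that fraction of each peak (reciprocal overlap).
    """
    _check_min_frac(min_frac)
    if mode not in ("either", "both"):
        raise UsageError(f"mode must be 'either' or 'both', got {mode!r}")
    ovl = overlap_length(a, b)
    if ovl == 0:
        return False
    over_a = ovl > min_frac * len(a)
    over_b = ovl > min_frac * len(b)
    return (over_a or over_b) if mode == "either" else (over_a and over_b)


def partition_sets(
    a: PeakSet, b: PeakSet, min_frac: float = 0.5, mode: str = "either"
) -> SetPartition:
    """Split ``a`` and ``b`` into shared and unique intervals.

    An interval of A is *shared* iff it overlaps (per :func:`peaks_overlap`)
    at least one interval of B, else *unique*; symmetrically for B. The four
    output lists are sorted (chrom, start, end).
    """
    _check_min_frac(min_frac)
    unique_a, shared_a = [], []
    for iv in a:
        (shared_a if b.any_overlap(iv, min_frac, mode) else unique_a).append(iv)
    unique_b, shared_b = [], []
    for iv in b:
        (shared_b if a.any_overlap(iv, min_frac, mode) else unique_b).append(iv)
    return SetPartition(unique_a, unique_b, shared_a, shared_b)


def multiway_membership(
    sets: Sequence[PeakSet], min_frac: float = 0.5, mode: str = "either"
) -> list[tuple[int, GenomicInterval, tuple[bool, ...]]]:
    """Overlap profile of every interval against every set.

    Returns one record per interval of each input set: the index of the set
    the interval belongs to, the interval, and a boolean vector over all sets
    (reflexive membership is always True). Enables region-style groupings
    across three or more conditions.
    """
    if len(sets) < 2:
        raise UsageError("multiway_membership requires at least 2 peak sets")
    _check_min_frac(min_frac)
    out = []
    for i, ps in enumerate(sets):
        for iv in ps:
            profile = tuple(
                True if j == i else other.any_overlap(iv, min_frac, mode)
                for j, other in enumerate(sets)
            )
            out.append((i, iv, profile))
    return out


def center_window(
    iv: GenomicInterval, flank: int, chrom_length: int
) -> GenomicInterval:
    """Window of ±``flank`` bp around the peak center, clipped to the chromosome.

    The nominal window is ``[c - flank, c + flank)`` where ``c`` is the summit
    (when called) or floor midpoint; it is truncated at position 0 and at
    ``chrom_length``.
    """
    if flank <= 0:
        raise UsageError(f"flank must be positive, got {flank}")
    if chrom_length <= 0:
        raise UsageError(f"chrom_length must be positive, got {chrom_length}")
    c = iv.center
    start = max(0, c - flank)
    end = min(chrom_length, c + flank)
    return GenomicInterval(iv.chrom, start, end, name=iv.name)


# ---------------------------------------------------------------------------
# BED6 / ENCODE narrowPeak readers and writers
# ---------------------------------------------------------------------------

def _fmt(value: float | None, default: str = ".") -> str:
    if value is None:
        return default
    if float(value).is_integer():
        return str(int(value))
    return repr(float(value))


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED file (3 to 6 columns) into intervals."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataFormatError(
                    f"{path}:{lineno}: BED line has {len(fields)} fields, "
                    "need at least 3"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                name = fields[3] if len(fields) > 3 else None
                score = (
                    float(fields[4])
                    if len(fields) > 4 and fields[4] != "."
                    else None
                )
                strand = fields[5] if len(fields) > 5 else "."
                out.append(
                    GenomicInterval(chrom, start, end, name, score, strand)
                )
            except (ValueError, UsageError) as exc:
                raise DataFormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(path, intervals: Iterable[GenomicInterval]) -> None:
    """Write intervals as 6-column BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                "\t".join(
                    (
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        iv.name or ".",
                        _fmt(iv.score, "0"),
                        iv.strand,
                    )
                )
                + "\n"
            )


def read_narrowpeak(path) -> list[GenomicInterval]:
    """Read an ENCODE narrowPeak file (10 columns; summit = column 10, -1 = absent)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) != 10:
                raise DataFormatError(
                    f"{path}:{lineno}: narrowPeak line has {len(fields)} "
                    "fields, expected 10"
                )
            try:
                summit = int(fields[9])
                out.append(
                    GenomicInterval(
                        fields[0],
                        int(fields[1]),
                        int(fields[2]),
                        fields[3],
                        float(fields[4]),
                        fields[5],
                        summit if summit >= 0 else None,
                        extra=tuple(fields[6:9]),
                    )
                )
            except (ValueError, UsageError) as exc:
                raise DataFormatError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_narrowpeak(path, intervals: Iterable[GenomicInterval]) -> None:
    """Write intervals as ENCODE narrowPeak."""
    with open(path, "w") as fh:
        for iv in intervals:
            extra = iv.extra if len(iv.extra) == 3 else ("0", "-1", "-1")
            summit = -1 if iv.summit_offset is None else iv.summit_offset
            fh.write(
                "\t".join(
                    (
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        iv.name or ".",
                        _fmt(iv.score, "0"),
                        iv.strand,
                        *extra,
                        str(summit),
                    )
                )
                + "\n"
            )
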