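"""Genomic interval primitives: coordinates, mask tracks, set arithmetic.

All coordinates are 0-based half-open throughout the package; conversion to
1-based conventions (Bismark coverage, VCF) happens only at I/O boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on a named sequence."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union: sort and merge overlapping/adjacent intervals per chromosome.

    Strand is dropped (merged intervals are unstranded).
    """
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in by_pos:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def intersect_two(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Intersection of two normalized (sorted, merged) interval lists."""
    out: list[GenomicInterval] = []
    a = sorted(a, key=lambda iv: (iv.chrom, iv.start))
    b = sorted(b, key=lambda iv: (iv.chrom, iv.start))
    i = j = 0
    while i < len(a) and j < len(b):
        x, y = a[i], b[j]
        if x.chrom != y.chrom:
            if x.chrom < y.chrom:
                i += 1
            else:
                j += 1
            continue
        lo = max(x.start, y.start)
        hi = min(x.end, y.end)
        if lo < hi:
            out.append(GenomicInterval(x.chrom, lo, hi))
        if x.end <= y.end:
            i += 1
        else:
            j += 1
    return out


def total_bases(intervals: Iterable[GenomicInterval]) -> int:
    return sum(iv.length for iv in merge_intervals(intervals))


@dataclass
class MaskTrack:
    """A named set of masked intervals, normalized (sorted, non-overlapping)."""

    name: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)

    @property
    def total_bases(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def overlap_bases(self, interval: GenomicInterval) -> int:
        """Number of bases of ``interval`` covered by this track."""
        return sum(interval.overlap_length(iv) for iv in self.intervals)

    def contains(self, other: "MaskTrack") -> bool:
        """True if every base of ``other`` is masked by this track."""
        inter = intersect_two(self.intervals, other.intervals)
        return sum(iv.length for iv in inter) == other.total_bases
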