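"""Genomic interval primitives.

All coordinates are 0-based half-open ``[start, end)`` on a named
chromosome; strand is ``+``, ``-`` or ``.`` (unstranded). These objects are
the substrate of every overlap, merge and coverage computation in the
package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

STRANDS = frozenset({"+", "-", "."})


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        ``+``, ``-`` or ``.``.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", ignore_strand: bool = True) -> bool:
        """True iff the two intervals share >= 1 bp.

        Half-open convention: abutting intervals do not overlap.
        """
        if self.chrom != other.chrom:
            return False
        if not ignore_strand and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a sorted list of disjoint intervals.

    Strand and chromosome are preserved only when uniform; intervals from
    several chromosomes are merged per chromosome.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_start, cur_end, cur_strand = ivs[0].start, ivs[0].end, ivs[0].strand
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # touching intervals collapse in a union
                cur_end = max(cur_end, iv.end)
                if iv.strand != cur_strand:
                    cur_strand = "."
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end, cur_strand))
                cur_start, cur_end, cur_strand = iv.start, iv.end, iv.strand
        merged.append(GenomicInterval(chrom, cur_start, cur_end, cur_strand))
    return merged


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    """Total base pairs in the union of the intervals."""
    return sum(iv.length for iv in merge_intervals(intervals))


def intersect_length(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> int:
    """Base pairs in union(a) ∩ union(b); strand-ignorant."""
    ma, mb = merge_intervals(a), merge_intervals(b)
    out = 0
    for x in ma:
        for y in mb:
            if x.chrom != y.chrom:
                continue
            lo = max(x.start, y.start)
            hi = min(x.end, y.end)
            if lo < hi:
                out += hi - lo
    return out
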