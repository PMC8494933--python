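"""Genomic intervals and the small set of interval operations the pipeline needs.

All coordinates follow BED conventions: 0-based, half-open ``[start, end)``.
Two intervals overlap iff they share at least one base, i.e.
``a.start < b.end and b.start < a.end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: {self.chrom}:{self.start}-{self.end}")
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def union(self, other: "GenomicInterval") -> "GenomicInterval":
        if self.chrom != other.chrom:
            raise ValueError("cannot union intervals on different chromosomes")
        return GenomicInterval(
            self.chrom, min(self.start, other.start), max(self.end, other.end)
        )

    def with_name(self, name: str) -> "GenomicInterval":
        return replace(self, name=name)


def sort_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(
    intervals: Iterable[GenomicInterval], gap: int = 0
) -> list[GenomicInterval]:
    """Merge intervals whose gap is ``<= gap`` bases (0 = touching/overlapping)."""
    ivs = sort_intervals(intervals)
    if not ivs:
        return []
    merged: list[GenomicInterval] = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.chrom == last.chrom and iv.start - last.end <= gap:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def any_overlap(
    iv: GenomicInterval, others: Sequence[GenomicInterval]
) -> bool:
    return any(iv.overlaps(o) for o in others)


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene annotation: strand-aware TSS/TES on a chromosome.

    ``tss``/``tes`` are genomic coordinates; for ``-`` strand genes the TSS is
    the larger coordinate.
    """

    gene: str
    chrom: str
    tss: int
    tes: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene}: strand must be + or -")

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)

    def promoter(self, flank: int) -> GenomicInterval:
        """Promoter window [TSS - flank, TSS + flank)."""
        return GenomicInterval(
            self.chrom, max(0, self.tss - flank), self.tss + flank,
            name=self.gene, strand=self.strand,
        )

    def association_window(self, upstream: int) -> GenomicInterval:
        """Strand-aware window from ``upstream`` bp before the TSS to the TES."""
        if self.strand == "+":
            lo, hi = self.tss - upstream, max(self.tes, self.tss + 1)
        else:
            lo, hi = min(self.tes, self.tss), self.tss + upstream
        return GenomicInterval(self.chrom, max(0, lo), hi, name=self.gene,
                               strand=self.strand)


def promoters(genes: Iterable[GeneModel], flank: int) -> list[GenomicInterval]:
    return [g.promoter(flank) for g in genes]
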