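"""Genomic interval primitives.

Coordinates are 0-based half-open (BED convention) throughout the package;
1-based inputs (GTF-style gene tables) are converted on read.  Chromosome
names are compared by exact string match — no "chr" aliasing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "RegionSet",
    "GeneModel",
    "normalize",
    "width_stats",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open, 0-based span on one chromosome.

    ``extra`` keeps any trailing columns of a narrowPeak/BED record verbatim
    so that files round-trip; it never participates in equality of coordinates.
    """

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: Optional[str] = None
    extra: tuple = field(default=(), compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be a non-empty string")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start >= self.end:
            raise ValueError(
                f"start must be < end, got [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand is not None and self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of +, -, . — got {self.strand!r}")

    @property
    def width(self) -> int:
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

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end)


@dataclass
class RegionSet:
    """A labelled collection of intervals, e.g. the peak set of one stage."""

    stage: str
    intervals: list[GenomicInterval]
    normalized: bool = False

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def total_bases(self) -> int:
        if self.normalized:
            return sum(iv.width for iv in self.intervals)
        return sum(iv.width for iv in normalize(self).intervals)


def normalize(regions: RegionSet) -> RegionSet:
    """Sort and merge a region set.

    Overlapping or book-ended (touching) intervals on the same chromosome are
    merged into one; the total number of covered bases is unchanged.  Names,
    scores and extra columns are dropped from merged records.
    """
    if regions.normalized:
        return regions
    ivs = sorted(regions.intervals, key=GenomicInterval.key)
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = replace(merged[-1], end=iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return RegionSet(stage=regions.stage, intervals=merged, normalized=True)


def width_stats(intervals: Sequence[GenomicInterval] | Iterable[GenomicInterval]) -> dict:
    """Summary of interval widths: n, median, mean, min, max.

    The median of an even-length list is the mean of the two central values.
    Raises ``ValueError`` on an empty list.
    """
    widths = sorted(iv.width for iv in intervals)
    n = len(widths)
    if n == 0:
        raise ValueError("width_stats requires a non-empty interval list")
    mid = n // 2
    median = float(widths[mid]) if n % 2 else (widths[mid - 1] + widths[mid]) / 2.0
    return {
        "n": n,
        "median_width": median,
        "mean_width": sum(widths) / n,
        "min": widths[0],
        "max": widths[-1],
    }


@dataclass
class GeneModel:
    """A gene with TSS, body span and exon blocks (0-based half-open).

    For ``+`` strand genes the TSS is ``gene_start``; for ``-`` strand genes it
    is ``gene_end - 1`` (the last covered base).
    """

    gene_id: str
    chrom: str
    strand: str
    gene_start: int
    gene_end: int
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.gene_start >= self.gene_end:
            raise ValueError(f"gene {self.gene_id}: empty span")
        for s, e in self.exons:
            if s < self.gene_start or e > self.gene_end:
                raise ValueError(f"gene {self.gene_id}: exon ({s},{e}) outside gene span")

    @property
    def tss(self) -> int:
        return self.gene_start if self.strand == "+" else self.gene_end - 1

    def body_contains(self, pos: int) -> bool:
        return self.gene_start <= pos < self.gene_end
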