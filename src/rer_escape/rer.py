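"""Persistence intersection: regions covered by every stage's peak set.

A reprogramming-escape region (RER) is a maximal genomic span covered by the
H3K4me3 peak set of *every* surveyed stage — a per-base AND across stages,
split wherever any stage's coverage ends.  Fragment semantics (rather than
reporting whole source peaks on any overlap) is what makes the result set
simultaneously more numerous and narrower than any input set when wide peaks
from one reprogramming window are intersected with narrow peaks from the
other.

The production path is a single boundary sweep per chromosome; the dense
per-base bitmap appears only as a test oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .regions import GenomicInterval, RegionSet, normalize

__all__ = ["RER", "persistence_intersect", "rers_to_region_set"]


@dataclass
class RER:
    """A persistence fragment with per-stage provenance.

    ``supporting`` maps each stage label to the first (by coordinate) source
    interval of that stage covering the fragment.  ``label``, ``feature`` and
    ``genes`` are filled by the annotation step.
    """

    rer_id: str
    interval: GenomicInterval
    supporting: dict[str, GenomicInterval]
    label: Optional[str] = None  # promoter | enhancer
    feature: Optional[str] = None  # TSS | intronic | intergenic
    genes: list[str] = field(default_factory=list)
    me3_mean: Optional[float] = None
    me1_mean: Optional[float] = None


def _fragments_for_chrom(
    per_stage: list[tuple[np.ndarray, np.ndarray]], n_stages: int
) -> list[tuple[int, int]]:
    """Maximal runs covered by all stages, via a boundary sweep."""
    starts = np.concatenate([s for s, _ in per_stage])
    ends = np.concatenate([e for _, e in per_stage])
    points = np.concatenate([starts, ends])
    deltas = np.concatenate([np.ones_like(starts), -np.ones_like(ends)])
    order = np.argsort(points, kind="stable")
    points, deltas = points[order], deltas[order]
    frags: list[tuple[int, int]] = []
    coverage = 0
    run_start = None
    i = 0
    n = len(points)
    while i < n:
        pos = points[i]
        while i < n and points[i] == pos:
            coverage += deltas[i]
            i += 1
        if coverage == n_stages and run_start is None:
            run_start = int(pos)
        elif coverage < n_stages and run_start is not None:
            frags.append((run_start, int(pos)))
            run_start = None
    return frags


def _first_source(
    originals_starts: np.ndarray,
    originals_ends: np.ndarray,
    originals: list[GenomicInterval],
    frag_start: int,
    frag_end: int,
) -> GenomicInterval:
    """First-by-coordinate source interval overlapping the fragment."""
    hi = int(np.searchsorted(originals_starts, frag_end, side="left"))
    idx = np.nonzero(originals_ends[:hi] > frag_start)[0]
    return originals[int(idx[0])]


def persistence_intersect(
    stage_sets: Sequence[RegionSet], min_width: int = 1
) -> list[RER]:
    """Intersect N stage peak sets into disjoint, sorted persistence fragments.

    Each output fragment is covered by every stage; fragments shorter than
    ``min_width`` are discarded.  Provenance records, per stage, the first
    source interval (by coordinate, pre-normalization) overlapping the
    fragment.  The operation is commutative and associative in the stage sets.
    """
    if len(stage_sets) == 0:
        raise ValueError("persistence_intersect requires at least one stage set")
    if min_width < 1:
        raise ValueError("min_width must be >= 1")
    n_stages = len(stage_sets)
    normalized = [normalize(rs) for rs in stage_sets]

    # chromosomes present in every stage
    chrom_sets = [set(iv.chrom for iv in rs.intervals) for rs in normalized]
    common = sorted(set.intersection(*chrom_sets)) if chrom_sets else []

    # per stage, per chromosome: normalized arrays + sorted originals
    originals_by_stage: list[dict[str, tuple]] = []
    norm_by_stage: list[dict[str, tuple[np.ndarray, np.ndarray]]] = []
    for rs, raw in zip(normalized, stage_sets):
        norm_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom in common:
            ivs = [iv for iv in rs.intervals if iv.chrom == chrom]
            norm_chrom[chrom] = (
                np.array([iv.start for iv in ivs], dtype=np.int64),
                np.array([iv.end for iv in ivs], dtype=np.int64),
            )
        norm_by_stage.append(norm_chrom)
        orig_chrom: dict[str, tuple] = {}
        for chrom in common:
            ivs = sorted(
                (iv for iv in raw.intervals if iv.chrom == chrom),
                key=GenomicInterval.key,
            )
            orig_chrom[chrom] = (
                np.array([iv.start for iv in ivs], dtype=np.int64),
                np.array([iv.end for iv in ivs], dtype=np.int64),
                ivs,
            )
        originals_by_stage.append(orig_chrom)

    rers: list[RER] = []
    for chrom in common:
        per_stage = [norm_by_stage[k][chrom] for k in range(n_stages)]
        if any(len(s) == 0 for s, _ in per_stage):
            continue
        for frag_start, frag_end in _fragments_for_chrom(per_stage, n_stages):
            if frag_end - frag_start < min_width:
                continue
            supporting = {}
            for k, rs in enumerate(stage_sets):
                o_starts, o_ends, o_ivs = originals_by_stage[k][chrom]
                supporting[rs.stage] = _first_source(
                    o_starts, o_ends, o_ivs, frag_start, frag_end
                )
            rers.append(
                RER(
                    rer_id="",
                    interval=GenomicInterval(chrom, frag_start, frag_end),
                    supporting=supporting,
                )
            )
    rers.sort(key=lambda r: r.interval.key())
    for i, r in enumerate(rers):
        r.rer_id = f"RER_{i + 1:05d}"
        r.interval = GenomicInterval(
            r.interval.chrom,
            r.interval.start,
            r.interval.end,
            name=r.rer_id,
            score=float(r.interval.width),
        )
    return rers


def rers_to_region_set(rers: Sequence[RER], stage: str = "RER") -> RegionSet:
    """The RER fragments as a plain region set (disjoint + sorted = normalized)."""
    return RegionSet(
        stage=stage,
        intervals=[r.interval for r in rers],
        normalized=True,
    )
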