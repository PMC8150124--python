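"""Promoter/enhancer classification, feature assignment and TSS profiles.

A region is a presumptive promoter when its mean H3K4me3 intensity exceeds
its mean H3K4me1 intensity, and a presumptive enhancer in the reverse case;
equal intensities default to promoter because the regions are defined by
H3K4me3 presence in the first place.  Feature assignment uses the region
midpoint (TSS-proximal within a +/-1 kb window, else gene body, else
intergenic) so that categories partition any region set; gene association
uses any-overlap with the TSS window to maximize recall.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .regions import GeneModel, GenomicInterval, RegionSet
from .rer import RER
from .tracks import CoverageTrack

__all__ = [
    "AnnotationConfig",
    "mean_signal",
    "classify_promoter_enhancer",
    "assign_feature",
    "associate_genes",
    "feature_proportion_table",
    "tss_profile",
]


@dataclass
class AnnotationConfig:
    tss_window: int = 1000
    me3_track: Optional[CoverageTrack] = None
    me1_track: Optional[CoverageTrack] = None
    tie_label: str = "promoter"
    profile_bin: int = 50
    bootstrap_resamples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tss_window <= 0:
            raise ValueError("tss_window must be positive")
        if (2 * self.tss_window) % self.profile_bin != 0:
            raise ValueError("profile_bin must divide 2 * tss_window")
        if self.tie_label not in ("promoter", "enhancer"):
            raise ValueError("tie_label must be 'promoter' or 'enhancer'")


def mean_signal(region: GenomicInterval, track: CoverageTrack) -> float:
    """Length-weighted mean of the track over the region; uncovered bases are 0."""
    return track.mean_over(region.chrom, region.start, region.end)


def classify_promoter_enhancer(rer: RER, cfg: AnnotationConfig) -> str:
    """Label a region promoter/enhancer by comparing me3 vs me1 mean intensity.

    The comparison is scale-equivariant: multiplying both tracks by the same
    positive constant never changes a label.  Ties take ``cfg.tie_label``.
    """
    if cfg.me3_track is None or cfg.me1_track is None:
        raise ValueError("classification requires both me3 and me1 tracks")
    me3 = mean_signal(rer.interval, cfg.me3_track)
    me1 = mean_signal(rer.interval, cfg.me1_track)
    if me3 > me1:
        label = "promoter"
    elif me1 > me3:
        label = "enhancer"
    else:
        label = cfg.tie_label
    rer.label, rer.me3_mean, rer.me1_mean = label, me3, me1
    return label


def _in_tss_window(pos: int, gene: GeneModel, window: int) -> bool:
    return abs(pos - gene.tss) <= window


def assign_feature(rer: RER, genes: Sequence[GeneModel], cfg: AnnotationConfig) -> str:
    """TSS if the midpoint is within the window of any TSS; else intronic
    (gene body) if inside any gene; else intergenic."""
    mid = rer.interval.midpoint
    chrom = rer.interval.chrom
    feature = "intergenic"
    for g in genes:
        if g.chrom == chrom and _in_tss_window(mid, g, cfg.tss_window):
            feature = "TSS"
            break
    else:
        for g in genes:
            if g.chrom == chrom and g.body_contains(mid):
                feature = "intronic"
                break
    rer.feature = feature
    return feature


def _tss_distance(iv: GenomicInterval, tss: int) -> int:
    if iv.start <= tss < iv.end:
        return 0
    return min(abs(tss - iv.start), abs(tss - (iv.end - 1)))


def associate_genes(
    rers: Sequence[RER], genes: Sequence[GeneModel], cfg: AnnotationConfig
) -> tuple[dict[str, list[str]], list[str]]:
    """Associate a gene with a region when the region overlaps the closed
    window [tss - w, tss + w].

    Many-to-many; per region, genes are sorted by distance to the TSS then by
    id.  Returns the per-region mapping and the deduplicated gene universe
    (sorted).
    """
    w = cfg.tss_window
    mapping: dict[str, list[str]] = {}
    universe: set[str] = set()
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for rer in rers:
        iv = rer.interval
        matches = []
        for g in by_chrom.get(iv.chrom, []):
            if iv.start <= g.tss + w and iv.end - 1 >= g.tss - w:
                matches.append((_tss_distance(iv, g.tss), g.gene_id))
        matches.sort()
        gene_ids = [gid for _, gid in matches]
        mapping[rer.rer_id] = gene_ids
        rer.genes = gene_ids
        universe.update(gene_ids)
    return mapping, sorted(universe)


def feature_proportion_table(
    region_sets: Sequence[RegionSet],
    genes: Sequence[GeneModel],
    cfg: AnnotationConfig,
) -> pd.DataFrame:
    """Per set: count of regions whose midpoint lies within the TSS window of
    any gene, vs outside.  Feeds the chi-square homogeneity test."""
    if len(region_sets) < 2:
        raise ValueError("need at least two region sets to compare")
    by_chrom: dict[str, list[int]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g.tss)
    tss_arr = {c: np.sort(np.array(v, dtype=np.int64)) for c, v in by_chrom.items()}
    rows = []
    for rs in region_sets:
        within = 0
        for iv in rs.intervals:
            arr = tss_arr.get(iv.chrom)
            if arr is None or len(arr) == 0:
                continue
            mid = iv.midpoint
            i = int(np.searchsorted(arr, mid))
            near = []
            if i < len(arr):
                near.append(arr[i])
            if i > 0:
                near.append(arr[i - 1])
            if any(abs(mid - t) <= cfg.tss_window for t in near):
                within += 1
        rows.append((rs.stage, within, len(rs.intervals) - within))
    return pd.DataFrame(rows, columns=["set", "within", "outside"]).set_index("set")


def tss_profile(
    rers: Sequence[RER], genes: Sequence[GeneModel], cfg: AnnotationConfig
) -> dict:
    """Mean occupancy profile of regions across [-w, +w] around TSSs.

    Rows are region-TSS pairs (a region overlapping the window of a TSS),
    columns are strand-oriented bins of width ``cfg.profile_bin``; occupancy
    is the covered fraction of each bin.  The confidence band is a percentile
    (2.5, 97.5) bootstrap over row resampling with the config seed.
    """
    w, b = cfg.tss_window, cfg.profile_bin
    n_bins = 2 * w // b
    rows = []
    for rer in rers:
        iv = rer.interval
        for g in genes:
            if g.chrom != iv.chrom:
                continue
            if not (iv.start <= g.tss + w and iv.end - 1 >= g.tss - w):
                continue
            occ = np.zeros(n_bins)
            for bi in range(n_bins):
                r_lo = -w + bi * b  # relative coords, strand-oriented
                if g.strand == "+":
                    g_lo, g_hi = g.tss + r_lo, g.tss + r_lo + b
                else:
                    g_lo, g_hi = g.tss - r_lo - b + 1, g.tss - r_lo + 1
                ov = min(iv.end, g_hi) - max(iv.start, g_lo)
                occ[bi] = max(ov, 0) / b
            rows.append(occ)
    if not rows:
        raise ValueError("no region-TSS pairs within the window")
    matrix = np.vstack(rows)
    mean = matrix.mean(axis=0)
    rng = np.random.default_rng(cfg.seed)
    n = matrix.shape[0]
    boots = np.empty((cfg.bootstrap_resamples, n_bins))
    for i in range(cfg.bootstrap_resamples):
        idx = rng.integers(0, n, size=n)
        boots[i] = matrix[idx].mean(axis=0)
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    centers = np.arange(n_bins) * b - w + b / 2.0
    return {
        "bin_centers": centers,
        "mean": mean,
        "ci_low": lo,
        "ci_high": hi,
        "matrix": matrix,
        "n_pairs": n,
    }
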