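"""End-to-end orchestration: peaks in, annotated persistent regions out.

``run_all`` chains the stages — persistence intersection, promoter/enhancer
classification, feature assignment and gene association, TSS profile and
proportion chi-square, motif scanning with conservation filtering, and the
expression analyses (clustering, with/without-region comparison, moderated
differential expression) — writing every stage output plus a machine-readable
report.  Missing optional inputs (expression, motifs) mark their report
section as skipped rather than aborting.  Every threshold is carried in the
config and logged in the report; none is hard-coded.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .annotation import (
    AnnotationConfig,
    assign_feature,
    associate_genes,
    classify_promoter_enhancer,
    feature_proportion_table,
    tss_profile,
)
from .motifs import conservation_filter, scan_sequence
from .regions import width_stats
from .rer import persistence_intersect, rers_to_region_set
from .stats import (
    ExpressionMatrix,
    chisq_homogeneity,
    cluster_expression,
    de_analysis,
    two_sample_t,
)

__all__ = ["PipelineConfig", "run_all"]


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run.

    ``peaks`` preserves stage order; the first ``n_early_stages`` entries are
    the sperm/early-embryo sets whose intersection gives the early-escape
    regions that the final (all-stage) set is compared against.
    """

    peaks: dict[str, str] = field(default_factory=dict)  # stage -> BED path
    n_early_stages: int = 7
    me3_track: Optional[str] = None
    me1_track: Optional[str] = None
    conservation_track: Optional[str] = None
    genes: Optional[str] = None
    genome: Optional[str] = None
    motifs: Optional[str] = None
    expression_groups: Optional[str] = None
    expression_stages: Optional[str] = None
    group_a: str = "atz"
    group_b: str = "control"

    min_width: int = 1
    tss_window: int = 1000
    profile_bin: int = 50
    bootstrap_resamples: int = 1000
    motif_threshold_p: float = 1e-4
    conservation_threshold: float = 0.70
    fc_threshold: float = 2.0
    fdr_threshold: float = 0.1
    n_clusters: int = 4
    seed: int = 0

    out_dir: str = "rer_out"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            # keep the stage order of `peaks`: it defines the early-stage prefix
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _stage(report: dict, name: str, **payload) -> None:
    report["stages"][name] = payload


def run_all(cfg: PipelineConfig) -> dict:
    """Run the full analysis; returns the report (also written as JSON)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "thresholds": {
            "min_width": cfg.min_width,
            "tss_window": cfg.tss_window,
            "motif_threshold_p": cfg.motif_threshold_p,
            "conservation_threshold": cfg.conservation_threshold,
            "fc_threshold": cfg.fc_threshold,
            "fdr_threshold": cfg.fdr_threshold,
            "n_clusters": cfg.n_clusters,
            "bootstrap_resamples": cfg.bootstrap_resamples,
        },
        "stages": {},
    }

    # ---- persistence intersection -----------------------------------------
    if not cfg.peaks:
        raise ValueError("pipeline aborted at stage 'rers': no peak files configured")
    stage_sets = [rio.read_bed(path, stage=stage) for stage, path in cfg.peaks.items()]
    rers = persistence_intersect(stage_sets, min_width=cfg.min_width)
    rio.write_bed(rers_to_region_set(rers), out / "rers.bed")
    with open(out / "provenance.tsv", "w") as fh:
        fh.write("rer_id\tstage\tsource_chrom\tsource_start\tsource_end\n")
        for r in rers:
            for stage, src in r.supporting.items():
                fh.write(f"{r.rer_id}\t{stage}\t{src.chrom}\t{src.start}\t{src.end}\n")
    rer_ws = width_stats([r.interval for r in rers]) if rers else None
    payload = {"n_rers": len(rers), "width_stats": rer_ws,
               "n_input_records": {rs.stage: len(rs) for rs in stage_sets}}

    early_sets = stage_sets[: cfg.n_early_stages]
    if 0 < cfg.n_early_stages < len(stage_sets):
        early = persistence_intersect(early_sets, min_width=cfg.min_width)
        rio.write_bed(rers_to_region_set(early, stage="early"), out / "early_regions.bed")
        payload["n_early_regions"] = len(early)
        payload["early_width_stats"] = (
            width_stats([r.interval for r in early]) if early else None
        )
    _stage(report, "rers", **payload)

    # ---- annotation --------------------------------------------------------
    genes = rio.read_gene_table(cfg.genes) if cfg.genes else []
    ann_cfg = AnnotationConfig(
        tss_window=cfg.tss_window,
        profile_bin=cfg.profile_bin,
        bootstrap_resamples=cfg.bootstrap_resamples,
        seed=cfg.seed,
    )
    if cfg.me3_track and cfg.me1_track:
        ann_cfg.me3_track = rio.read_bedgraph(cfg.me3_track)
        ann_cfg.me1_track = rio.read_bedgraph(cfg.me1_track)
        for r in rers:
            classify_promoter_enhancer(r, ann_cfg)
        n_prom = sum(1 for r in rers if r.label == "promoter")
        _stage(report, "classify", n_promoters=n_prom, n_enhancers=len(rers) - n_prom,
               promoter_fraction_pct=round(100.0 * n_prom / len(rers), 2) if rers else None)
    else:
        _stage(report, "classify", skipped="me3/me1 tracks not configured")

    if genes:
        for r in rers:
            assign_feature(r, genes, ann_cfg)
        mapping, universe = associate_genes(rers, genes, ann_cfg)
        counts = {f: sum(1 for r in rers if r.feature == f)
                  for f in ("TSS", "intronic", "intergenic")}
        fractions = {f: round(100.0 * c / len(rers), 2) if rers else None
                     for f, c in counts.items()}
        _stage(report, "annotate", feature_counts=counts, feature_pct=fractions,
               n_associated_genes=len(universe))

        table = feature_proportion_table(stage_sets + [rers_to_region_set(rers)], genes, ann_cfg)
        table.to_csv(out / "proportions.tsv", sep="\t")
        chi2, df, p = chisq_homogeneity(table.to_numpy())
        _stage(report, "proportions", chi2=chi2, df=df, p=p)

        try:
            prof = tss_profile(rers, genes, ann_cfg)
            pd.DataFrame(
                {"bin_center": prof["bin_centers"], "mean": prof["mean"],
                 "ci_low": prof["ci_low"], "ci_high": prof["ci_high"]}
            ).to_csv(out / "tss_profile.tsv", sep="\t", index=False)
            _stage(report, "tss_profile", n_pairs=prof["n_pairs"],
                   peak_occupancy=float(prof["mean"].max()))
        except ValueError as exc:
            _stage(report, "tss_profile", skipped=str(exc))
    else:
        mapping, universe = {}, []
        _stage(report, "annotate", skipped="gene table not configured")

    ann_rows = []
    for r in rers:
        ann_rows.append(
            (r.rer_id, r.interval.chrom, r.interval.start, r.interval.end,
             r.label, r.feature, ",".join(r.genes), r.me3_mean, r.me1_mean)
        )
    pd.DataFrame(
        ann_rows,
        columns=["rer_id", "chrom", "start", "end", "label", "feature",
                 "genes", "me3_mean", "me1_mean"],
    ).to_csv(out / "annotation.tsv", sep="\t", index=False)

    # ---- motif scanning -----------------------------------------------------
    if cfg.genome and cfg.motifs:
        fasta = rio.open_fasta(cfg.genome)
        pwms = rio.read_meme_motifs(cfg.motifs)
        coords = {r.rer_id: r.interval for r in rers}
        hits = []
        for r in rers:
            seq = rio.fetch_sequence(fasta, r.interval)
            for pwm in pwms:
                hits.extend(scan_sequence(r.rer_id, seq, pwm, cfg.motif_threshold_p))
        if cfg.conservation_track:
            cons = rio.read_bedgraph(cfg.conservation_track)
            hits = conservation_filter(
                hits, cons, coords, threshold=cfg.conservation_threshold
            )
        pd.DataFrame(
            [(h.region_id, h.motif_id, h.offset, h.strand, h.width, h.score,
              h.p_value, h.mean_conservation, h.retained) for h in hits],
            columns=["region_id", "motif_id", "offset", "strand", "width",
                     "score", "p_value", "mean_conservation", "retained"],
        ).to_csv(out / "motif_hits.tsv", sep="\t", index=False)
        _stage(report, "motifs", n_hits=len(hits),
               n_retained=sum(1 for h in hits if h.retained))
    else:
        _stage(report, "motifs", skipped="genome/motif inputs not configured")

    # ---- expression ---------------------------------------------------------
    if cfg.expression_stages and universe:
        smat = rio.read_expression(cfg.expression_stages)
        in_universe = [g for g in smat.genes if g in set(universe)]
        if len(in_universe) >= cfg.n_clusters:
            clusters = cluster_expression(smat.subset(in_universe), k=cfg.n_clusters)
            pd.Series(clusters, name="cluster").rename_axis("gene_id").to_csv(
                out / "clusters.tsv", sep="\t"
            )
            _stage(report, "clustering", n_genes=len(clusters),
                   k=cfg.n_clusters,
                   cluster_sizes={str(c): int(n) for c, n in
                                  pd.Series(clusters).value_counts().sort_index().items()})
        else:
            _stage(report, "clustering", skipped="fewer associated genes than clusters")
        means = smat.values.mean(axis=1)
        with_r = means[[g in set(universe) for g in smat.genes]]
        without = means[[g not in set(universe) for g in smat.genes]]
        if len(with_r) >= 2 and len(without) >= 2:
            t, p = two_sample_t(with_r, without)
            _stage(report, "with_without_expression", t=t, p=p,
                   mean_with=float(with_r.mean()), mean_without=float(without.mean()))
        else:
            _stage(report, "with_without_expression", skipped="too few genes per side")
    else:
        _stage(report, "clustering", skipped="stage expression not configured")

    if cfg.expression_groups and universe:
        gmat = rio.read_expression(cfg.expression_groups)
        selected = [g for g in gmat.genes if g in set(universe)]
        de = de_analysis(
            gmat.subset(selected), cfg.group_a, cfg.group_b,
            fc_threshold=cfg.fc_threshold, fdr_threshold=cfg.fdr_threshold,
        )
        de.to_csv(out / "de.tsv", sep="\t")
        _stage(report, "de", n_tested=len(de), n_de=int(de["passes"].sum()),
               de_genes=sorted(de.index[de["passes"]].tolist()))
    else:
        _stage(report, "de", skipped="group expression not configured")

    # consistency: labels and features partition the region set
    report["consistency"] = {
        "labels_sum_to_n": all(
            r.label in (None, "promoter", "enhancer") for r in rers
        ),
        "features_sum_to_n": (
            sum(1 for r in rers if r.feature) in (0, len(rers))
        ),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=_jsonable)
    return report


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON serializable: {type(x)}")
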