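"""Self-contained synthetic fixtures with machine-readable planted truth.

The generator emulates the study conditions end to end: nine stage-wise
H3K4me3 peak sets (sperm + six early-embryo stages with wide peaks, median
~2000 bp; two PGC stages with narrow peaks, median ~250 bp), a subset of
planted loci persisting across all stages, decoy loci missing from at least
one stage, paired H3K4me3/H3K4me1 intensity tracks, GC-rich and AT-rich
motif instances written into the genome sequence with per-base conservation,
and expression matrices with planted stage-cluster structure and planted
between-group differential expression.

Every planted truth item is recoverable by its pipeline stage at default
thresholds, by construction: a persistent locus contributes one narrow peak
per core at the final PGC stage, equal to the core exactly, while every
other stage's peak contains the core — so the nine-way per-base AND returns
the core itself.  Decoys are omitted from >= 1 stage and can never survive
the AND.

All randomness flows from the config seed; the same seed yields a
byte-identical bundle.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import io as rio
from .motifs import PWMRecord
from .regions import GeneModel, GenomicInterval
from .stats import ExpressionMatrix

__all__ = [
    "SyntheticConfig",
    "MotifSpec",
    "TruthTable",
    "generate_fixture",
    "summarize_fixture",
    "sp_like_pwm",
    "sry_like_pwm",
]

_BLOCK = 15_000  # bp per placement block; one planted entity per block

EMBRYO_STAGES = ("sperm", "PN5", "2cell_early", "2cell_late", "4cell", "8cell", "ICM")
PGC_STAGES = ("PGC_E11.5", "PGC_E13.5")

EXPRESSION_STAGES = (
    "priSG", "SG_A", "SG_B", "lepSC", "pacSC", "rST", "eST",
    "sperm", "PN5", "2cell_E", "2cell_L", "4cell", "8cell", "ICM",
)


def _sharp_pwm(motif_id: str, consensus: str, dominant: float = 0.85) -> PWMRecord:
    other = (1.0 - dominant) / 3.0
    rows = []
    for ch in consensus:
        row = [other] * 4
        row["ACGT".index(ch)] = dominant
        rows.append(row)
    return PWMRecord(motif_id, np.array(rows))


def sp_like_pwm() -> PWMRecord:
    """A GC-rich, SP-family-style 10-mer (GC-box-like consensus)."""
    return _sharp_pwm("SP_GC", "GGGGCGGGGC")


def sry_like_pwm() -> PWMRecord:
    """An AT-rich, SRY-style 9-mer around the AACAAT core."""
    return _sharp_pwm("SRY_AT", "TAAACAATA")


@dataclass
class MotifSpec:
    pwm: PWMRecord
    n_sites: int
    conservation: float  # per-base score planted over each site span


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic bundle.

    Width regimes follow the two reprogramming windows: embryo-stage peaks
    log-normal around a 2000 bp median, PGC-stage peaks around 250 bp.
    ``loci_core_counts`` fixes how many persistent loci carry 1, 2 or 3
    narrow cores, so wide embryo peaks spanning several PGC cores split into
    several fragments — the mechanism that makes the final set more numerous
    and narrower than the embryo-only set.
    """

    seed: int = 0
    genome: tuple[tuple[str, int], ...] = (("chr1", 1_500_000), ("chr2", 1_500_000))
    stages: tuple[str, ...] = EMBRYO_STAGES + PGC_STAGES
    n_pgc_stages: int = 2

    loci_core_counts: tuple[tuple[int, int], ...] = ((1, 30), (2, 12), (3, 8))
    n_decoys_embryo: int = 10  # omitted from >= 1 sperm/embryo stage
    n_decoys_pgc: int = 5  # present at every embryo stage, omitted from >= 1 PGC stage
    n_background_peaks: int = 40  # per stage, independent placements
    n_filler_genes: int = 60

    core_width_median: float = 250.0
    core_width_sigma: float = 0.35
    embryo_peak_width: tuple[float, float] = (2000.0, 0.5)  # background (median, sigma)
    pgc_peak_width: tuple[float, float] = (250.0, 0.35)
    flank_range: tuple[int, int] = (300, 1450)  # per-side embryo flank around a locus
    pgc_jitter: int = 30  # first PGC stage expands cores by <= this per side

    promoter_fraction: float = 0.964
    feature_fractions: tuple[float, float, float] = (0.9283, 0.0279, 0.0398)
    tss_window: int = 1000

    motif_specs: tuple[MotifSpec, ...] = None  # type: ignore[assignment]

    groups: tuple[str, str] = ("control", "atz")
    n_per_group: int = 4
    n_de_genes: int = 15
    log2_effect: float = 2.0
    noise_sd: float = 0.5
    n_clusters: int = 4
    cluster_amplitude: float = 2.0
    rer_gene_baseline: float = 8.0
    other_gene_baseline: float = 5.0

    def __post_init__(self) -> None:
        if self.motif_specs is None:
            self.motif_specs = (
                MotifSpec(sp_like_pwm(), 20, 0.9),
                MotifSpec(sry_like_pwm(), 15, 0.9),
                MotifSpec(sp_like_pwm(), 10, 0.3),  # planted but poorly conserved
            )
        total_sites = sum(s.n_sites for s in self.motif_specs)
        if total_sites > self.n_loci:
            raise ValueError(
                f"{total_sites} motif sites need {total_sites} distinct cores "
                f"but only {self.n_loci} loci are guaranteed"
            )

    @property
    def n_loci(self) -> int:
        return sum(count for _, count in self.loci_core_counts)

    @property
    def embryo_stages(self) -> tuple[str, ...]:
        return self.stages[: len(self.stages) - self.n_pgc_stages]

    @property
    def pgc_stages(self) -> tuple[str, ...]:
        return self.stages[len(self.stages) - self.n_pgc_stages :]


@dataclass
class TruthTable:
    """Ground truth referencing only entities present in the emitted files."""

    rers: list[dict]  # chrom,start,end,locus_id,label,feature,genes
    early_regions: list[dict]  # embryo-only intersection spans
    decoys: list[dict]  # span + omitted stages
    motif_sites: list[dict]  # core + offset + motif_id + conservation
    de_genes: dict[str, float]  # gene -> signed log2 effect
    clusters: dict[str, int]  # RER-associated gene -> planted cluster id
    rer_gene_ids: list[str]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            return cls(**json.load(fh))


def _lognormal_width(rng, median: float, sigma: float, lo: int, hi: int) -> int:
    w = int(round(float(rng.lognormal(np.log(median), sigma))))
    return int(min(max(w, lo), hi))


@dataclass
class _Locus:
    locus_id: str
    chrom: str
    center: int
    cores: list[tuple[int, int]]
    category: str  # TSS | intronic | intergenic
    omitted: tuple[str, ...] = ()
    gene: GeneModel | None = None

    @property
    def span(self) -> tuple[int, int]:
        return self.cores[0][0], self.cores[-1][1]


def _build_cores(rng, cfg: SyntheticConfig, m: int, center: int) -> list[tuple[int, int]]:
    for _ in range(100):
        widths = [
            _lognormal_width(rng, cfg.core_width_median, cfg.core_width_sigma, 80, 600)
            for _ in range(m)
        ]
        gaps = [int(rng.integers(100, 301)) for _ in range(m - 1)]
        span = sum(widths) + sum(gaps)
        if span <= 1800:
            break
    start = center - span // 2
    cores = []
    pos = start
    for i, w in enumerate(widths):
        cores.append((pos, pos + w))
        pos += w + (gaps[i] if i < len(gaps) else 0)
    return cores


def _place_gene(rng, cfg: SyntheticConfig, locus: _Locus, gene_id: str) -> GeneModel | None:
    """Plant the gene that realizes the locus's feature category."""
    lo, hi = locus.span
    mid = (lo + hi) // 2
    if locus.category == "TSS":
        strand = "+" if rng.random() < 0.5 else "-"
        span = int(rng.integers(2000, 4501))
        if strand == "+":
            gs, ge = mid, mid + span
        else:
            gs, ge = mid + 1 - span, mid + 1
        exons = [(gs, gs + 200), (ge - 200, ge)]
        return GeneModel(gene_id, locus.chrom, strand, gs, ge, exons)
    if locus.category == "intronic":
        gs, ge = mid - 5000, mid + 3000
        exons = [(gs, gs + 200), (ge - 200, ge)]
        return GeneModel(gene_id, locus.chrom, "+", gs, ge, exons)
    return None  # intergenic: no gene near the locus


def generate_fixture(cfg: SyntheticConfig, out_dir) -> tuple[dict, TruthTable]:
    """Emit the full bundle into ``out_dir`` and return (paths, truth)."""
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_embryo = len(cfg.embryo_stages)

    # --- block allocation -------------------------------------------------
    blocks: list[tuple[str, int]] = []  # (chrom, block_start)
    for chrom, length in cfg.genome:
        for b in range(length // _BLOCK):
            blocks.append((chrom, b * _BLOCK))
    n_entities = cfg.n_loci + cfg.n_decoys_embryo + cfg.n_decoys_pgc + cfg.n_filler_genes
    if n_entities > len(blocks):
        raise ValueError(
            f"cannot place {n_entities} non-overlapping entities in "
            f"{len(blocks)} blocks of {_BLOCK} bp; enlarge the genome"
        )
    order = rng.permutation(len(blocks))
    cursor = 0

    def next_block() -> tuple[str, int]:
        nonlocal cursor
        chrom, bstart = blocks[order[cursor]]
        cursor += 1
        return chrom, bstart

    # --- planted loci and decoys -----------------------------------------
    core_counts = [m for m, count in cfg.loci_core_counts for _ in range(count)]
    loci: list[_Locus] = []
    cats = np.array(["TSS", "intronic", "intergenic"])
    for i, m in enumerate(core_counts):
        chrom, bstart = next_block()
        center = bstart + _BLOCK // 2 + int(rng.integers(-1500, 1501))
        category = str(rng.choice(cats, p=np.array(cfg.feature_fractions) / sum(cfg.feature_fractions)))
        loci.append(
            _Locus(f"locus_{i + 1:04d}", chrom, center, _build_cores(rng, cfg, m, center), category)
        )

    decoys: list[_Locus] = []
    for i in range(cfg.n_decoys_embryo + cfg.n_decoys_pgc):
        chrom, bstart = next_block()
        center = bstart + _BLOCK // 2 + int(rng.integers(-1500, 1501))
        m = int(rng.integers(1, 3))
        if i < cfg.n_decoys_embryo:
            k = int(rng.integers(1, 3))
            omitted = tuple(
                sorted(rng.choice(cfg.embryo_stages, size=k, replace=False).tolist())
            )
        else:
            k = int(rng.integers(1, cfg.n_pgc_stages + 1))
            omitted = tuple(sorted(rng.choice(cfg.pgc_stages, size=k, replace=False).tolist()))
        decoys.append(
            _Locus(
                f"decoy_{i + 1:04d}", chrom, center,
                _build_cores(rng, cfg, m, center), "decoy", omitted=omitted,
            )
        )

    # --- genes ------------------------------------------------------------
    genes: list[GeneModel] = []
    gene_counter = 0
    for locus in loci:
        gene_counter += 1
        g = _place_gene(rng, cfg, locus, f"gene_{gene_counter:04d}")
        if g is not None:
            locus.gene = g
            genes.append(g)
    for _ in range(cfg.n_filler_genes):
        gene_counter += 1
        chrom, bstart = next_block()
        center = bstart + _BLOCK // 2
        strand = "+" if rng.random() < 0.5 else "-"
        span = int(rng.integers(2000, 6001))
        gs = center - span // 2
        ge = gs + span
        genes.append(
            GeneModel(f"gene_{gene_counter:04d}", chrom, strand, gs, ge,
                      [(gs, gs + 200), (ge - 200, ge)])
        )
    background_blocks = [blocks[order[j]] for j in range(cursor, len(blocks))]

    # --- stage peaks -------------------------------------------------------
    fmin, fmax = cfg.flank_range
    stage_peaks: dict[str, list[GenomicInterval]] = {s: [] for s in cfg.stages}
    early_truth: list[dict] = []
    for locus in loci + decoys:
        lo, hi = locus.span
        emb_starts, emb_ends = [], []
        for stage in cfg.embryo_stages:
            if stage in locus.omitted:
                continue
            s = lo - int(rng.integers(fmin, fmax + 1))
            e = hi + int(rng.integers(fmin, fmax + 1))
            stage_peaks[stage].append(GenomicInterval(locus.chrom, s, e))
            emb_starts.append(s)
            emb_ends.append(e)
        for k, stage in enumerate(cfg.pgc_stages):
            if stage in locus.omitted:
                continue
            last = k == cfg.n_pgc_stages - 1
            for cs, ce in locus.cores:
                if last:
                    s, e = cs, ce  # exact core: pins the 9-way AND to the core
                else:
                    s = cs - int(rng.integers(0, cfg.pgc_jitter + 1))
                    e = ce + int(rng.integers(0, cfg.pgc_jitter + 1))
                stage_peaks[stage].append(GenomicInterval(locus.chrom, s, e))
        if len(emb_starts) == n_embryo:  # survives the whole first window
            early_truth.append(
                {"chrom": locus.chrom, "start": max(emb_starts), "end": min(emb_ends),
                 "locus_id": locus.locus_id}
            )

    for stage_idx, stage in enumerate(cfg.stages):
        is_pgc = stage_idx >= n_embryo
        median, sigma = cfg.pgc_peak_width if is_pgc else cfg.embryo_peak_width
        for _ in range(cfg.n_background_peaks):
            chrom, bstart = background_blocks[int(rng.integers(len(background_blocks)))]
            w = _lognormal_width(rng, median, sigma, 80, _BLOCK - 400)
            s = bstart + 200 + int(rng.integers(0, _BLOCK - 400 - w + 1))
            stage_peaks[stage].append(GenomicInterval(chrom, s, s + w))
    for stage in cfg.stages:
        stage_peaks[stage].sort(key=GenomicInterval.key)

    # --- per-core truth: labels, features, genes, signal tracks ------------
    rer_truth: list[dict] = []
    me3_steps: dict[str, list[tuple[int, int, float]]] = {}
    me1_steps: dict[str, list[tuple[int, int, float]]] = {}
    planted_cores: list[tuple[str, int, int]] = []
    for locus in loci + decoys:
        for cs, ce in locus.cores:
            promoter = bool(rng.random() < cfg.promoter_fraction)
            hi_val = round(float(rng.uniform(4.0, 8.0)), 3)
            lo_val = round(float(rng.uniform(1.0, 3.0)), 3)
            me3_steps.setdefault(locus.chrom, []).append(
                (cs, ce, hi_val if promoter else lo_val)
            )
            me1_steps.setdefault(locus.chrom, []).append(
                (cs, ce, lo_val if promoter else hi_val)
            )
            if locus.category == "decoy":
                continue
            planted_cores.append((locus.chrom, cs, ce))
            rer_truth.append(
                {
                    "chrom": locus.chrom, "start": cs, "end": ce,
                    "locus_id": locus.locus_id,
                    "label": "promoter" if promoter else "enhancer",
                    "feature": locus.category,
                    "genes": [locus.gene.gene_id] if locus.category == "TSS" else [],
                }
            )

    # --- genome sequence + planted motif sites + conservation --------------
    seq: dict[str, np.ndarray] = {
        chrom: rng.integers(0, 4, size=length).astype(np.int8)
        for chrom, length in cfg.genome
    }
    core_order = rng.permutation(len(planted_cores))
    site_truth: list[dict] = []
    cons_steps: dict[str, list[tuple[int, int, float]]] = {}
    ci = 0
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    for spec in cfg.motif_specs:
        consensus = spec.pwm.consensus()
        codes = np.array([int(np.uint8("ACGT".index(c))) for c in consensus], dtype=np.int8)
        for _ in range(spec.n_sites):
            chrom, cs, ce = planted_cores[core_order[ci]]
            ci += 1
            w = spec.pwm.width
            offset = int(rng.integers(10, ce - cs - w - 9))
            gstart = cs + offset
            seq[chrom][gstart : gstart + w] = codes
            cons_steps.setdefault(chrom, []).append((gstart, gstart + w, spec.conservation))
            site_truth.append(
                {
                    "chrom": chrom, "start": gstart, "end": gstart + w,
                    "core": [chrom, cs, ce], "offset": offset,
                    "motif_id": spec.pwm.motif_id, "conservation": spec.conservation,
                }
            )

    # --- expression matrices ------------------------------------------------
    rer_gene_ids = sorted({g for r in rer_truth for g in r["genes"]})
    all_gene_ids = [g.gene_id for g in genes]
    patterns = _cluster_patterns(len(EXPRESSION_STAGES), cfg.n_clusters)
    clusters = {g: (i % cfg.n_clusters) + 1 for i, g in enumerate(rer_gene_ids)}
    stage_vals = np.empty((len(all_gene_ids), len(EXPRESSION_STAGES)))
    for i, gid in enumerate(all_gene_ids):
        if gid in clusters:
            base = cfg.rer_gene_baseline
            profile = cfg.cluster_amplitude * patterns[clusters[gid] - 1]
        else:
            base = cfg.other_gene_baseline
            profile = 0.0
        stage_vals[i] = base + profile + rng.normal(0, cfg.noise_sd, len(EXPRESSION_STAGES))
    stage_mat = ExpressionMatrix(
        genes=list(all_gene_ids),
        samples=[(s, s) for s in EXPRESSION_STAGES],
        values=stage_vals,
    )

    n_de = min(cfg.n_de_genes, len(rer_gene_ids))
    de_pick = rng.choice(len(rer_gene_ids), size=n_de, replace=False)
    de_genes = {
        rer_gene_ids[int(j)]: float(cfg.log2_effect * (1 if rng.random() < 0.5 else -1))
        for j in sorted(de_pick)
    }
    samples = [
        (f"{grp}_{r + 1}", grp) for grp in cfg.groups for r in range(cfg.n_per_group)
    ]
    group_vals = np.empty((len(all_gene_ids), len(samples)))
    for i, gid in enumerate(all_gene_ids):
        base = float(rng.uniform(4.0, 8.0))
        log2 = np.full(len(samples), base) + rng.normal(0, cfg.noise_sd, len(samples))
        if gid in de_genes:
            atz_cols = [j for j, (_, grp) in enumerate(samples) if grp == cfg.groups[1]]
            log2[atz_cols] += de_genes[gid]
        group_vals[i] = 2.0 ** log2
    group_mat = ExpressionMatrix(
        genes=list(all_gene_ids), samples=samples, values=group_vals
    )

    # --- emit ---------------------------------------------------------------
    paths = {"dir": str(out)}
    fasta_path = out / "genome.fa"
    with open(fasta_path, "w") as fh:
        for chrom, _ in cfg.genome:
            fh.write(f">{chrom}\n")
            letters = alphabet[seq[chrom].astype(np.intp)].tobytes().decode("ascii")
            for k in range(0, len(letters), 80):
                fh.write(letters[k : k + 80] + "\n")
    paths["genome"] = str(fasta_path)

    from .regions import RegionSet  # local to avoid confusion with module-level names
    from .tracks import CoverageTrack

    paths["peaks"] = {}
    for stage in cfg.stages:
        p = out / f"peaks_{stage}.bed"
        rio.write_bed(RegionSet(stage, stage_peaks[stage]), p)
        paths["peaks"][stage] = str(p)

    gene_path = out / "genes.tsv"
    rio.write_gene_table(genes, gene_path)
    paths["genes"] = str(gene_path)

    for name, steps in (("me3", me3_steps), ("me1", me1_steps), ("conservation", cons_steps)):
        p = out / f"{name}.bedgraph"
        rio.write_bedgraph(CoverageTrack(steps), p)
        paths[name] = str(p)

    motif_path = out / "motifs.meme"
    seen: dict[str, PWMRecord] = {}
    for spec in cfg.motif_specs:
        seen.setdefault(spec.pwm.motif_id, spec.pwm)
    rio.write_meme_motifs(list(seen.values()), motif_path)
    paths["motifs"] = str(motif_path)

    stage_expr_path = out / "expression_stages.tsv"
    rio.write_expression(stage_mat, stage_expr_path)
    paths["expression_stages"] = str(stage_expr_path)
    group_expr_path = out / "expression_groups.tsv"
    rio.write_expression(group_mat, group_expr_path)
    paths["expression_groups"] = str(group_expr_path)

    truth = TruthTable(
        rers=sorted(rer_truth, key=lambda r: (r["chrom"], r["start"])),
        early_regions=sorted(early_truth, key=lambda r: (r["chrom"], r["start"])),
        decoys=[
            {"chrom": d.chrom, "start": d.span[0], "end": d.span[1],
             "omitted_stages": list(d.omitted), "locus_id": d.locus_id}
            for d in decoys
        ],
        motif_sites=sorted(site_truth, key=lambda s: (s["chrom"], s["start"])),
        de_genes=de_genes,
        clusters=clusters,
        rer_gene_ids=rer_gene_ids,
    )
    truth_path = out / "truth.json"
    truth.to_json(truth_path)
    paths["truth"] = str(truth_path)
    return paths, truth


def _cluster_patterns(n_stages: int, k: int) -> np.ndarray:
    """k near-orthogonal +/-1 stage profiles (block patterns)."""
    half = n_stages // 2
    quarter = n_stages // 4
    base = np.ones(n_stages)
    p1 = base.copy()
    p1[half:] = -1
    p2 = -p1
    p3 = -base.copy()
    p3[quarter : quarter + half] = 1
    p4 = -p3
    patterns = np.vstack([p1, p2, p3, p4])
    if k > 4:
        raise ValueError("at most 4 planted cluster profiles are defined")
    return patterns[:k]


def summarize_fixture(bundle_dir) -> dict:
    """Per-stage peak counts and width medians of an emitted bundle."""
    out = {}
    for p in sorted(Path(bundle_dir).glob("peaks_*.bed")):
        stage = p.stem[len("peaks_") :]
        rs = rio.read_bed(p, stage=stage)
        widths = sorted(iv.width for iv in rs.intervals)
        n = len(widths)
        if n == 0:
            out[stage] = {"n": 0, "median_width": None}
            continue
        mid = n // 2
        med = float(widths[mid]) if n % 2 else (widths[mid - 1] + widths[mid]) / 2.0
        out[stage] = {"n": n, "median_width": med}
    return out
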