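"""Statistics on expression matrices and count tables.

The centrepiece is the empirical-Bayes moderated t-statistic: per-gene
residual variances are shrunk toward a common prior estimated by moments
matching of log variances against a scaled-F model, and the t-statistic
gains the prior degrees of freedom.  Around it: strict fold-change
filtering, Benjamini-Hochberg FDR, the classical two-sample t, Pearson's
chi-square homogeneity test, average-linkage correlation clustering, and
one-sided hypergeometric term enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.special import polygamma
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "fold_change_filter",
    "moderated_t",
    "bh_fdr",
    "two_sample_t",
    "chisq_homogeneity",
    "cluster_expression",
    "term_enrichment",
    "de_analysis",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample group labels."""

    genes: list[str]
    samples: list[tuple[str, str]]  # (sample_id, group/stage label)
    values: np.ndarray
    log_transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if np.any(np.isnan(self.values)):
            raise ValueError("expression matrix contains missing values")

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for _, g in self.samples:
            if g not in seen:
                seen.append(g)
        return seen

    def group_columns(self, group: str) -> np.ndarray:
        cols = np.array([i for i, (_, g) in enumerate(self.samples) if g == group])
        if len(cols) == 0:
            raise KeyError(f"no samples in group {group!r}")
        return cols

    def subset(self, genes: Sequence[str]) -> "ExpressionMatrix":
        index = {g: i for i, g in enumerate(self.genes)}
        rows = [index[g] for g in genes]
        return ExpressionMatrix(
            genes=list(genes),
            samples=list(self.samples),
            values=self.values[rows],
            log_transformed=self.log_transformed,
        )

    def log2_values(self, offset: float = 0.1) -> np.ndarray:
        if self.log_transformed:
            return self.values
        return np.log2(self.values + offset)


def fold_change_filter(
    mat: ExpressionMatrix,
    group_a: str,
    group_b: str,
    fc_threshold: float = 2.0,
    epsilon: float = 0.1,
) -> pd.DataFrame:
    """Per-gene fold change (ratio of linear-scale group means) and pass flag.

    A gene passes iff max(FC, 1/FC) is *strictly* greater than the threshold
    ("more than"-fold semantics, so a ratio of exactly 2 fails at threshold 2).
    ``epsilon`` is added to both means to guard zero denominators.
    """
    a = mat.group_columns(group_a)
    b = mat.group_columns(group_b)
    vals = 2.0 ** mat.values if mat.log_transformed else mat.values
    mean_a = vals[:, a].mean(axis=1)
    mean_b = vals[:, b].mean(axis=1)
    if epsilon == 0.0 and (np.any(mean_a == 0) or np.any(mean_b == 0)):
        raise ValueError("all-zero group mean with epsilon = 0")
    fc = (mean_a + epsilon) / (mean_b + epsilon)
    abs_fc = np.maximum(fc, 1.0 / fc)
    return pd.DataFrame(
        {"gene_id": mat.genes, "fc": fc, "abs_fc": abs_fc, "fc_pass": abs_fc > fc_threshold}
    ).set_index("gene_id")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the log scale)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) / x < 1e-10:
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moments-matching estimate of the prior (d0, s0^2) from residual
    variances s2 with df degrees of freedom each.

    Under the hierarchical model, log s2 follows log s0^2 plus a log-F
    offset; matching the mean and variance of log s2 gives the prior df
    (via the inverse trigamma) and the prior variance.  A sample variance
    of log s2 at or below the sampling noise floor yields d0 = inf.
    """
    ok = s2 > 0
    if not np.any(ok):
        raise ValueError("all residual variances are zero")
    z = np.log(s2[ok])
    e = z - float(polygamma(0, df / 2.0)) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_2 = np.exp(emean + float(polygamma(0, d0 / 2.0)) - np.log(d0 / 2.0))
    else:
        d0 = np.inf
        s0_2 = np.exp(emean)
    return d0, s0_2


def moderated_t(
    mat: ExpressionMatrix,
    group_a: str,
    group_b: str,
    log_offset: float = 0.1,
    d0_override: Optional[float] = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t per gene (A vs B, log2 scale).

    Values are log2(x + offset)-transformed unless already logged.  The
    posterior variance blends each gene's pooled residual variance with the
    estimated prior: s_post^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g), and the
    statistic log2fc / (s_post sqrt(1/nA + 1/nB)) is referred to a t
    distribution on d0 + d_g degrees of freedom.  ``d0_override`` forces the
    prior df: 0 recovers the ordinary pooled t, inf fully shrinks to s0^2.
    """
    a = mat.group_columns(group_a)
    b = mat.group_columns(group_b)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("moderated_t needs >= 2 samples per group")
    x = mat.log2_values(log_offset)
    xa, xb = x[:, a], x[:, b]
    log2fc = xa.mean(axis=1) - xb.mean(axis=1)
    df_resid = na + nb - 2
    ss = ((xa - xa.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (xb - xb.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid
    if np.all(s2 == 0):
        raise ValueError("zero residual variance for every gene")
    d0, s0_2 = estimate_variance_prior(s2, df_resid)
    if d0_override is not None:
        d0 = d0_override
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    elif d0 == 0:
        s2_post = s2
        df_total = float(df_resid)
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    stderr = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(stderr > 0, log2fc / stderr, 0.0)
    if np.isinf(df_total):
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame(
        {
            "gene_id": mat.genes,
            "log2fc": log2fc,
            "t_mod": t,
            "p": p,
            "s2": s2,
            "s2_post": s2_post,
        }
    ).set_index("gene_id").assign(d0=d0, s0_2=s0_2, df_total=df_total)


def bh_fdr(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def two_sample_t(
    values_a: Sequence[float], values_b: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Classical two-sided two-sample t (pooled variance; Welch via flag).

    Two constant, equal groups are reported as (t=0, p=1) rather than NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("two_sample_t needs >= 2 values per group")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # near-constant input
        t, p = sps.ttest_ind(a, b, equal_var=not welch)
    if np.isnan(t):
        return 0.0, 1.0
    return float(t), float(p)


def chisq_homogeneity(counts) -> tuple[float, int, float]:
    """Pearson chi-square homogeneity test on an r x 2 count table.

    No continuity correction; df = r - 1.  Zero margins or zero expected
    cells are errors.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2 or table.shape[0] < 2:
        raise ValueError("expected an r x 2 table with r >= 2")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row or column margin")
    chi2, p, df, expected = sps.chi2_contingency(table, correction=False)
    if np.any(expected <= 0):
        raise ValueError("zero expected cell count")
    return float(chi2), int(df), float(p)


def cluster_expression(mat: ExpressionMatrix, k: int = 4) -> dict[str, int]:
    """Cut an average-linkage tree on 1 - Pearson distance into k clusters.

    Rows are z-scored first; a constant row has undefined correlation and is
    an error.  Cluster ids are renumbered 1..k in order of first appearance,
    so the labelling is deterministic given input order.
    """
    if len(mat.genes) < k:
        raise ValueError(f"need >= {k} genes to form {k} clusters")
    x = mat.values
    sd = x.std(axis=1)
    if np.any(sd == 0):
        bad = mat.genes[int(np.argmax(sd == 0))]
        raise ValueError(f"constant expression row (undefined correlation): {bad}")
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    dist = pdist(z, metric="correlation")
    tree = linkage(dist, method="average")
    raw = fcluster(tree, t=k, criterion="maxclust")
    relabel: dict[int, int] = {}
    out: dict[str, int] = {}
    for gene, c in zip(mat.genes, raw):
        if c not in relabel:
            relabel[c] = len(relabel) + 1
        out[gene] = relabel[c]
    return out


def term_enrichment(
    selected_genes: Sequence[str],
    universe: Sequence[str],
    term_map: Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment per term, BH-adjusted across terms.

    The tail P(X >= overlap) is the Fisher's-exact enrichment p-value.  Terms
    are restricted to universe members; selected genes must be a subset of
    the universe.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    sel = set(selected_genes)
    if not sel <= uni:
        raise ValueError("selected genes must be a subset of the universe")
    m_total = len(uni)
    n_sel = len(sel)
    rows = []
    for term, members in term_map.items():
        members_in = set(members) & uni
        k_term = len(members_in)
        overlap = len(members_in & sel)
        if k_term == 0:
            p = 1.0
        else:
            p = float(sps.hypergeom.sf(overlap - 1, m_total, k_term, n_sel))
        rows.append((term, overlap, k_term, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "overlap", "term_size", "p"]).set_index("term")
    df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
    return df


def de_analysis(
    mat: ExpressionMatrix,
    group_a: str,
    group_b: str,
    fc_threshold: float = 2.0,
    fdr_threshold: float = 0.1,
    epsilon: float = 0.1,
    order: str = "filter_then_test",
) -> pd.DataFrame:
    """Differential expression: strict fold-change filter + moderated t + BH.

    ``filter_then_test`` (default) applies the moderated test and the BH
    adjustment only to genes passing the fold-change filter; ``joint`` tests
    every gene and intersects afterwards.  A gene passes overall iff its
    fold change strictly exceeds ``fc_threshold`` and q < ``fdr_threshold``.
    """
    if order not in ("filter_then_test", "joint"):
        raise ValueError("order must be 'filter_then_test' or 'joint'")
    fc = fold_change_filter(mat, group_a, group_b, fc_threshold, epsilon)
    if order == "filter_then_test":
        kept = [g for g in mat.genes if bool(fc.loc[g, "fc_pass"])]
        out = fc.copy()
        out["t_mod"] = np.nan
        out["p"] = np.nan
        out["q"] = np.nan
        out["log2fc"] = np.nan
        if kept:
            tt = moderated_t(mat.subset(kept), group_a, group_b)
            out.loc[kept, ["log2fc", "t_mod", "p"]] = tt[["log2fc", "t_mod", "p"]].to_numpy()
            out.loc[kept, "q"] = bh_fdr(tt["p"].to_numpy())
        out["passes"] = out["fc_pass"] & (out["q"] < fdr_threshold)
    else:
        tt = moderated_t(mat, group_a, group_b)
        out = fc.join(tt[["log2fc", "t_mod", "p"]])
        out["q"] = bh_fdr(out["p"].to_numpy())
        out["passes"] = out["fc_pass"] & (out["q"] < fdr_threshold)
    out["passes"] = out["passes"].fillna(False).astype(bool)
    return out
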