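import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from oracles import pearson_chi2, pooled_t
from rer_escape.stats import (
    ExpressionMatrix,
    bh_fdr,
    chisq_homogeneity,
    cluster_expression,
    de_analysis,
    fold_change_filter,
    moderated_t,
    term_enrichment,
    two_sample_t,
)


def two_group_matrix(values, n_a=4, n_b=4, group_a="atz", group_b="control"):
    values = np.asarray(values, float)
    samples = [(f"a{i}", group_a) for i in range(n_a)] + [
        (f"b{i}", group_b) for i in range(n_b)
    ]
    genes = [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(genes, samples, values)


def hierarchical_null(rng, n_genes=5000, n=4, d0=8.0, s0=0.25):
    """Null data from the hierarchical variance model: per-gene variance
    drawn scaled-inverse-chi-square(d0, s0), Gaussian noise, no mean shift."""
    s2 = d0 * s0 / rng.chisquare(d0, size=n_genes)
    x = rng.normal(0, np.sqrt(s2)[:, None], size=(n_genes, 2 * n))
    mat = two_group_matrix(x, n_a=n, n_b=n)
    mat.log_transformed = True
    return mat


class TestFoldChange:
    def test_clear_difference_passes(self):
        mat = two_group_matrix([[4.0] * 4 + [1.0] * 4])
        out = fold_change_filter(mat, "atz", "control", epsilon=0.0)
        assert bool(out["fc_pass"].iloc[0]) and out["fc"].iloc[0] == 4.0

    def test_exactly_two_fold_fails_strict_rule(self):
        mat = two_group_matrix([[2.0] * 4 + [1.0] * 4])
        out = fold_change_filter(mat, "atz", "control", epsilon=0.0)
        assert not bool(out["fc_pass"].iloc[0])

    def test_down_regulation_symmetric(self):
        mat = two_group_matrix([[1.0] * 4 + [5.0] * 4])
        out = fold_change_filter(mat, "atz", "control", epsilon=0.0)
        assert bool(out["fc_pass"].iloc[0]) and out["abs_fc"].iloc[0] == 5.0

    def test_zero_mean_with_zero_epsilon_rejected(self):
        mat = two_group_matrix([[0.0] * 4 + [1.0] * 4])
        with pytest.raises(ValueError):
            fold_change_filter(mat, "atz", "control", epsilon=0.0)

    def test_random_matrix_matches_direct_recomputation(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 50, size=(300, 8))
        mat = two_group_matrix(x)
        out = fold_change_filter(mat, "atz", "control", fc_threshold=2.0, epsilon=0.1)
        fc = (x[:, :4].mean(axis=1) + 0.1) / (x[:, 4:].mean(axis=1) + 0.1)
        expected = np.maximum(fc, 1 / fc) > 2.0
        np.testing.assert_array_equal(out["fc_pass"].to_numpy(), expected)


class TestModeratedT:
    def test_d0_zero_equals_ordinary_pooled_t(self):
        rng = np.random.default_rng(7)
        mat = two_group_matrix(rng.normal(5, 1, size=(200, 8)))
        mat.log_transformed = True
        out = moderated_t(mat, "atz", "control", d0_override=0.0)
        for i in range(0, 200, 17):
            t, p = pooled_t(mat.values[i, :4], mat.values[i, 4:])
            assert out["t_mod"].iloc[i] == pytest.approx(t, abs=1e-8)
            assert out["p"].iloc[i] == pytest.approx(p, abs=1e-8)

    def test_d0_infinite_shrinks_to_prior_variance(self):
        rng = np.random.default_rng(8)
        mat = two_group_matrix(rng.normal(5, 1, size=(100, 8)))
        mat.log_transformed = True
        out = moderated_t(mat, "atz", "control", d0_override=np.inf)
        assert out["s2_post"].nunique() == 1
        assert out["s2_post"].iloc[0] == pytest.approx(out["s0_2"].iloc[0])

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(11)
        out = moderated_t(hierarchical_null(rng), "atz", "control")
        ks = sps.kstest(out["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_prior_df_recovery_over_20_seeds(self):
        """Moments matching recovers the simulated prior df within 25%."""
        d0_true = 8.0
        estimates = []
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            out = moderated_t(hierarchical_null(rng, d0=d0_true), "atz", "control")
            estimates.append(out["d0"].iloc[0])
        assert abs(np.median(estimates) - d0_true) / d0_true < 0.25

    def test_zero_variance_everywhere_rejected(self):
        mat = two_group_matrix(np.ones((10, 8)))
        mat.log_transformed = True
        with pytest.raises(ValueError):
            moderated_t(mat, "atz", "control")

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_limma_reference(self, tmp_path):
        """Cross-check t, p and the estimated prior against limma's eBayes."""
        rng = np.random.default_rng(42)
        x = hierarchical_null(rng, n_genes=400)
        df = pd.DataFrame(x.values, index=x.genes,
                          columns=[s for s, _ in x.samples])
        mat_path = tmp_path / "mat.tsv"
        df.to_csv(mat_path, sep="\t")
        out_path = tmp_path / "limma.tsv"
        script = f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.table("{mat_path}", header=TRUE, row.names=1, sep="\\t"))
        grp <- factor(c(rep("A", 4), rep("B", 4)), levels=c("A", "B"))
        design <- model.matrix(~0 + grp)
        colnames(design) <- levels(grp)
        fit <- lmFit(x, design)
        fit <- contrasts.fit(fit, makeContrasts(A - B, levels=design))
        fit <- eBayes(fit)
        out <- data.frame(t=fit$t[,1], p=fit$p.value[,1],
                          d0=fit$df.prior, s0=fit$s2.prior)
        write.table(out, "{out_path}", sep="\\t", quote=FALSE)
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(out_path, sep="\t")
        mine = moderated_t(x, "atz", "control")
        assert mine["d0"].iloc[0] == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert mine["s0_2"].iloc[0] == pytest.approx(ref["s0"].iloc[0], rel=1e-4)
        np.testing.assert_allclose(mine["t_mod"], ref["t"], rtol=1e-4)
        np.testing.assert_allclose(mine["p"], ref["p"], rtol=1e-3)


class TestBH:
    def test_single_pvalue_unchanged(self):
        assert bh_fdr([0.03])[0] == pytest.approx(0.03)

    def test_forced_equal_qvalues(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_out_of_range_rejected(self):
        for bad in ([0.0, 0.5], [0.5, 1.5]):
            with pytest.raises(ValueError):
                bh_fdr(bad)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(1e-6, 1, size=50)
        q = bh_fdr(p)
        perm = rng.permutation(50)
        np.testing.assert_allclose(bh_fdr(p[perm]), q[perm], rtol=1e-12)

    def test_null_false_discovery_proportion_controlled(self):
        rng = np.random.default_rng(17)
        n = 5000
        frac = np.mean(bh_fdr(rng.uniform(size=n)) < 0.1)
        se = np.sqrt(0.1 * 0.9 / n)
        assert frac <= 0.1 + 3 * se


class TestTwoSampleT:
    def test_identical_groups(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_constant_equal_groups(self):
        assert two_sample_t([2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)

    def test_clear_separation(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1e-6, 8)
        b = 1 + rng.normal(0, 1e-6, 8)
        _, p = two_sample_t(a, b)
        assert p < 1e-10

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            a = rng.normal(0, 2, int(rng.integers(3, 12)))
            b = rng.normal(0.5, 1, int(rng.integers(3, 12)))
            t, p = two_sample_t(a, b)
            t_ref, p_ref = pooled_t(a, b)
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)


class TestChisq:
    def test_homogeneous_table(self):
        chi2, df, p = chisq_homogeneity([[10, 10], [10, 10]])
        assert chi2 == 0.0 and df == 1 and p == pytest.approx(1.0)

    def test_perfect_separation(self):
        chi2, df, _ = chisq_homogeneity([[50, 0], [0, 50]])
        assert chi2 == pytest.approx(100.0) and df == 1

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chisq_homogeneity([[0, 10], [0, 20]])

    def test_matches_direct_formula_and_row_order_invariant(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            table = rng.integers(1, 200, size=(int(rng.integers(2, 10)), 2))
            chi2, df, _ = chisq_homogeneity(table)
            assert chi2 == pytest.approx(pearson_chi2(table), abs=1e-9)
            assert df == table.shape[0] - 1
            chi2_perm, _, _ = chisq_homogeneity(table[::-1])
            assert chi2_perm == pytest.approx(chi2, abs=1e-9)


class TestClustering:
    def stage_matrix(self, values):
        genes = [f"g{i}" for i in range(values.shape[0])]
        samples = [(f"s{j}", f"s{j}") for j in range(values.shape[1])]
        return ExpressionMatrix(genes, samples, values)

    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(1)
        mat = self.stage_matrix(rng.normal(size=(6, 10)))
        labels = cluster_expression(mat, k=6)
        assert len(set(labels.values())) == 6

    def test_anticorrelated_blocks_recovered(self):
        base = np.tile([1.0, -1.0, 1.0, -1.0, 1.0, -1.0], (4, 1))
        values = np.vstack([base + 0.01, -base + 0.02])
        labels = cluster_expression(self.stage_matrix(values), k=2)
        lab = list(labels.values())
        assert lab[:4] == [lab[0]] * 4 and lab[4:] == [lab[4]] * 4
        assert lab[0] != lab[4]

    def test_constant_row_rejected(self):
        values = np.vstack([np.ones(8), np.arange(8, dtype=float)])
        with pytest.raises(ValueError, match="constant"):
            cluster_expression(self.stage_matrix(values), k=2)

    def test_planted_four_clusters_recovered(self):
        """Planted block profiles are recovered with ARI >= 0.9 across seeds."""
        from sklearn.metrics import adjusted_rand_score

        from rer_escape.simulate import _cluster_patterns

        patterns = _cluster_patterns(14, 4)
        aris = []
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            truth, rows = [], []
            for i in range(48):
                c = i % 4
                truth.append(c)
                rows.append(8.0 + 2.0 * patterns[c] + rng.normal(0, 0.5, 14))
            labels = cluster_expression(self.stage_matrix(np.vstack(rows)), k=4)
            aris.append(adjusted_rand_score(truth, list(labels.values())))
        assert np.mean(aris) >= 0.9


class TestTermEnrichment:
    def test_perfect_overlap_closed_form(self):
        universe = [f"g{i}" for i in range(20)]
        term = {"T": universe[:5]}
        out = term_enrichment(universe[:5], universe, term)
        assert out.loc["T", "p"] == pytest.approx(1 / 15504, rel=1e-12)

    def test_disjoint_term_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        out = term_enrichment(universe[:5], universe, {"T": universe[10:15]})
        assert out.loc["T", "p"] == 1.0

    def test_selected_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            term_enrichment(["x"], ["a", "b"], {})

    def test_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(14)
        universe = [f"g{i}" for i in range(30)]
        for _ in range(20):
            sel = list(rng.choice(universe, size=int(rng.integers(1, 15)), replace=False))
            members = list(rng.choice(universe, size=int(rng.integers(1, 20)), replace=False))
            out = term_enrichment(sel, universe, {"T": members})
            k = len(set(sel) & set(members))
            # direct pmf summation over the upper tail
            p = sum(
                sps.hypergeom.pmf(j, 30, len(members), len(sel))
                for j in range(k, min(len(members), len(sel)) + 1)
            )
            assert out.loc["T", "p"] == pytest.approx(p, abs=1e-12)


class TestDeAnalysis:
    def test_pass_rule_requires_both_conditions(self):
        rng = np.random.default_rng(30)
        n_genes = 60
        log2 = rng.uniform(4, 8, size=(n_genes, 1)) + rng.normal(0, 0.4, size=(n_genes, 8))
        log2[:10, :4] += 2.5  # strong effect: passes both
        log2[10:20, :4] += 0.15  # tiny effect: fails the fold filter
        mat = two_group_matrix(2.0 ** log2)
        out = de_analysis(mat, "atz", "control")
        assert out["passes"][:10].all()
        assert not out["passes"][10:].any()
        assert (out["passes"] == (out["fc_pass"] & (out["q"] < 0.1))).all()

    def test_joint_order_agrees_on_strong_signal(self):
        rng = np.random.default_rng(31)
        log2 = np.full((40, 8), 6.0) + rng.normal(0, 0.3, size=(40, 8))
        log2[:5, :4] += 3.0
        mat = two_group_matrix(2.0 ** log2)
        a = de_analysis(mat, "atz", "control", order="filter_then_test")
        b = de_analysis(mat, "atz", "control", order="joint")
        assert set(a.index[a["passes"]]) == set(b.index[b["passes"]]) == set(a.index[:5])
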