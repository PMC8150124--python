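import numpy as np
import pytest

from rer_escape.annotation import (
    AnnotationConfig,
    assign_feature,
    associate_genes,
    classify_promoter_enhancer,
    feature_proportion_table,
    mean_signal,
    tss_profile,
)
from rer_escape.regions import GeneModel, GenomicInterval, RegionSet
from rer_escape.rer import RER
from rer_escape.tracks import CoverageTrack


def make_rer(start, end, rer_id="R1", chrom="chr1"):
    return RER(rer_id=rer_id, interval=GenomicInterval(chrom, start, end), supporting={})


def const_track(value, start=0, end=100_000, chrom="chr1"):
    return CoverageTrack({chrom: [(start, end, value)]})


class TestMeanSignal:
    def test_constant_track(self):
        assert mean_signal(GenomicInterval("chr1", 10, 60), const_track(2.5)) == 2.5

    def test_equal_length_steps_average(self):
        track = CoverageTrack({"chr1": [(0, 50, 1.0), (50, 100, 3.0)]})
        assert mean_signal(GenomicInterval("chr1", 0, 100), track) == 2.0

    def test_uncovered_bases_count_as_zero(self):
        track = CoverageTrack({"chr1": [(0, 50, 4.0)]})
        assert mean_signal(GenomicInterval("chr1", 0, 100), track) == 2.0

    def test_random_track_matches_per_base_oracle(self):
        rng = np.random.default_rng(17)
        pos, steps = 0, []
        for _ in range(300):
            pos += int(rng.integers(0, 50))
            w = int(rng.integers(1, 80))
            steps.append((pos, pos + w, float(rng.uniform(0, 5))))
            pos += w
        track = CoverageTrack({"chr1": steps})
        for _ in range(50):
            s = int(rng.integers(0, pos - 10))
            e = s + int(rng.integers(1, 2000))
            region = GenomicInterval("chr1", s, e)
            oracle = track.per_base("chr1", s, e).mean()
            assert mean_signal(region, track) == pytest.approx(oracle, abs=1e-9)


class TestClassify:
    def cfg(self, me3_val, me1_val):
        return AnnotationConfig(me3_track=const_track(me3_val), me1_track=const_track(me1_val))

    @pytest.mark.parametrize(
        "me3,me1,expected",
        [(5.0, 2.0, "promoter"), (2.0, 5.0, "enhancer"), (1.0, 1.0, "promoter")],
    )
    def test_rule_and_tie_break(self, me3, me1, expected):
        rer = make_rer(100, 200)
        assert classify_promoter_enhancer(rer, self.cfg(me3, me1)) == expected
        assert (rer.me3_mean, rer.me1_mean) == (me3, me1)

    def test_scale_equivariance(self):
        """Multiplying both tracks by the same constant never flips a label."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            a, b, scale = rng.uniform(0.1, 10, 3)
            r1, r2 = make_rer(0, 100), make_rer(0, 100)
            lab1 = classify_promoter_enhancer(r1, self.cfg(a, b))
            lab2 = classify_promoter_enhancer(r2, self.cfg(a * scale, b * scale))
            assert lab1 == lab2


class TestAssignFeature:
    GENES = [
        GeneModel("near", "chr1", "+", 10_000, 20_000),
        GeneModel("far", "chr1", "+", 50_000, 60_000),
    ]

    def cfg(self):
        return AnnotationConfig()

    def test_midpoint_near_tss(self):
        rer = make_rer(10_200, 10_400)  # midpoint 300 bp from TSS at 10_000
        assert assign_feature(rer, self.GENES, self.cfg()) == "TSS"

    def test_midpoint_in_gene_body(self):
        rer = make_rer(14_900, 15_100)  # 5 kb into the gene
        assert assign_feature(rer, self.GENES, self.cfg()) == "intronic"

    def test_midpoint_far_from_genes(self):
        rer = make_rer(30_000, 30_200)
        assert assign_feature(rer, self.GENES, self.cfg()) == "intergenic"

    def test_categories_partition(self):
        rng = np.random.default_rng(8)
        rers = [make_rer(int(s), int(s) + 200) for s in rng.integers(0, 70_000, 200)]
        feats = [assign_feature(r, self.GENES, self.cfg()) for r in rers]
        assert len(feats) == 200
        assert set(feats) <= {"TSS", "intronic", "intergenic"}

    def test_strand_mirror_invariance(self):
        """Reflecting all coordinates and flipping strands preserves
        TSS-window membership of every midpoint."""
        L = 100_000
        genes = [GeneModel("g", "chr1", "+", 40_000, 45_000)]
        mirrored = [GeneModel("g", "chr1", "-", L - 45_000, L - 40_000)]
        cfg = self.cfg()
        rng = np.random.default_rng(21)
        for _ in range(100):
            s = int(rng.integers(0, L - 201))
            width = int(rng.integers(2, 200))
            fwd = make_rer(s, s + width)
            rev = make_rer(L - (s + width), L - s)
            assert (assign_feature(fwd, genes, cfg) == "TSS") == (
                assign_feature(rev, mirrored, cfg) == "TSS"
            )


class TestAssociateGenes:
    def test_divergent_promoter_hits_both_genes(self):
        genes = [
            GeneModel("left", "chr1", "-", 5_000, 10_000),  # TSS 9_999
            GeneModel("right", "chr1", "+", 10_500, 15_000),  # TSS 10_500
        ]
        rer = make_rer(9_900, 10_600)
        mapping, universe = associate_genes([rer], genes, AnnotationConfig())
        assert sorted(mapping["R1"]) == ["left", "right"]
        assert universe == ["left", "right"]

    def test_window_boundary_exclusive(self):
        genes = [GeneModel("g", "chr1", "+", 10_000, 15_000)]
        cfg = AnnotationConfig()
        inside = make_rer(8_900, 9_000)  # last base 8999 = tss - 1001
        mapping, _ = associate_genes([inside], genes, cfg)
        assert mapping["R1"] == []
        touching = make_rer(8_900, 9_001)  # last base 9000 = tss - 1000
        mapping, _ = associate_genes([touching], genes, cfg)
        assert mapping["R1"] == ["g"]

    def test_sorted_by_distance_then_id(self):
        genes = [
            GeneModel("b_far", "chr1", "+", 11_000, 15_000),
            GeneModel("a_near", "chr1", "+", 10_100, 15_000),
        ]
        rer = make_rer(10_000, 10_050)
        mapping, _ = associate_genes([rer], genes, AnnotationConfig())
        assert mapping["R1"] == ["a_near", "b_far"]


class TestFeatureProportionTable:
    GENES = [GeneModel(f"g{i}", "chr1", "+", 10_000 * i, 10_000 * i + 5000) for i in range(1, 8)]

    def test_identical_sets_identical_rows(self):
        ivs = [GenomicInterval("chr1", 9_800, 10_300), GenomicInterval("chr1", 500, 700)]
        table = feature_proportion_table(
            [RegionSet("a", list(ivs)), RegionSet("b", list(ivs))],
            self.GENES,
            AnnotationConfig(),
        )
        assert (table.loc["a"] == table.loc["b"]).all()

    def test_fully_tss_proximal_set(self):
        ivs = [GenomicInterval("chr1", 10_000 * i - 100, 10_000 * i + 100) for i in range(1, 8)]
        table = feature_proportion_table(
            [RegionSet("all_in", ivs), RegionSet("other", [GenomicInterval("chr1", 500, 600)])],
            self.GENES,
            AnnotationConfig(),
        )
        assert tuple(table.loc["all_in"]) == (7, 0)
        assert tuple(table.loc["other"]) == (0, 1)

    def test_random_sets_match_direct_recount(self):
        rng = np.random.default_rng(33)
        cfg = AnnotationConfig()
        sets = []
        for name in ("x", "y", "z"):
            ivs = [
                GenomicInterval("chr1", int(s), int(s) + int(rng.integers(50, 500)))
                for s in rng.integers(0, 80_000, 150)
            ]
            sets.append(RegionSet(name, ivs))
        table = feature_proportion_table(sets, self.GENES, cfg)
        tss_list = [g.tss for g in self.GENES]
        for rs in sets:
            within = sum(
                1
                for iv in rs.intervals
                if any(abs(iv.midpoint - t) <= cfg.tss_window for t in tss_list)
            )
            assert tuple(table.loc[rs.stage]) == (within, len(rs.intervals) - within)


class TestTssProfile:
    def test_single_region_downstream_occupancy(self):
        genes = [GeneModel("g", "chr1", "+", 10_000, 15_000)]
        rer = make_rer(10_000, 10_100)
        cfg = AnnotationConfig(profile_bin=50, bootstrap_resamples=50)
        prof = tss_profile([rer], genes, cfg)
        expected = np.zeros(40)
        expected[20:22] = 1.0  # the two bins immediately downstream of the TSS
        np.testing.assert_allclose(prof["mean"], expected)
        np.testing.assert_allclose(prof["ci_low"], expected)  # single row: degenerate CI
        np.testing.assert_allclose(prof["ci_high"], expected)

    def test_minus_strand_orientation(self):
        """On a - strand gene, downstream of the TSS means lower coordinates."""
        genes = [GeneModel("g", "chr1", "-", 5_000, 10_000)]  # TSS at 9_999
        rer = make_rer(9_900, 10_000)  # covers [tss-99, tss]: downstream side
        cfg = AnnotationConfig(profile_bin=50, bootstrap_resamples=50)
        prof = tss_profile([rer], genes, cfg)
        assert prof["mean"][20] == 1.0 and prof["mean"][21] == 1.0
        assert prof["mean"][19] == 0.0  # nothing upstream of the TSS

    def test_band_contains_mean_and_counts_pairs(self):
        rng = np.random.default_rng(6)
        genes = [GeneModel(f"g{i}", "chr1", "+", 20_000 * i, 20_000 * i + 5000) for i in range(1, 6)]
        rers = []
        for i, g in enumerate(genes):
            s = g.tss + int(rng.integers(-800, 500))
            rers.append(make_rer(s, s + int(rng.integers(100, 400)), rer_id=f"R{i}"))
        prof = tss_profile(rers, genes, AnnotationConfig(bootstrap_resamples=200))
        assert prof["n_pairs"] == 5
        assert np.all(prof["ci_low"] <= prof["mean"] + 1e-12)
        assert np.all(prof["mean"] <= prof["ci_high"] + 1e-12)
        # mean equals a direct per-bin recount over rows
        np.testing.assert_allclose(prof["mean"], prof["matrix"].mean(axis=0))

    def test_no_pairs_is_an_error(self):
        genes = [GeneModel("g", "chr1", "+", 50_000, 55_000)]
        with pytest.raises(ValueError):
            tss_profile([make_rer(0, 100)], genes, AnnotationConfig())
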