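import numpy as np
import pandas as pd
import pytest

from hicdyn import (
    GeneModel,
    bin_genome,
    breakpoint_overlap,
    de_enrichment_chisq,
    enrichment_table,
    enrichment_test,
    expression_correlation,
    partition_gene,
    peaks_per_bin,
    rank_association,
    summarize_gene_counts,
)
from hicdyn.frequency import FrequencyProfile
from hicdyn.integration import aggregate_signal, binomial_tail_log10


class TestPartitionGene:
    def test_plus_strand(self):
        g = GeneModel("g", "c1", 10_001, 20_000, "+")
        p = partition_gene(g, flank=5000)
        assert p.upstream == (5_001, 10_000)
        assert p.downstream == (10_001, 15_000)
        assert p.body == (10_001, 20_000)

    def test_minus_strand_mirrors(self):
        g = GeneModel("g", "c1", 10_001, 20_000, "-")
        p = partition_gene(g, flank=5000)
        assert p.upstream == (20_001, 25_000)
        assert p.downstream == (15_001, 20_000)

    def test_tss_at_origin_clips_upstream_empty(self):
        g = GeneModel("g", "c1", 1, 500, "+")
        p = partition_gene(g, flank=5000)
        assert p.upstream is None
        assert p.downstream == (1, 5000)

    def test_chromosome_end_clips(self):
        g = GeneModel("g", "c1", 900, 1000, "-")
        p = partition_gene(g, flank=500, chrom_length=1000)
        assert p.upstream is None  # (1001, 1500) clipped away

    def test_bad_flank(self):
        with pytest.raises(ValueError, match="flank"):
            partition_gene(GeneModel("g", "c1", 1, 10, "+"), flank=0)


@pytest.fixture
def genome3():
    return bin_genome([("c1", 3_000_000)], window=1_000_000)


class TestAggregateSignal:
    def test_seven_body_reads_give_log2_eight(self, genome3):
        genes = [GeneModel("g1", "c1", 100_001, 200_000, "+")]
        reads = pd.DataFrame(
            {"chrom": ["c1"] * 7, "start": np.arange(110_000, 117_000, 1000),
             "end": np.arange(110_100, 117_100, 1000)}
        )
        s = aggregate_signal(reads, genes, genome3, part="body")
        assert s.gene_values["g1"] == pytest.approx(3.0)  # log2(7 + 1)
        assert s.bin_values[0] == pytest.approx(3.0)

    def test_zero_reads_give_zero_log(self, genome3):
        genes = [GeneModel("g1", "c1", 100_001, 200_000, "+")]
        reads = pd.DataFrame(columns=["chrom", "start", "end"])
        s = aggregate_signal(reads, genes, genome3, part="body")
        assert s.bin_values[0] == pytest.approx(0.0)  # log2(0 + 1)

    def test_geneless_bins_excluded(self, genome3):
        genes = [GeneModel("g1", "c1", 100_001, 200_000, "+")]
        s = aggregate_signal(
            pd.DataFrame(columns=["chrom", "start", "end"]), genes, genome3, "body"
        )
        assert s.excluded_bins.tolist() == [False, True, True]
        assert np.isnan(s.bin_values[1])

    def test_excluded_set_stable_across_marks_and_conditions(self, genome3):
        genes = [
            GeneModel("g1", "c1", 100_001, 200_000, "+"),
            GeneModel("g2", "c1", 2_100_001, 2_200_000, "-"),
        ]
        excl = []
        for counts in (pd.Series({"g1": 0, "g2": 9}), pd.Series({"g1": 7, "g2": 2})):
            s = summarize_gene_counts(counts, genes, genome3)
            excl.append(s.excluded_bins.tolist())
        assert excl[0] == excl[1] == [False, True, False]


class TestEnrichment:
    def make_summaries(self, values_t0, values_t1, genome):
        genes = [
            GeneModel(f"g{i}", "c1", 1 + i, 10 + i, "+") for i in range(len(values_t0))
        ]
        s0 = summarize_gene_counts(
            pd.Series(values_t0, index=[g.name for g in genes]), genes, genome
        )
        s1 = summarize_gene_counts(
            pd.Series(values_t1, index=[g.name for g in genes]), genes, genome
        )
        return s0, s1, {g.name for g in genes}

    def test_identical_conditions_flat(self, genome3):
        vals = list(range(10, 40))
        s0, s1, names = self.make_summaries(vals, vals, genome3)
        (res,) = enrichment_test(s1, s0, {"gain-intra": names})
        assert res.statistic == 0.0 and res.pvalue == 1.0 and res.direction == 0

    def test_planted_shift_recovered(self, genome3):
        rng = np.random.default_rng(8)
        base = rng.poisson(50, size=200)
        shifted = rng.poisson(100, size=200)  # +1 log2 unit
        s0, s1, names = self.make_summaries(base, shifted, genome3)
        (t_res,) = enrichment_test(s1, s0, {"gain-intra": names}, test="t")
        assert t_res.statistic > 0 and t_res.pvalue < 0.01 and t_res.direction == 1
        (u_res,) = enrichment_test(s1, s0, {"gain-intra": names}, test="mann-whitney")
        assert u_res.direction == t_res.direction and u_res.pvalue < 0.01

    def test_statistic_sign_tracks_mean_difference(self, genome3):
        rng = np.random.default_rng(9)
        for _ in range(10):
            a = rng.poisson(40, size=30)
            b = rng.poisson(45, size=30)
            s0, s1, names = self.make_summaries(a, b, genome3)
            (res,) = enrichment_test(s1, s0, {"x": names})
            diff = s1.gene_values.mean() - s0.gene_values.mean()
            if res.statistic != 0:
                assert np.sign(res.statistic) == np.sign(diff) == res.direction

    def test_small_set_undefined(self, genome3):
        s0, s1, _ = self.make_summaries([1, 2, 3], [4, 5, 6], genome3)
        (res,) = enrichment_test(s1, s0, {"gain-intra": {"g0"}})
        assert res.undefined and np.isnan(res.statistic)

    def test_table_attaches_bh_qvalues(self, genome3):
        s0, s1, names = self.make_summaries(range(30), range(1, 31), genome3)
        results = enrichment_test(s1, s0, {"a": names, "b": set()})
        df = enrichment_table(results)
        assert {"qvalue", "statistic", "pvalue"} <= set(df.columns)
        assert df.loc[df["type"] == "a", "qvalue"].notna().all()
        assert df.loc[df["type"] == "b", "qvalue"].isna().all()


class TestPeaks:
    def test_hand_midpoint_assignment(self, genome3):
        peaks = pd.DataFrame(
            {
                "chrom": ["c1"] * 3,
                "start": [100, 900_000, 2_100_000],
                "end": [300, 999_999, 2_100_400],
            }
        )
        counts = peaks_per_bin(peaks, genome3)
        assert counts.tolist() == [2, 0, 1]

    def test_no_peaks_association_undefined(self, genome3):
        counts = peaks_per_bin(pd.DataFrame(columns=["chrom", "start", "end"]), genome3)
        assert counts.tolist() == [0, 0, 0]
        prof = FrequencyProfile(
            genome=genome3, counts=np.array([1, 2, 3]),
            frequency=np.array([0.1, 0.2, 0.3]),
        )
        rho, p = rank_association(counts, prof)
        assert np.isnan(rho) and np.isnan(p)


class TestBreakpoints:
    def test_zero_overlap_tail_is_one(self, genome3):
        bp = pd.DataFrame({"chrom": ["c1"] * 50, "pos": [1_500_000] * 50})
        res = breakpoint_overlap(bp, [0], genome3)
        assert res.overlap == 0 and res.pvalue == pytest.approx(1.0)

    def test_all_inside_closed_form(self, genome3):
        n = 5
        bp = pd.DataFrame({"chrom": ["c1"] * n, "pos": [10] * n})
        res = breakpoint_overlap(bp, [0], genome3)
        assert res.pvalue == pytest.approx((1 / 3) ** n, rel=1e-9)

    def test_tail_monotone_in_overlap(self):
        tails = [binomial_tail_log10(k, 100, 0.1) for k in range(0, 40, 5)]
        assert all(a > b for a, b in zip(tails, tails[1:]))

    def test_empty_hot_set_rejected(self, genome3):
        with pytest.raises(ValueError, match="hot"):
            breakpoint_overlap(pd.DataFrame({"chrom": ["c1"], "pos": [1]}), [], genome3)

    def test_hypergeometric_alternative(self, genome3):
        bp = pd.DataFrame({"chrom": ["c1"] * 2, "pos": [10, 1_200_000]})
        res = breakpoint_overlap(bp, [0], genome3, method="hypergeometric")
        assert res.method == "hypergeometric" and 0 < res.pvalue <= 1


class TestExpression:
    def test_identity_and_affine_invariance(self):
        x = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        assert expression_correlation(x, x)[0] == pytest.approx(1.0)
        assert expression_correlation(x, 2 * x)[0] == pytest.approx(1.0)

    def test_hand_computed_pearson(self):
        x = pd.Series([1.0, 2, 3, 4], index=list("abcd"))
        y = pd.Series([2.0, 1, 4, 3], index=list("abcd"))
        xc, yc = x - x.mean(), y - y.mean()
        oracle = float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
        r, n = expression_correlation(x, y)
        assert r == pytest.approx(oracle, abs=1e-12) and n == 4

    def test_too_few_shared_genes(self):
        x = pd.Series([1.0, 2], index=list("ab"))
        with pytest.raises(ValueError, match="3"):
            expression_correlation(x, x)

    def test_zero_variance_undefined(self):
        x = pd.Series([1.0, 1, 1], index=list("abc"))
        y = pd.Series([1.0, 2, 3], index=list("abc"))
        assert np.isnan(expression_correlation(x, y)[0])


class TestChiSquare:
    def test_equal_proportions_flat(self):
        all_genes = [f"g{i}" for i in range(100)]
        region = set(all_genes[:50])
        de = set(all_genes[:10]) | set(all_genes[50:60])  # 20% everywhere
        res = de_enrichment_chisq(de, region, all_genes)
        assert res.statistic == pytest.approx(0.0) and res.pvalue == pytest.approx(1.0)

    def test_textbook_table_against_hand_oracle(self):
        # table [[30, 70], [10, 90]]
        all_genes = [f"g{i}" for i in range(200)]
        region = set(all_genes[:100])
        de = set(all_genes[:30]) | set(all_genes[100:110])
        res = de_enrichment_chisq(de, region, all_genes)
        obs = np.array([[30, 70], [10, 90]], dtype=float)
        row, col = obs.sum(1, keepdims=True), obs.sum(0, keepdims=True)
        exp = row @ col / obs.sum()
        oracle = float(((obs - exp) ** 2 / exp).sum())
        assert np.array_equal(res.table, obs)
        assert res.statistic == pytest.approx(oracle, rel=1e-12)
        assert res.pvalue < 0.01

    def test_empty_de_set(self):
        all_genes = [f"g{i}" for i in range(20)]
        res = de_enrichment_chisq([], set(all_genes[:10]), all_genes)
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_region_must_be_subset(self):
        with pytest.raises(ValueError, match="subset"):
            de_enrichment_chisq([], {"zz"}, ["a", "b"])
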