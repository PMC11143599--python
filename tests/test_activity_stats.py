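import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from conftest import nb_counts
from enact.activity_stats import (
    bh_fdr,
    filter_low_expression,
    kmeans_profiles,
    lrt_any_change,
    nbql_test,
    quantify_regions,
    rle_size_factors,
)
from enact.core_io import CountMatrix, GenomicInterval, StrandedCoverage


def coverage_from(plus, chrom="chr1"):
    n = len(plus)
    cov = StrandedCoverage.zeros({chrom: n})
    cov.plus[chrom][:] = plus
    return cov


class TestQuantifyRegions:
    def test_per_position_cap(self):
        cov = coverage_from([5.0, 1.0, 0.0])
        region = GenomicInterval("chr1", 0, 3, name="r")
        assert quantify_regions(cov, [region], per_position_cap=3)[0] == 4.0

    def test_exon_masking_halves_uniform_signal(self):
        cov = coverage_from(np.ones(1000))
        region = GenomicInterval("chr1", 0, 1000, "+", "g")
        exons = {"g": [GenomicInterval("chr1", 0, 500, "+")]}
        out = quantify_regions(cov, [region], exon_mask=exons, strand_mode="sense")
        assert out[0] == 500.0

    def test_zero_coverage_region(self):
        cov = coverage_from(np.zeros(100))
        assert quantify_regions(cov, [GenomicInterval("chr1", 10, 50)])[0] == 0.0

    def test_effective_mode_applies_balance_rule(self):
        cov = StrandedCoverage.zeros({"chr1": 100})
        cov.plus["chr1"][:50] = 2.0   # plus 100
        cov.minus["chr1"][:4] = 2.0   # minus 8 -> ratio > 10 -> 2 x 8
        out = quantify_regions(cov, [GenomicInterval("chr1", 0, 100)],
                               strand_mode="effective")
        assert out[0] == 16.0

    def test_no_cap_equals_plain_sums(self):
        rng = np.random.default_rng(0)
        vals = rng.poisson(2.0, 500).astype(float)
        cov = coverage_from(vals)
        regions = [GenomicInterval("chr1", i * 50, i * 50 + 50) for i in range(10)]
        out = quantify_regions(cov, regions)
        expect = [vals[i * 50 : i * 50 + 50].sum() for i in range(10)]
        np.testing.assert_allclose(out, expect)

    def test_cap_below_one_errors(self):
        cov = coverage_from(np.ones(10))
        with pytest.raises(ValueError):
            quantify_regions(cov, [GenomicInterval("chr1", 0, 5)], per_position_cap=0)


class TestFilterLowExpression:
    def _matrix(self, rows):
        arr = np.array(rows, dtype=float)
        return CountMatrix(
            [f"f{i}" for i in range(arr.shape[0])],
            [f"s{j}" for j in range(arr.shape[1])],
            arr,
        )

    def test_raw_cutoff_five_in_two_samples(self):
        m = self._matrix([[6, 7, 0], [6, 0, 0], [0, 0, 0]])
        out = filter_low_expression(m, 5.0, min_samples=2, unit="raw")
        assert out.feature_ids == ["f0"]

    def test_rpkm_requires_lengths(self):
        m = self._matrix([[10, 10]])
        with pytest.raises(ValueError):
            filter_low_expression(m, 0.5, unit="cpm", rpkm_cutoff=0.5)


class TestRLE:
    def test_identical_samples_unit_factors(self):
        m = CountMatrix(["a", "b"], ["s1", "s2"], np.array([[10, 10], [20, 20]]))
        f = rle_size_factors(m)
        assert f["s1"] == pytest.approx(1.0) and f["s2"] == pytest.approx(1.0)

    def test_doubled_sample(self):
        m = CountMatrix(["a", "b", "c"], ["s1", "s2"],
                        np.array([[10, 20], [30, 60], [7, 14]]))
        f = rle_size_factors(m)
        assert f["s1"] == pytest.approx(1 / np.sqrt(2))
        assert f["s2"] == pytest.approx(np.sqrt(2))

    def test_zero_containing_feature_excluded_from_reference(self):
        # feature b has a zero: factors determined by a and c only
        m = CountMatrix(["a", "b", "c"], ["s1", "s2"],
                        np.array([[10, 10], [0, 1000], [30, 30]]))
        f = rle_size_factors(m)
        assert f["s1"] == pytest.approx(1.0) and f["s2"] == pytest.approx(1.0)

    def test_no_allpositive_feature_errors(self):
        m = CountMatrix(["a"], ["s1", "s2"], np.array([[0, 5]]))
        with pytest.raises(ValueError, match="pseudo-reference"):
            rle_size_factors(m)

    def test_scaling_one_sample_scales_its_factor(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(50, size=(200, 3)) + 1
        m1 = CountMatrix([f"f{i}" for i in range(200)], ["a", "b", "c"], base)
        scaled = base.astype(float).copy()
        scaled[:, 1] *= 3.0
        m2 = CountMatrix([f"f{i}" for i in range(200)], ["a", "b", "c"], scaled)
        f1, f2 = rle_size_factors(m1), rle_size_factors(m2)
        # ratio of factors for sample b is 3 up to the geometric-mean rescale
        rescale = (f2["a"] / f1["a"])
        assert f2["b"] / f1["b"] / rescale == pytest.approx(3.0, rel=1e-9)


class TestNBQL:
    def test_constant_feature_log2fc_zero(self):
        y = np.array([[50, 50, 50, 50, 50, 50], [30, 30, 30, 30, 30, 30]])
        m = CountMatrix(["const", "other"], list("abcdef"), y)
        res = nbql_test(m, ["A"] * 3 + ["B"] * 3)
        assert res.loc[res.feature == "const", "log2FC"].abs().iloc[0] < 1e-6

    def test_all_zero_feature_p_one(self):
        y = np.array([[0, 0, 0, 0, 0, 0], [10, 20, 15, 40, 50, 45]])
        m = CountMatrix(["zero", "var"], list("abcdef"), y)
        res = nbql_test(m, ["A"] * 3 + ["B"] * 3)
        assert res.loc[res.feature == "zero", "pvalue"].iloc[0] == 1.0

    def test_requires_two_samples_per_condition(self):
        m = CountMatrix(["f"], list("abc"), np.array([[1, 2, 3]]))
        with pytest.raises(ValueError):
            nbql_test(m, ["A", "B", "B"])

    def test_null_pvalues_uniform(self):
        """Type-I control and KS uniformity on 2000 null NB features."""
        rng = np.random.default_rng(11)
        y = nb_counts(rng, 100.0, 0.1, (2000, 6))
        m = CountMatrix([f"f{i}" for i in range(2000)], list("abcdef"), y)
        p = nbql_test(m, ["A"] * 3 + ["B"] * 3)["pvalue"].to_numpy()
        assert 0.035 <= np.mean(p < 0.05) <= 0.065
        assert stats.kstest(p, "uniform").statistic < 0.05

    def test_power_on_planted_fourfold(self):
        """>= 90% of planted 4-fold features recalled at BH q < 0.1."""
        rng = np.random.default_rng(11)
        mu = np.full((2000, 6), 100.0)
        mu[1800:, 3:] = 400.0
        y = nb_counts(rng, mu, 0.05, mu.shape)
        m = CountMatrix([f"f{i}" for i in range(2000)], list("abcdef"), y)
        res = nbql_test(m, ["A"] * 3 + ["B"] * 3, size_factors=rle_size_factors(m))
        assert np.mean(res["qvalue"].to_numpy()[1800:] < 0.1) >= 0.9


class TestLRT:
    def test_single_condition_errors(self):
        m = CountMatrix(["f"], list("ab"), np.array([[1, 2]]))
        with pytest.raises(ValueError):
            lrt_any_change(m, ["A", "A"])

    def test_power_on_threefold_shift(self):
        """One condition shifted 3-fold is detected at q < 0.001 with power >= 0.8."""
        power = 0.0
        reps = 20
        for s in range(reps):
            rng = np.random.default_rng(100 + s)
            mu = np.full((300, 6), 200.0)
            mu[:30, 4:] = 600.0
            y = nb_counts(rng, mu, 0.05, mu.shape)
            m = CountMatrix([f"g{i}" for i in range(300)], list("abcdef"), y)
            res = lrt_any_change(m, ["A", "A", "B", "B", "C", "C"],
                                 size_factors=rle_size_factors(m))
            power += np.mean(res["qvalue"].to_numpy()[:30] < 0.001)
        assert power / reps >= 0.8

    def test_null_type_one_error(self):
        rng = np.random.default_rng(500)
        y = nb_counts(rng, 200.0, 0.05, (500, 6))
        m = CountMatrix([f"g{i}" for i in range(500)], list("abcdef"), y)
        res = lrt_any_change(m, ["A", "A", "B", "B", "C", "C"],
                             size_factors=rle_size_factors(m))
        rate = np.mean(res["pvalue"] < 0.05)
        # binomial interval around 0.05 at n=500
        assert abs(rate - 0.05) < 2.5 * np.sqrt(0.05 * 0.95 / 500) + 1e-12


class TestKMeans:
    def test_separated_blocks_recovered_exactly(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 0.1, size=(40, 4)) + np.array([5, 5, -5, -5])
        b = rng.normal(0, 0.1, size=(20, 4)) + np.array([-5, -5, 5, 5])
        z = np.vstack([a, b])
        labels = kmeans_profiles(z, k=2, seed=0)
        true = np.array([0] * 40 + [1] * 20)
        assert adjusted_rand_score(true, labels) == 1.0
        # labels renumbered by size: the larger block is cluster 0
        assert labels[0] == 0

    def test_k_one_single_label(self):
        z = np.random.default_rng(0).normal(size=(10, 3))
        assert set(kmeans_profiles(z, k=1, seed=0)) == {0}

    def test_same_seed_identical(self):
        z = np.random.default_rng(0).normal(size=(50, 4))
        a = kmeans_profiles(z, k=6, seed=3)
        b = kmeans_profiles(z, k=6, seed=3)
        assert np.array_equal(a, b)

    def test_invalid_k(self):
        z = np.zeros((5, 2))
        with pytest.raises(ValueError):
            kmeans_profiles(z, k=0)
        with pytest.raises(ValueError):
            kmeans_profiles(z, k=10)


def brute_force_bh(p):
    """Literal step-up: q_(i) = min_{j >= i} p_(j) * m / j, capped at 1."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_idx in range(m):
        best = 1.0
        for j in range(rank_idx, m):
            best = min(best, p[order[j]] * m / (j + 1))
        q[order[rank_idx]] = best
    return q


class TestBH:
    def test_textbook_vector(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones(self):
        assert np.all(bh_fdr([1.0, 1.0, 1.0]) == 1.0)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 30))
            np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_statsmodels_reference(self, p):
        from statsmodels.stats.multitest import multipletests

        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(bh_fdr(p), q_ref, atol=1e-12)
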