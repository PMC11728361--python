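import numpy as np
import pytest
from hypothesis import given, strategies as st

from echotex.errors import ValidationError
from echotex.stats import (
    classify_strength,
    grade_comparison,
    min_max_normalize,
    pearson_with_p,
    pooled_pearson_from_group_stats,
)

# published per-grade EV summary (sizes, mean, SD for grades 1-4)
GROUP_NS = [24, 58, 24, 24]
GROUP_MEANS = [67.28, 46.62, 37.16, 26.85]
GROUP_SDS = [15.05, 7.17, 4.94, 4.06]


class TestMinMaxNormalize:
    def test_affine_rescale(self):
        np.testing.assert_allclose(min_max_normalize([10, 20, 30]), [0, 0.5, 1])

    def test_constant_column_maps_to_zero(self):
        np.testing.assert_array_equal(min_max_normalize([5, 5, 5]), [0, 0, 0])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=30, unique=True))
    def test_pearson_invariant_under_normalization(self, xs):
        x = np.array(xs)
        y = np.sin(x) + 0.1 * x  # arbitrary non-constant companion
        if np.ptp(y) == 0:
            return
        r_raw = pearson_with_p(x, y).r
        r_norm = pearson_with_p(min_max_normalize(x), min_max_normalize(y)).r
        assert r_norm == pytest.approx(r_raw, abs=1e-9)


class TestPearsonWithP:
    def test_perfect_positive_affine(self):
        x = np.arange(10.0)
        assert pearson_with_p(x, 2 * x + 1).r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(10.0)
        assert pearson_with_p(x, -x).r == pytest.approx(-1.0)

    def test_hand_computed_r_and_t_tail(self):
        res = pearson_with_p([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.r == pytest.approx(0.6)
        assert res.p_value == pytest.approx(0.4, abs=1e-9)
        assert res.n == 4

    def test_constant_column_named_in_error(self):
        with pytest.raises(ValidationError, match="ev_column"):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], name="ev_column")


class TestClassifyStrength:
    @pytest.mark.parametrize(
        "r,label",
        [
            (-0.81, "very strong"),
            (0.87, "very strong"),
            (0.80, "very strong"),
            (0.79, "moderately strong"),
            (0.60, "moderately strong"),
            (-0.37, "moderate"),
            (0.30, "moderate"),
            (0.29, "weak"),
            (0.0, "weak"),
        ],
    )
    def test_bands(self, r, label):
        assert classify_strength(r) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            classify_strength(1.5)


class TestPooledPearson:
    def test_equal_group_means_give_zero(self):
        r = pooled_pearson_from_group_stats([5, 5], [10.0, 10.0], [2.0, 3.0], [1, 2])
        assert r == pytest.approx(0.0, abs=1e-15)

    def test_published_grade_summary_reproduces_reported_r(self):
        r = pooled_pearson_from_group_stats(GROUP_NS, GROUP_MEANS, GROUP_SDS, [1, 2, 3, 4])
        assert round(r, 2) == -0.81
        assert r == pytest.approx(-0.8086, abs=5e-4)

    def test_vanishing_within_group_spread_separates_fully(self):
        r = pooled_pearson_from_group_stats([8, 8], [0.0, 10.0], [1e-9, 1e-9], [1, 2])
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_matches_direct_pearson_on_constructed_data(self, rng):
        """Two-point groups {m-s, m+s} realise any (mean, population-SD)
        pair exactly, so the closed form must match scipy on them."""
        from scipy.stats import pearsonr

        for _ in range(20):
            means = rng.normal(50, 20, size=4)
            sds = rng.uniform(0.5, 10, size=4)
            g_values = np.arange(1.0, 5.0)
            x = np.repeat(g_values, 2)
            y = np.concatenate([[m - s, m + s] for m, s in zip(means, sds)])
            expected = pearsonr(x, y).statistic
            got = pooled_pearson_from_group_stats([2] * 4, means, sds, g_values)
            assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_total_variance_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            pooled_pearson_from_group_stats([3, 3], [5.0, 5.0], [0.0, 0.0], [1, 2])


class TestGradeComparison:
    def test_kruskal_level_under_the_null(self):
        """Omnibus rejection rate at alpha=0.05 stays within 0.05 +- 0.02
        over 1000 identical-distribution cohorts."""
        rng = np.random.default_rng(2024)
        rejections = 0
        grades = np.repeat([1, 2, 3, 4], [24, 58, 24, 24])
        for _ in range(1000):
            values = rng.normal(size=grades.size)
            res = grade_comparison(values, grades, method="kruskal")
            rejections += res.p_value < 0.05
        assert rejections / 1000 == pytest.approx(0.05, abs=0.02)

    def test_published_group_parameters_fully_separated(self):
        """A cohort drawn from the published per-grade EV distributions
        shows all six Bonferroni-adjusted pairwise differences < 0.001."""
        rng = np.random.default_rng(7)
        values = np.concatenate(
            [rng.normal(m, s, n) for n, m, s in zip(GROUP_NS, GROUP_MEANS, GROUP_SDS)]
        )
        grades = np.repeat([1, 2, 3, 4], GROUP_NS)
        res = grade_comparison(values, grades)
        assert res.p_value < 0.001
        assert len(res.pairwise) == 6
        assert all(p.p_adjusted < 0.001 for p in res.pairwise)

    def test_two_shifted_groups_detected(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(0, 1, 50), rng.normal(5, 1, 50)])
        grades = np.repeat([1, 2], 50)
        res = grade_comparison(values, grades)
        assert len(res.pairwise) == 1 and res.pairwise[0].significant

    def test_bonferroni_never_decreases_p(self, rng):
        values = rng.normal(size=40)
        grades = np.repeat([1, 2, 3, 4], 10)
        res = grade_comparison(values, grades, method="kruskal")
        for p in res.pairwise:
            assert p.p_adjusted >= p.p_raw
            assert p.p_adjusted == pytest.approx(min(1.0, 6 * p.p_raw))

    def test_normality_gate_routes_heavy_tails_to_kruskal(self):
        # deterministic samples: normal quantiles pass Shapiro-Wilk,
        # lognormal quantiles fail it
        from scipy.stats import norm

        z = norm.ppf((np.arange(30) + 0.5) / 30)
        grades = np.repeat([1, 2, 3], 30)
        gaussianish = np.concatenate([10 + z, 12 + z, 14 + 2 * z])
        assert grade_comparison(gaussianish, grades, method="auto").omnibus_method == "anova"
        heavy = np.concatenate([10 + z, 12 + z, np.exp(2 * z)])
        assert (
            grade_comparison(heavy, grades, method="auto").omnibus_method
            == "kruskal_wallis"
        )

    def test_undersized_group_rejected(self):
        with pytest.raises(ValidationError, match="fewer than 2"):
            grade_comparison([1.0, 2.0, 3.0], [1, 1, 2])
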