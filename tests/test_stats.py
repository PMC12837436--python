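"""Trend regression and the normality-gated comparison decision tree."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from phhkit.errors import DegeneratePredictorError, EmptyInputError
from phhkit.stats import (
    ComparisonTest,
    GroupComparison,
    GroupSample,
    VolumeTrend,
    compare_groups,
    normality_gate,
    trend_from_means,
)
from phhkit.synthetic import DEFAULT_GROUP_MEANS

DAYS = (5, 12, 19, 26)


def closed_form_ols(x, y):
    """Independent oracle: covariance/variance formulas for slope and r."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    sxy = np.mean((x - x.mean()) * (y - y.mean()))
    slope = sxy / np.var(x)
    r = sxy / np.sqrt(np.var(x) * np.var(y))
    return slope, y.mean() - slope * x.mean(), r


class TestTrend:
    @pytest.mark.parametrize("group,slope,r", [
        ("iron", 0.04310, 0.9793),
        ("L-RBC", 0.01495, 0.9900),
    ])
    def test_progressive_groups_reproduce_printed_slopes(self, group, slope, r):
        res = trend_from_means(zip(DAYS, DEFAULT_GROUP_MEANS[group]))
        assert res.slope == pytest.approx(slope, abs=5e-6)
        assert res.pearson_r == pytest.approx(r, abs=1e-4)

    def test_hb_group_slope_to_three_significant_figures(self):
        res = trend_from_means(zip(DAYS, DEFAULT_GROUP_MEANS["Hb"]))
        assert res.slope == pytest.approx(0.0006705, rel=5e-3)

    def test_control_group_slope_is_near_zero(self):
        res = trend_from_means(zip(DAYS, DEFAULT_GROUP_MEANS["control"]))
        assert abs(res.slope) < 1e-4

    def test_exact_line_recovered(self):
        res = trend_from_means([(x, 2.0 * x + 1.0) for x in (0, 1, 2, 5)])
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)
        assert res.pearson_r == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.floats(-50, 50), st.floats(-50, 50)),
                    min_size=3, max_size=12))
    def test_fit_matches_covariance_formula_and_residual_orthogonality(self, points):
        x = np.array([p[0] for p in points])
        y = np.array([p[1] for p in points])
        if np.ptp(x) < 1e-6 or np.ptp(y) < 1e-6:
            return
        res = VolumeTrend(x, y).fit()
        slope_oracle, _, r_oracle = closed_form_ols(x, y)
        assert res.slope == pytest.approx(slope_oracle, rel=1e-9, abs=1e-12)
        assert res.pearson_r == pytest.approx(r_oracle, rel=1e-9, abs=1e-12)
        residuals = y - res.predict(x)
        assert float(residuals @ (x - x.mean())) == pytest.approx(0.0, abs=1e-6)

    def test_pearson_r_invariant_to_affine_rescaling(self):
        x = np.array(DAYS, float)
        y = np.array(DEFAULT_GROUP_MEANS["iron"])
        base = VolumeTrend(x, y).fit().pearson_r
        rescaled = VolumeTrend(3.0 * x - 7.0, 1000.0 * y + 2.0).fit().pearson_r
        assert rescaled == pytest.approx(base)

    def test_constant_response_flags_undefined_r(self):
        with pytest.warns(UserWarning, match="constant response"):
            res = VolumeTrend([1, 2, 3], [0.5, 0.5, 0.5]).fit()
        assert res.slope == 0.0 and not res.r_defined and np.isnan(res.pearson_r)

    def test_identical_days_raise(self):
        with pytest.raises(DegeneratePredictorError):
            VolumeTrend([7, 7, 7], [1, 2, 3])


class TestNormalityGate:
    def test_gaussian_samples_mostly_route_parametric(self):
        rng = np.random.default_rng(42)
        hits = sum(
            normality_gate([GroupSample("g", rng.normal(size=100))])[0] == "parametric"
            for _ in range(100))
        assert hits >= 90  # Shapiro-Wilk nominal level 0.05 per group

    def test_gross_non_normality_routes_nonparametric(self):
        rng = np.random.default_rng(0)
        values = np.where(rng.random(50) < 0.5, 0.0, 10.0) + rng.normal(0, 0.01, 50)
        route, trace = normality_gate([GroupSample("mix", values)])
        assert route == "nonparametric"
        assert trace.shapiro_p["mix"] < 0.05

    def test_tiny_group_routes_nonparametric_with_warning(self):
        groups = [GroupSample("tiny", [1.0, 1.0, 1.0][:2]),
                  GroupSample("big", np.random.default_rng(3).normal(size=30))]
        with pytest.warns(UserWarning, match="n < 3"):
            route, trace = normality_gate(groups)
        assert route == "nonparametric"
        assert trace.shapiro_p["tiny"] is None
        assert "tiny" in trace.small_groups


class TestCompareGroups:
    @staticmethod
    def gaussian(rng, n=20, loc=0.0, scale=1.0):
        return rng.normal(loc, scale, n)

    @staticmethod
    def heavy(rng, n=50, loc=0.0):
        return loc + np.where(rng.random(n) < 0.5, 0.0, 10.0) + rng.normal(0, 0.01, n)

    def test_identical_groups_give_p_one(self):
        values = np.random.default_rng(1).normal(size=15)
        res = compare_groups({"a": values, "b": values.copy()})
        assert res.omnibus_p == pytest.approx(1.0)

    def test_two_parametric_groups_use_t_test(self):
        rng = np.random.default_rng(10)
        res = compare_groups({"a": self.gaussian(rng), "b": self.gaussian(rng, loc=0.3)})
        assert res.gate_trace.route == "parametric"
        assert res.test_chosen is ComparisonTest.T_TEST

    def test_equal_spread_parametric_groups_use_anova_tukey(self):
        rng = np.random.default_rng(11)
        res = compare_groups({k: self.gaussian(rng, n=25) for k in "abc"})
        assert res.test_chosen is ComparisonTest.ONEWAY_ANOVA_TUKEY
        assert res.gate_trace.variance_gate_p >= 0.05
        assert len(res.posthoc) == 3  # all pairs

    def test_unequal_spread_routes_to_bf_welch_dunnett(self):
        rng = np.random.default_rng(12)
        res = compare_groups({"control": self.gaussian(rng, n=25, scale=1.0),
                              "a": self.gaussian(rng, n=25, scale=1.0),
                              "b": self.gaussian(rng, n=25, scale=12.0)})
        assert res.test_chosen is ComparisonTest.BF_WELCH_ANOVA_DUNNETT
        assert res.gate_trace.variance_gate_p < 0.05
        assert res.extras["dunnett_control"] == "control"
        assert {e.pair[0] for e in res.posthoc} == {"control"}
        assert "brown_forsythe_anova_p" in res.extras

    def test_two_nonnormal_groups_use_mann_whitney(self):
        rng = np.random.default_rng(13)
        res = compare_groups({"a": self.heavy(rng), "b": self.heavy(rng, loc=1.0)})
        assert res.test_chosen is ComparisonTest.MANN_WHITNEY

    def test_four_nonnormal_groups_use_kruskal_dunn(self):
        rng = np.random.default_rng(14)
        res = compare_groups({k: self.heavy(rng) for k in "abcd"})
        assert res.test_chosen is ComparisonTest.KRUSKAL_WALLIS_DUNN
        assert len(res.posthoc) == 6

    def test_decision_is_deterministic_and_replayable(self):
        rng = np.random.default_rng(15)
        data = {k: self.heavy(rng) for k in "abcd"}
        r1, r2 = compare_groups(data), compare_groups(data)
        assert r1.test_chosen is r2.test_chosen
        assert r1.omnibus_p == r2.omnibus_p
        assert r1.gate_trace == r2.gate_trace

    def test_dunn_adjustment_is_never_anticonservative(self):
        rng = np.random.default_rng(16)
        res = compare_groups({k: self.heavy(rng, loc=i * 0.5)
                              for i, k in enumerate("abcd")})
        assert res.test_chosen is ComparisonTest.KRUSKAL_WALLIS_DUNN
        for entry in res.posthoc:
            unadjusted = 2.0 * sps.norm.sf(abs(entry.statistic))
            assert entry.p_adj >= unadjusted - 1e-12
            assert 0.0 <= entry.p_adj <= 1.0

    def test_mann_whitney_is_symmetric_in_group_order(self):
        rng = np.random.default_rng(17)
        a, b = self.heavy(rng), self.heavy(rng, loc=0.7)
        assert (compare_groups({"a": a, "b": b}).omnibus_p
                == compare_groups({"b": b, "a": a}).omnibus_p)

    def test_empty_group_rejected(self):
        with pytest.raises(EmptyInputError):
            GroupSample("empty", [])
        with pytest.raises(EmptyInputError):
            GroupComparison({"only": [1.0, 2.0]})

    def test_summary_names_the_gate_and_test(self):
        rng = np.random.default_rng(18)
        text = compare_groups({k: self.heavy(rng) for k in "abcd"}).summary()
        assert "Shapiro-Wilk" in text and "kruskal_wallis_dunn" in text
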