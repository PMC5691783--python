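"""Reaction-norm fitting, nested model comparison and group tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.base import clone

from camonorm.stats import (PolynomialReactionNorm, ReactionNormFit,
                            ResponseRecord, compare_nested_fits,
                            drop_most_variable_and_retest, fit_polynomials,
                            levene_test, nested_anova, one_way_anova,
                            records_to_frame, reference_responses,
                            select_best)


def make_records(x, y, boxes_per_treatment=1):
    recs = []
    levels = {v: f"T{i}" for i, v in enumerate(sorted(set(x)))}
    for i, (xi, yi) in enumerate(zip(x, y)):
        t = levels[xi]
        recs.append(ResponseRecord(f"s{i}", t, f"{t}-b1", float(xi), float(yi)))
    return recs


class TestFitPolynomials:
    def test_exact_line_recovered(self):
        x = np.array([0.0, 1, 2, 3, 4])
        fits = fit_polynomials(x, 2 + 3 * x, orders=[1])
        f = fits[0]
        assert f.coefficients == pytest.approx([2.0, 3.0], abs=1e-10)
        assert f.r2 == pytest.approx(1.0)

    def test_noiseless_cubic_identity(self):
        x = np.tile(np.linspace(-1, 1, 5), 4)
        y = x**3 - x
        fits = fit_polynomials(x, y, orders=[1, 3])
        by_order = {f.order: f for f in fits}
        assert by_order[3].r2 == pytest.approx(1.0, abs=1e-12)
        assert by_order[1].r2 < 1.0
        assert by_order[3].coefficients == pytest.approx([0, -1, 0, 1],
                                                         abs=1e-8)

    def test_order4_matches_normal_equations_oracle(self, rng):
        x = rng.uniform(0, 2, 60)
        y = rng.normal(size=60)
        (fit,) = fit_polynomials(x, y, orders=[4])
        X = np.vander(x, 5, increasing=True)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.coefficients == pytest.approx(beta, abs=1e-8)

    def test_r2_nondecreasing_in_order(self, rng):
        x = rng.uniform(0, 1, 80)
        y = np.sin(3 * x) + rng.normal(0, 0.2, 80)
        fits = fit_polynomials(x, y, orders=[1, 2, 3, 4])
        r2s = [f.r2 for f in fits]
        assert np.all(np.diff(r2s) >= -1e-12)

    def test_insufficient_levels_skips_order_with_warning(self):
        x = np.tile([0.0, 0.5, 1.0, 1.5, 2.0], 10)
        y = x.copy()
        with pytest.warns(UserWarning, match="order 4 skipped"):
            fits = fit_polynomials(x, y, orders=[1, 2, 3, 4])
        assert [f.order for f in fits] == [1, 2, 3]

    def test_records_input_equivalent(self, rng):
        x = np.tile([0.0, 1.0, 2.0, 3.0, 4.0, 5.0], 5)
        y = rng.normal(size=x.size)
        direct = fit_polynomials(x, y, orders=[2])[0]
        via_records = fit_polynomials(make_records(x, y), orders=[2])[0]
        assert via_records.coefficients == pytest.approx(direct.coefficients)


class TestCompareNested:
    def _fit(self, order, rss, n=30, tss=10.0):
        p = order + 1
        return ReactionNormFit(order, np.zeros(p), np.zeros(p),
                               np.zeros((p, p)), 0.5, 0.5, rss, tss,
                               np.zeros(n), n)

    def test_identical_rss_gives_zero_f(self):
        tbl = compare_nested_fits([self._fit(1, 4.0), self._fit(2, 4.0)])
        assert tbl.loc[0, "f"] == 0.0

    def test_zero_residual_higher_order_flagged_infinite(self):
        x = np.tile(np.linspace(0, 1, 6), 5)
        y = 1 + x - 2 * x**2 + 0.5 * x**3
        fits = fit_polynomials(x, y, orders=[2, 3])
        tbl = compare_nested_fits(fits)
        assert np.isinf(tbl.loc[0, "f"]) and bool(tbl.loc[0, "degenerate"])

    def test_matches_hand_computed_extra_ss(self, rng):
        x = np.tile(np.linspace(0, 1, 8), 6)
        y = 2 * x + rng.normal(0, 0.3, x.size)
        fits = fit_polynomials(x, y, orders=[1, 2])
        tbl = compare_nested_fits(fits)
        rss1, rss2 = fits[0].rss, fits[1].rss
        df2 = x.size - 3
        f_hand = (rss1 - rss2) / (rss2 / df2)
        assert tbl.loc[0, "f"] == pytest.approx(f_hand)
        assert tbl.loc[0, "p"] == pytest.approx(sps.f.sf(f_hand, 1, df2))

    def test_non_nested_inputs_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            compare_nested_fits([self._fit(2, 1.0), self._fit(1, 2.0)])
        with pytest.raises(ValueError, match="identical data"):
            compare_nested_fits([self._fit(1, 2.0, n=30),
                                 self._fit(2, 1.0, n=40)])


class TestSelectBest:
    def test_noise_free_cubic_selects_three(self):
        x = np.tile(np.linspace(0, 1, 7), 4)
        y = 1 - 2 * x + 0.5 * x**3
        fits = fit_polynomials(x, y, orders=[1, 2, 3, 4])
        assert select_best(fits).order == 3

    def test_pure_noise_selects_one(self):
        rng = np.random.default_rng(7)
        x = np.tile(np.linspace(0, 1, 8), 10)
        y = rng.normal(size=x.size)
        fits = fit_polynomials(x, y, orders=[1, 2, 3, 4])
        assert select_best(fits).order == 1

    def test_rationale_and_diagnostics_attached(self, rng):
        x = np.tile(np.linspace(0, 1, 8), 5)
        y = x + rng.normal(0, 0.1, x.size)
        sel = select_best(fit_polynomials(x, y, orders=[1, 2, 3]))
        assert "alpha=0.05" in sel.rationale
        assert set(sel.diagnostics) == {"adj_r2", "residual_runs_z"}


class TestReferenceResponses:
    def test_midpoint_of_linear_curve(self):
        tbl = reference_responses([0.0, 0.5, 1.0], (0.0, 10.0), (1.0, 30.0))
        assert tbl.loc[1, "linear"] == pytest.approx(20.0)

    def test_stepped_below_midpoint_is_low_extreme(self):
        tbl = reference_responses([0.49, 0.5, 0.51], (0.0, 10.0), (1.0, 30.0))
        assert list(tbl["stepped"]) == [10.0, 30.0, 30.0]

    def test_curves_agree_at_extremes(self):
        tbl = reference_responses([0.0, 1.0], (0.0, 10.0), (1.0, 30.0))
        assert np.allclose(tbl["linear"], tbl["stepped"])

    def test_equal_extreme_stimuli_rejected(self):
        with pytest.raises(ValueError):
            reference_responses([0], (0.5, 1.0), (0.5, 2.0))


class TestOneWayAnova:
    def test_identical_groups_f_zero(self):
        res = one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_example(self):
        res = one_way_anova({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        assert res.statistic == pytest.approx(8.0)
        assert res.df == (1, 2)

    def test_matches_scipy(self, rng):
        groups = {f"g{i}": rng.normal(i * 0.3, 1, 40) for i in range(4)}
        res = one_way_anova(groups)
        f, p = sps.f_oneway(*groups.values())
        assert res.statistic == pytest.approx(f)
        assert res.p_value == pytest.approx(p)

    def test_shift_and_scale_invariance(self, rng):
        groups = [rng.normal(0, 1, 30) for _ in range(3)]
        base = one_way_anova(groups)
        shifted = one_way_anova([g + 100 for g in groups])
        scaled = one_way_anova([g * 5.5 for g in groups])
        assert shifted.statistic == pytest.approx(base.statistic)
        assert scaled.statistic == pytest.approx(base.statistic)

    def test_degenerate_zero_within_variance(self):
        res = one_way_anova({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert res.degenerate and np.isinf(res.statistic)


class TestNestedAnova:
    def _balanced(self, rng, trt_eff=0.0, box_sd=0.0, k=4, b=3, m=10):
        recs = []
        for t in range(k):
            for bx in range(b):
                off = rng.normal(0, box_sd) if box_sd else 0.0
                for i in range(m):
                    recs.append(ResponseRecord(
                        f"s{t}{bx}{i}", f"T{t}", f"T{t}-b{bx}",
                        float(t), trt_eff * t + off + rng.normal()))
        return recs

    def test_equals_anova_on_box_means_when_balanced(self, rng):
        recs = self._balanced(rng, trt_eff=0.5, box_sd=0.2)
        res = nested_anova(recs)
        df = records_to_frame(recs)
        box_means = df.groupby(["treatment", "box"])["response"].mean()
        groups = {t: g.to_numpy() for t, g in box_means.groupby("treatment")}
        oneway = one_way_anova(groups)
        assert res.statistic == pytest.approx(oneway.statistic)
        assert res.df == oneway.df

    def test_null_f_near_one_with_large_box_effect(self):
        # treatment effect zero, box effect large: the box-stratum test
        # should stay near its null expectation
        stats_ = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            res = nested_anova(self._balanced(rng, trt_eff=0.0, box_sd=2.0))
            stats_.append(res.statistic)
        # mean of F(3, 8) is 8/6 = 1.33
        assert np.mean(stats_) == pytest.approx(8 / 6, abs=0.45)

    def test_single_box_falls_back_to_one_way(self, rng):
        recs = self._balanced(rng, b=1)
        with pytest.warns(UserWarning, match="one-way"):
            res = nested_anova(recs)
        assert res.method == "one-way ANOVA"

    def test_single_treatment_rejected(self, rng):
        recs = self._balanced(rng, k=1)
        with pytest.raises(ValueError, match=">= 2 treatments"):
            nested_anova(recs)


class TestLevene:
    def test_identical_multisets_w_zero(self):
        res = levene_test({"a": [1, 2, 3, 4], "b": [4, 3, 2, 1]})
        assert res.statistic == 0.0

    def test_symmetric_pairs_degenerate(self):
        res = levene_test({"a": [0.0, 10.0], "b": [4.0, 6.0]})
        assert res.degenerate and np.isinf(res.statistic)

    def test_matches_scipy_brown_forsythe(self, rng):
        groups = [rng.normal(0, s, 35) for s in (1.0, 1.5, 2.5)]
        res = levene_test(groups)
        w, p = sps.levene(*groups, center="median")
        assert res.statistic == pytest.approx(w)
        assert res.p_value == pytest.approx(p)

    def test_group_table_reports_original_medians(self, rng):
        g = {"a": rng.normal(5, 1, 20), "b": rng.normal(9, 3, 20)}
        res = levene_test(g)
        assert res.groups.loc["a", "median"] == pytest.approx(
            np.median(g["a"]))


class TestDropMostVariable:
    def test_highest_variance_group_removed(self, rng):
        groups = {"t1": rng.normal(0, 1, 30), "t2": rng.normal(0, 10, 30),
                  "t3": rng.normal(0, 1, 30)}
        res = drop_most_variable_and_retest(groups)
        assert "dropped most variable group 't2'" in res.note
        assert set(res.groups.index) == {"t1", "t3"}

    def test_tie_breaks_to_lowest_code(self):
        g = {"t2": [0.0, 2.0, 4.0], "t1": [1.0, 3.0, 5.0],
             "t3": [0.0, 0.1, 0.2]}
        res = drop_most_variable_and_retest(g)
        assert "'t1'" in res.note

    def test_needs_three_groups(self):
        with pytest.raises(ValueError, match=">= 3 groups"):
            drop_most_variable_and_retest({"a": [1, 2], "b": [3, 4]})


class TestPolynomialReactionNormEstimator:
    def test_fit_predict_on_cubic(self, rng):
        x = np.tile(np.linspace(0, 1, 8), 10)
        y = 0.2 + 1.5 * x - 2 * x**2 + 1.1 * x**3 + rng.normal(0, 0.02,
                                                               x.size)
        est = PolynomialReactionNorm().fit(x, y)
        assert est.order_ == 3
        assert est.predict([[0.5]])[0] == pytest.approx(
            0.2 + 0.75 - 0.5 + 1.1 / 8, abs=0.02)

    def test_fixed_order_respected(self, rng):
        x = rng.uniform(0, 1, 50)
        y = x + rng.normal(0, 0.1, 50)
        est = PolynomialReactionNorm(order=2).fit(x, y)
        assert est.order_ == 2 and est.selection_ is None

    def test_sklearn_protocol(self, rng):
        est = PolynomialReactionNorm(max_order=3, alpha=0.01)
        params = est.get_params()
        assert params == {"max_order": 3, "order": None, "alpha": 0.01}
        cloned = clone(est)
        assert cloned.get_params() == params
        x = rng.uniform(0, 1, 40)
        y = 2 * x + rng.normal(0, 0.1, 40)
        assert cloned.fit(x, y).score(x, y) > 0.8

    def test_two_column_input_rejected(self, rng):
        est = PolynomialReactionNorm()
        with pytest.raises(ValueError, match="single column"):
            est.fit(rng.uniform(size=(10, 2)), rng.uniform(size=10))
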