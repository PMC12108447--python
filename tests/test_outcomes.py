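"""Logistic regression against closed forms and statsmodels; Kaplan-Meier and
log-rank against hand calculations, lifelines and a permutation oracle."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from betalactam_tdm.outcomes import (
    CURE_MODEL,
    MORTALITY_MODEL,
    ConvergenceError,
    ModelSpec,
    SingularDesignError,
    Term,
    fit_logistic,
    fit_logistic_arrays,
    km_estimate,
    log_rank,
    study_tables,
    tte_prepare,
)
from oracles import permutation_logrank_p, two_sample_logrank_chi2


def two_by_two(n11, n10, n01, n00):
    """exposed events / exposed non-events / unexposed events / unexposed."""
    x = np.repeat([1, 1, 0, 0], [n11, n10, n01, n00])
    y = np.repeat([1, 0, 1, 0], [n11, n10, n01, n00])
    return pd.DataFrame({"exposed": x, "outcome": y})


class TestLogistic:
    def test_univariate_or_equals_cross_product_ratio(self):
        df = two_by_two(10, 90, 20, 80)
        res = fit_logistic(df, ModelSpec("outcome", (Term("exposed", "binary"),)))
        assert res.odds_ratio("exposed") == pytest.approx(
            (10 * 80) / (90 * 20), abs=1e-6)

    def test_null_model_intercept_is_logit_of_event_fraction(self):
        y = np.repeat([1, 0], [30, 70])
        res = fit_logistic_arrays(np.ones((100, 1)), y, ["intercept"])
        assert res.coef("intercept") == pytest.approx(logit(0.3), abs=1e-8)

    def test_constant_predictor_is_singular(self):
        df = two_by_two(10, 90, 20, 80).assign(flat=1.0)
        with pytest.raises(SingularDesignError, match="flat|intercept"):
            fit_logistic(df, ModelSpec("outcome", (Term("flat", "binary"),)))

    def test_separation_raises_diagnostic(self):
        df = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)],
                           "y": np.r_[np.zeros(20), np.ones(20)]})
        with pytest.raises(ConvergenceError):
            fit_logistic(df, ModelSpec("y", (Term("x", "binary"),)))

    def test_single_class_outcome_rejected(self):
        df = pd.DataFrame({"x": [0, 1, 0, 1], "y": [1, 1, 1, 1]})
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(df, ModelSpec("y", (Term("x", "binary"),)))

    def test_agrees_with_statsmodels_on_random_designs(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(42)
        for _ in range(25):
            n, p = 120, 3
            x = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
            beta = rng.normal(scale=0.8, size=p + 1)
            y = (rng.random(n) < 1 / (1 + np.exp(-x @ beta))).astype(float)
            if y.min() == y.max():
                continue
            ours = fit_logistic_arrays(x, y)
            ref = sm.Logit(y, x).fit(disp=0, method="newton", tol=1e-10)
            np.testing.assert_allclose(
                ours.table["coef"].to_numpy(), ref.params, atol=1e-6)
            np.testing.assert_allclose(
                ours.table["se"].to_numpy(), ref.bse, atol=1e-6)

    def test_wald_interval_construction(self):
        df = two_by_two(15, 85, 25, 75)
        res = fit_logistic(df, ModelSpec("outcome", (Term("exposed", "binary"),)))
        row = res.table.loc["exposed"]
        assert row["ci_low"] == pytest.approx(
            math.exp(row["coef"] - 1.959963984540054 * row["se"]))
        assert row["or"] == pytest.approx(math.exp(row["coef"]))

    def test_categorical_reference_coding(self, small_cohort_df):
        res = fit_logistic(small_cohort_df, CURE_MODEL)
        assert "change_group[increase]" in res.table.index
        assert "change_group[decrease]" in res.table.index
        assert "change_group[no_change]" not in res.table.index
        assert res.converged

    def test_missing_column_named(self, small_cohort_df):
        spec = ModelSpec("clinical_cure", (Term("not_a_column", "continuous"),))
        with pytest.raises(KeyError, match="not_a_column"):
            fit_logistic(small_cohort_df, spec)


class TestTTEPrepare:
    frame = pd.DataFrame({
        "los_days": [60.0, 22.0, 5.0, np.nan],
        "mortality_30d": [False, False, False, True],
        "change_group": ["increase", "no_change", "decrease", "increase"],
    })

    def test_censoring_and_exclusion_rules(self):
        rec = tte_prepare(self.frame)
        assert len(rec) == 3            # the 30-day death is excluded
        long_stay = rec.iloc[0]
        assert long_stay["time"] == 50.0 and not long_stay["event"]
        assert rec.iloc[1]["time"] == 22.0 and rec.iloc[1]["event"]

    def test_missing_los_for_survivor_rejected(self):
        bad = self.frame.assign(mortality_30d=[False] * 4)
        with pytest.raises(ValueError, match="missing"):
            tte_prepare(bad)


class TestKaplanMeier:
    def test_hand_product_limit(self):
        rec = pd.DataFrame({"time": [1, 2, 3], "event": True, "group": "a"})
        curve = km_estimate(rec)
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 2, 1])

    def test_all_censored_flat_curve(self):
        rec = pd.DataFrame({"time": [5, 9], "event": False, "group": "a"})
        curve = km_estimate(rec)
        assert curve.times.size == 0 and curve.censor_times.size == 2

    def test_no_censoring_equals_empirical_survivor(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, size=40).round(1)
        rec = pd.DataFrame({"time": t, "event": True, "group": "a"})
        curve = km_estimate(rec)
        for ti, si in zip(curve.times, curve.survival):
            assert si == pytest.approx((t > ti).mean())

    def test_matches_lifelines_with_censoring(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        t = rng.exponential(10, size=60).round(1) + 0.1
        e = rng.random(60) < 0.7
        rec = pd.DataFrame({"time": t, "event": e, "group": "a"})
        curve = km_estimate(rec)
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        ref = kmf.survival_function_at_times(curve.times).to_numpy()
        np.testing.assert_allclose(curve.survival, ref, atol=1e-10)

    def test_empty_group_rejected(self):
        rec = pd.DataFrame({"time": [1.0], "event": [True], "group": ["a"]})
        with pytest.raises(ValueError, match="no records"):
            km_estimate(rec, group="b")


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        half = pd.DataFrame({"time": [1, 2, 3, 4], "event": True, "group": "a"})
        other = half.assign(group="b")
        res = log_rank(pd.concat([half, other], ignore_index=True))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_three_groups_two_degrees_of_freedom(self):
        rng = np.random.default_rng(8)
        rec = pd.DataFrame({
            "time": rng.exponential(10, 90).round(1) + 0.1,
            "event": rng.random(90) < 0.8,
            "group": np.repeat(["a", "b", "c"], 30),
        })
        assert log_rank(rec).df == 2

    def test_fewer_than_two_groups_rejected(self):
        rec = pd.DataFrame({"time": [1.0, 2.0], "event": True, "group": "a"})
        with pytest.raises(ValueError, match="two groups"):
            log_rank(rec)

    def test_separated_groups_significant(self):
        t = np.r_[np.arange(1, 51), np.arange(101, 151)].astype(float)
        rec = pd.DataFrame({"time": t, "event": True,
                            "group": np.repeat(["early", "late"], 50)})
        res = log_rank(rec)
        assert res.statistic > 0 and res.p_value < 0.05

    def test_statistic_matches_independent_formula(self):
        rng = np.random.default_rng(13)
        t = rng.exponential(8, size=50).round(1) + 0.1
        e = rng.random(50) < 0.75
        g = rng.random(50) < 0.5
        rec = pd.DataFrame({"time": t, "event": e,
                            "group": np.where(g, "a", "b")})
        ours = log_rank(rec).statistic
        assert ours == pytest.approx(two_sample_logrank_chi2(t, e, g), rel=1e-9)

    def test_p_value_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(21)
        t = np.r_[rng.exponential(6, 30), rng.exponential(12, 30)].round(1) + 0.1
        e = rng.random(60) < 0.8
        g = np.repeat([True, False], 30)
        rec = pd.DataFrame({"time": t, "event": e,
                            "group": np.where(g, "a", "b")})
        p_chi2 = log_rank(rec).p_value
        p_perm = permutation_logrank_p(t, e, g, n_perm=4000, seed=1)
        assert p_chi2 == pytest.approx(p_perm, abs=0.01)

    def test_matches_lifelines_multivariate(self):
        stats_ll = pytest.importorskip("lifelines.statistics")
        rng = np.random.default_rng(30)
        rec = pd.DataFrame({
            "time": rng.exponential(10, 120).round(1) + 0.1,
            "event": rng.random(120) < 0.7,
            "group": rng.choice(["a", "b", "c"], 120),
        })
        ours = log_rank(rec)
        ref = stats_ll.multivariate_logrank_test(
            rec["time"], rec["group"], rec["event"])
        assert ours.statistic == pytest.approx(ref.test_statistic, rel=1e-9)
        assert ours.p_value == pytest.approx(ref.p_value, rel=1e-9)


class TestStudyTables:
    def test_layout_and_derived_contrast(self, small_cohort_df):
        tables = study_tables(small_cohort_df)
        assert set(tables) == {"clinical_cure", "mortality_30d"}
        mort = tables["mortality_30d"].set_index("predictor")
        assert "change_group[increase_vs_decrease]" in mort.index
        # derived contrast equals the ratio of the two fitted contrasts
        ratio = (mort.loc["change_group[increase]", "adj_or"]
                 / mort.loc["change_group[decrease]", "adj_or"])
        assert mort.loc["change_group[increase_vs_decrease]", "adj_or"] == (
            pytest.approx(ratio))
        assert mort.loc["sofa", "uni_or"] > 0
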