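import numpy as np
import pandas as pd
import pytest

from tamspatial._fastcox import CoxSeparationError, fast_coxph
from tamspatial.survival import (
    PARSIMONIOUS_TERMS,
    SurvivalData,
    build_design,
    cox_fit,
    km_estimate,
    ph_check,
    refit_with_strata,
)


def _sim_two_group(n, hr, seed, rate=0.05, cens=40.0):
    rng = np.random.default_rng(seed)
    g = (rng.random(n) < 0.5).astype(float)
    t = -np.log(rng.random(n)) / (rate * np.exp(np.log(hr) * g))
    c = rng.uniform(1, cens, n)
    return np.minimum(t, c), t <= c, g


class TestKaplanMeier:
    def test_single_event_drops_to_zero(self):
        s = km_estimate([2.0], [True])["all"]
        assert s["s"].iloc[0] == 1.0 or s["t"].iloc[0] == 0.0
        assert s.loc[s["t"] == 2.0, "s"].iloc[0] == 0.0

    def test_censored_then_event(self):
        s = km_estimate([1.0, 2.0], [False, True])["all"]
        assert s.loc[s["t"] == 1.0, "s"].iloc[0] == 1.0
        assert s.loc[s["t"] == 2.0, "s"].iloc[0] == 0.0

    def test_all_censored_flat_one(self):
        s = km_estimate([1.0, 5.0, 9.0], [False] * 3)["all"]
        assert (s["s"] == 1.0).all()

    def test_product_limit_hand_example(self):
        # events at 1 and 3, censor at 2: S(1)=2/3, S(3)=2/3*0=... risk set {3} at t=3
        s = km_estimate([1.0, 2.0, 3.0], [True, False, True])["all"]
        assert s.loc[s["t"] == 1.0, "s"].iloc[0] == pytest.approx(2 / 3)
        assert s.loc[s["t"] == 3.0, "s"].iloc[0] == pytest.approx(0.0)

    def test_groups_and_monotonicity(self):
        t, e, g = _sim_two_group(120, 2.0, 1)
        curves = km_estimate(t, e, np.where(g > 0, "hi", "lo"))
        assert set(curves) == {"hi", "lo"}
        for c in curves.values():
            assert (np.diff(c["s"]) <= 1e-12).all()


class TestCoxFit:
    def test_recovers_true_log_hr(self):
        t, e, g = _sim_two_group(2000, 3.0, 2)
        fit = cox_fit(SurvivalData(t, e, pd.DataFrame({"g": g})))
        assert abs(fit.coef[0] - np.log(3)) < 3 * fit.se[0]

    def test_constant_covariate_named_in_error(self):
        t, e, g = _sim_two_group(50, 1.0, 3)
        with pytest.raises(ValueError, match="const"):
            cox_fit(SurvivalData(t, e, pd.DataFrame({"const": np.ones(50)})))

    def test_relabeling_flips_sign(self):
        t, e, g = _sim_two_group(400, 2.0, 4)
        f1 = cox_fit(SurvivalData(t, e, pd.DataFrame({"g": g})))
        f2 = cox_fit(SurvivalData(t, e, pd.DataFrame({"g": 1 - g})))
        assert f1.coef[0] == pytest.approx(-f2.coef[0], abs=1e-6)

    def test_time_unit_invariance(self):
        t, e, g = _sim_two_group(300, 2.0, 5)
        f1 = cox_fit(SurvivalData(t, e, pd.DataFrame({"g": g})))
        f2 = cox_fit(SurvivalData(t * 12.0, e, pd.DataFrame({"g": g})))
        assert f1.coef[0] == pytest.approx(f2.coef[0], abs=1e-8)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="events"):
            cox_fit(SurvivalData(np.ones(10), np.zeros(10, bool), pd.DataFrame({"g": np.arange(10.0)})))

    def test_ci_is_wald_on_log_scale(self):
        t, e, g = _sim_two_group(300, 2.0, 6)
        fit = cox_fit(SurvivalData(t, e, pd.DataFrame({"g": g})))
        lo, hi = fit.ci
        assert lo[0] == pytest.approx(np.exp(fit.coef[0] - 1.96 * fit.se[0]), rel=1e-3)
        assert hi[0] == pytest.approx(np.exp(fit.coef[0] + 1.96 * fit.se[0]), rel=1e-3)


class TestFastCoxAgainstLifelines:
    """The private Newton solver must match the lifelines fit it replaces."""

    @pytest.mark.parametrize("p,tie", [(1, False), (3, False), (3, True)])
    def test_coefficients_and_se_match(self, p, tie):
        rng = np.random.default_rng(10 + p)
        n = 250
        X = rng.normal(size=(n, p))
        beta = np.linspace(0.5, -0.5, p)
        t = -np.log(rng.random(n)) / (0.05 * np.exp(X @ beta))
        c = rng.uniform(2, 40, n)
        time, ev = np.minimum(t, c), t <= c
        if tie:
            time = np.round(time, 0) + 1.0
        mine = fast_coxph(time, ev, X)
        fit = cox_fit(SurvivalData(time, ev, pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])))
        np.testing.assert_allclose(mine.coef, fit.coef, atol=2e-5)
        np.testing.assert_allclose(mine.se, fit.se, atol=2e-6)

    def test_separation_detected(self):
        # perfectly separating covariate: all events in one group, early
        time = np.array([1.0, 2, 3, 10, 11, 12])
        ev = np.array([True, True, True, False, False, False])
        X = np.array([1.0, 1, 1, 0, 0, 0])[:, None]
        with pytest.raises(CoxSeparationError):
            fast_coxph(time, ev, X)


class TestBuildDesign:
    def test_reference_levels_omitted(self):
        df = pd.DataFrame(
            {
                "grade": [1, 2, 3],
                "node": ["negative", "positive", "negative"],
                "size_cat": ["<2cm", "2-5cm", ">5cm"],
                "hr_hormone": ["HR+ compliant", "HR-", "HR+ non-compliant"],
            }
        )
        X = build_design(df, PARSIMONIOUS_TERMS)
        assert "grade[1]" not in X.columns and "grade[2]" in X.columns
        assert X.loc[0].sum() == 0  # all reference levels
        assert X["hr_hormone[HR-]"].tolist() == [0, 1, 0]

    def test_missing_propagates_to_dummies(self):
        df = pd.DataFrame({"grade": [1, None, 3]})
        X = build_design(df, ("grade",))
        assert X.loc[1].isna().all()


class TestProportionalHazards:
    def test_null_rarely_flagged_and_crossing_flagged(self):
        rng = np.random.default_rng(30)
        null_flags, cross_flags = 0, 0
        reps = 12
        for r in range(reps):
            n = 300
            g = (rng.random(n) < 0.5).astype(float)
            # proportional data
            t = -np.log(rng.random(n)) / (0.05 * np.exp(0.5 * g))
            c = rng.uniform(5, 60, n)
            data = SurvivalData(np.minimum(t, c), t <= c, pd.DataFrame({"g": g}))
            res = ph_check(data, cox_fit(data))
            null_flags += bool(res["violates"].any())
            # crossing hazards: effect reverses over time
            u = rng.random(n)
            t2 = np.where(g > 0, np.where(u < 0.6, rng.exponential(3, n), 30 + rng.exponential(30, n)), rng.exponential(12, n))
            c2 = rng.uniform(20, 80, n)
            data2 = SurvivalData(np.minimum(t2, c2), t2 <= c2, pd.DataFrame({"g": g}))
            res2 = ph_check(data2, cox_fit(data2))
            cross_flags += bool(res2["violates"].any())
        assert null_flags <= reps * 0.25
        assert cross_flags >= reps * 0.6

    def test_refit_with_strata_drops_term(self):
        t, e, g = _sim_two_group(200, 2.0, 8)
        extra = (np.random.default_rng(9).random(200) < 0.5).astype(float)
        data = SurvivalData(t, e, pd.DataFrame({"g": g, "z": extra}))
        fit2 = refit_with_strata(data, ["z"])
        assert "z" not in fit2.terms and "g" in fit2.terms
        assert fit2.strata == ["z"]
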