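"""Tests of follow-up construction, KM, log-rank, Cox, deciles, and splines."""

import math
from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter
from scipy.optimize import minimize_scalar

from lbsiz.survival import (
    SplineSpec,
    decile_groups,
    decile_hazard_ratios,
    fit_cox,
    follow_up_years,
    kaplan_meier,
    logrank_test,
    rcs_basis,
    spline_hazard_curve,
)


class TestFollowUp:
    def test_no_event_censored_at_study_end(self):
        years, event = follow_up_years(date(2002, 1, 1))
        assert event == 0
        assert years == pytest.approx(
            (date(2012, 12, 31) - date(2002, 1, 1)).days / 365.25
        )
        assert years == pytest.approx(10.999, abs=2e-3)

    def test_event_one_year_after_baseline(self):
        years, event = follow_up_years(
            date(2002, 1, 1), date(2002, 1, 1) + timedelta(days=365)
        )
        assert event == 1
        assert years == pytest.approx(365 / 365.25)

    def test_event_after_study_end_is_censored(self):
        years, event = follow_up_years(date(2002, 1, 1), date(2013, 6, 1))
        assert event == 0
        assert years == pytest.approx(
            (date(2012, 12, 31) - date(2002, 1, 1)).days / 365.25
        )

    def test_event_before_baseline_rejected(self):
        with pytest.raises(ValueError, match="precedes"):
            follow_up_years(date(2002, 1, 1), date(2001, 12, 1))


class TestKaplanMeier:
    def test_toy_all_events(self):
        km = kaplan_meier([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(
            km["survival"].to_numpy(), [2 / 3, 1 / 3, 0.0], atol=1e-12
        )

    def test_all_censored_survival_one(self):
        km = kaplan_meier([1, 2, 3], [0, 0, 0])
        assert (km["survival"] == 1.0).all()

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(2.0, 200)
        km = kaplan_meier(t, np.ones(200, int))
        emp = 1.0 - np.searchsorted(np.sort(t), km.index.to_numpy(), "right") / 200
        np.testing.assert_allclose(km["survival"].to_numpy(), emp, atol=1e-12)

    def test_monotone_nonincreasing_within_bands(self):
        km = kaplan_meier([1, 1, 2, 3, 4, 5], [1, 0, 1, 0, 1, 0])
        s = km["survival"].to_numpy()
        assert (np.diff(s) <= 1e-12).all()
        assert (km["ci_lower"] <= km["survival"] + 1e-12).all()
        assert (km["ci_upper"] >= km["survival"] - 1e-12).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])


class TestLogrank:
    def test_identical_groups_statistic_zero(self, rng):
        t = rng.exponential(3, 80)
        e = rng.integers(0, 2, 80)
        chi2, df, p = logrank_test(
            np.concatenate([t, t]), np.concatenate([e, e]), np.repeat([0, 1], 80)
        )
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_two_group_toy_matches_reference(self):
        # frozen from an independent standard survival implementation
        chi2, df, p = logrank_test(
            [1, 2, 4, 1.5, 2.5, 5], [1, 1, 0, 1, 1, 1], [0, 0, 0, 1, 1, 1]
        )
        assert df == 1
        assert chi2 == pytest.approx(0.0739030, abs=1e-6)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [1, 1], [0, 0])


def _toy_frame():
    return pd.DataFrame(
        {
            "follow_up_years": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "event": [1, 1, 0, 1, 1, 0],
            "x": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
        }
    )


class TestCox:
    def test_toy_matches_brute_force_partial_likelihood(self):
        df = _toy_frame()
        fit = fit_cox(df, ["x"])
        t = df["follow_up_years"].to_numpy()
        e = df["event"].to_numpy()
        x = df["x"].to_numpy()

        def neg_pl(b):
            ll = 0.0
            for i in range(len(t)):
                if e[i]:
                    ll += b * x[i] - math.log(np.sum(np.exp(b * x[t >= t[i]])))
            return -ll

        res = minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded",
                              options={"xatol": 1e-12})
        assert fit.coefficients["x"] == pytest.approx(res.x, abs=1e-6)
        assert fit.converged

    def test_matches_lifelines_with_ties(self, rng):
        n = 400
        x = rng.normal(size=n)
        x2 = rng.binomial(1, 0.4, n).astype(float)
        t = np.round(rng.exponential(5 * np.exp(-0.5 * x + 0.3 * x2)), 1) + 0.1
        e = (t <= 6).astype(int)
        d = pd.DataFrame(
            {"follow_up_years": np.minimum(t, 6), "event": e, "x": x, "x2": x2}
        )
        fit = fit_cox(d, ["x", "x2"])
        cph = CoxPHFitter().fit(d, duration_col="follow_up_years", event_col="event")
        np.testing.assert_allclose(
            fit.coefficients.to_numpy(), cph.params_.to_numpy(), atol=1e-5
        )
        assert fit.log_likelihood == pytest.approx(cph.log_likelihood_, abs=1e-6)
        np.testing.assert_allclose(
            fit.summary["se"].to_numpy(), cph.standard_errors_.to_numpy(), atol=1e-5
        )

    def test_efron_equals_breslow_without_ties(self, rng):
        n = 120
        d = pd.DataFrame(
            {
                "follow_up_years": rng.exponential(3, n) + rng.uniform(0, 1e-6, n),
                "event": rng.integers(0, 2, n),
                "x": rng.normal(size=n),
            }
        )
        fe = fit_cox(d, ["x"], ties="efron")
        fb = fit_cox(d, ["x"], ties="breslow")
        assert fe.coefficients["x"] == pytest.approx(fb.coefficients["x"], abs=1e-9)
        assert fe.log_likelihood == pytest.approx(fb.log_likelihood, abs=1e-9)

    def test_fitted_likelihood_beats_null(self):
        df = _toy_frame()
        fit = fit_cox(df, ["x"])
        t = df["follow_up_years"].to_numpy()
        e = df["event"].to_numpy()
        # partial log-likelihood at beta = 0 for this toy (no ties)
        ll0 = -sum(math.log(np.sum(t >= t[i])) for i in range(len(t)) if e[i])
        assert fit.log_likelihood >= ll0

    def test_duplicated_column_collinearity_error(self):
        df = _toy_frame().assign(x_dup=lambda d: d["x"])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_cox(df, ["x", "x_dup"])

    def test_no_events_rejected(self):
        df = _toy_frame().assign(event=0)
        with pytest.raises(ValueError, match="events"):
            fit_cox(df, ["x"])

    def test_hr_and_ci_consistency(self):
        fit = fit_cox(_toy_frame(), ["x"])
        s = fit.summary.loc["x"]
        assert s["hr"] == pytest.approx(math.exp(s["coef"]))
        assert s["hr_lower"] == pytest.approx(math.exp(s["coef"] - 1.96 * s["se"]),
                                              rel=1e-3)


class TestDeciles:
    def test_positions(self):
        dec = decile_groups(np.arange(1, 101, dtype=float))
        assert dec[4] == 1  # value 5
        assert dec[94] == 10  # value 95

    def test_balanced_sizes_without_ties(self, rng):
        dec = decile_groups(rng.normal(size=8485))
        sizes = np.bincount(dec)[1:]
        assert sizes.max() - sizes.min() <= 1

    def test_constant_values_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            decile_groups(np.ones(50))

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            decile_groups(np.arange(5))


class TestDecileHazardRatios:
    def test_reference_decile_is_exactly_one(self, scored_cohort):
        table, _ = decile_hazard_ratios(scored_cohort, "lbsiz")
        assert table.loc[1, "hr"] == 1.0
        assert np.isnan(table.loc[1, "hr_lower"])
        assert len(table) == 10

    def test_gradient_recovered_under_loglinear_hazard(self, scored_cohort):
        table, _ = decile_hazard_ratios(scored_cohort, "lbsiz")
        # monotone-ish risk gradient: top decile clearly above reference
        assert table.loc[10, "hr"] > table.loc[5, "hr"]
        assert table.loc[10, "hr_lower"] > 1.0


class TestRCS:
    KNOTS = np.array([-1.5, -0.4, 0.4, 1.5])

    def test_width_is_k_minus_one(self):
        basis = rcs_basis(np.linspace(-2, 2, 7), self.KNOTS)
        assert basis.shape == (7, 3)

    def test_nonlinear_terms_vanish_below_first_knot(self):
        basis = rcs_basis(np.array([-2.0, -1.6]), self.KNOTS)
        np.testing.assert_allclose(basis[:, 1:], 0.0, atol=1e-15)

    def test_linear_beyond_last_knot(self, rng):
        beta = rng.normal(size=3)
        h = 1e-4
        for x0 in (2.0, 3.5):
            vals = [
                (rcs_basis(np.array([x]), self.KNOTS) @ beta)[0]
                for x in (x0 - h, x0, x0 + h)
            ]
            second = (vals[0] - 2 * vals[1] + vals[2]) / h**2
            assert abs(second) < 1e-6

    def test_nonincreasing_knots_rejected(self):
        with pytest.raises(ValueError):
            rcs_basis(np.array([0.0]), np.array([0.0, 0.0, 1.0]))
        with pytest.raises(ValueError):
            SplineSpec(percentiles=(5, 5, 65, 95))


class TestSplineCurve:
    def test_reference_hr_exactly_one(self, scored_cohort):
        curve, info = spline_hazard_curve(
            scored_cohort,
            "lbsiz",
            spec=SplineSpec(reference=0.25),
            grid=np.array([0.25, 1.0]),
        )
        assert info["reference"] == 0.25
        assert curve.loc[0, "hr"] == pytest.approx(1.0, abs=1e-12)
        assert curve.loc[1, "hr"] > 1.0

    def test_shift_invariance(self, scored_cohort):
        spec = SplineSpec(reference=0.0)
        grid = np.linspace(-1.5, 1.5, 21)
        c1, _ = spline_hazard_curve(scored_cohort, "lbsiz", spec=spec, grid=grid)
        shifted = scored_cohort.assign(lbsiz=scored_cohort["lbsiz"] + 5.0)
        c2, _ = spline_hazard_curve(
            shifted, "lbsiz", spec=SplineSpec(reference=5.0), grid=grid + 5.0
        )
        np.testing.assert_allclose(
            c1["hr"].to_numpy(), c2["hr"].to_numpy(), rtol=1e-6
        )
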