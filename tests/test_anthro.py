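"""Unit and property tests for the anthropometric index computations."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from lbsiz.anthro import (
    KOREAN_COEFFS,
    KOREAN_STANDARDIZATION,
    AllometricCoefficients,
    Anthropometry,
    FriedewaldValidityError,
    PlausibilityWarning,
    StandardizationConstants,
    compute_absi,
    compute_bmi,
    compute_lbsi,
    estimate_standardization,
    fit_allometric_exponents,
    friedewald_ldl,
    load_reference_constants,
    standardize_lbsi,
)

plausible_anthro = st.tuples(
    st.floats(0.55, 1.4),  # wc m
    st.floats(30.0, 180.0),  # weight kg
    st.floats(1.3, 2.1),  # height m
)


class TestBMI:
    @pytest.mark.parametrize(
        "w, h, expected",
        [(80.0, 2.0, 20.0), (63.0, 1.60, 63.0 / 2.56), (1.0, 1.0, 1.0)],
    )
    def test_values(self, w, h, expected):
        assert compute_bmi(w, h) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError):
            compute_bmi(-1.0, 1.7)
        with pytest.raises(ValueError):
            compute_bmi(70.0, 0.0)


class TestABSI:
    def test_unit_inputs_give_one(self):
        a = Anthropometry(1.0, 1.0, 1.0)
        assert compute_absi(a, "krakauer") == pytest.approx(1.0)
        with pytest.warns(UserWarning):
            assert compute_absi(a, "as_printed") == pytest.approx(1.0)

    def test_krakauer_reference_value(self):
        # WC * H^(5/6) / W^(2/3) at (0.90 m, 80 kg, 1.75 m)
        a = Anthropometry(0.90, 80.0, 1.75)
        assert compute_absi(a) == pytest.approx(0.0772765, abs=5e-7)

    def test_monotone_in_wc(self):
        lo = compute_absi(Anthropometry(0.90, 80.0, 1.75))
        hi = compute_absi(Anthropometry(0.95, 80.0, 1.75))
        assert hi > lo

    def test_unknown_convention(self):
        with pytest.raises(ValueError, match="convention"):
            compute_absi(Anthropometry(0.9, 80, 1.75), "bogus")


class TestAnthropometryValidation:
    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            Anthropometry(0.0, 70.0, 1.7)

    def test_implausible_warns_but_accepts(self):
        with pytest.warns(PlausibilityWarning):
            a = Anthropometry(0.9, 300.0, 1.7)
        assert a.weight_kg == 300.0


class TestAllometricFit:
    @staticmethod
    def _noise_free(n, rng, coeffs=KOREAN_COEFFS):
        w = rng.uniform(45, 95, n)
        h = rng.uniform(1.45, 1.85, n)
        wc = np.exp(
            coeffs.intercept_c
            + coeffs.weight_exp_a * np.log(w)
            + coeffs.height_exp_b * np.log(h)
        )
        return np.column_stack([wc, w, h])

    def test_noise_free_recovery_exact(self, rng):
        fit = fit_allometric_exponents(self._noise_free(50, rng))
        c = fit.coefficients
        assert c.intercept_c == pytest.approx(-2.69, abs=1e-10)
        assert c.weight_exp_a == pytest.approx(0.73, abs=1e-10)
        assert c.height_exp_b == pytest.approx(-1.06, abs=1e-10)
        assert abs(fit.residuals.mean()) < 1e-12

    def test_three_points_interpolate(self, rng):
        fit = fit_allometric_exponents(self._noise_free(3, rng))
        assert fit.residual_sd == pytest.approx(0.0, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_too_few_points(self, rng):
        with pytest.raises(ValueError, match="at least 3"):
            fit_allometric_exponents(self._noise_free(2, rng))

    def test_collinear_design(self):
        w = np.array([50.0, 60.0, 70.0, 80.0])
        h = w / 40.0  # ln h = ln w - ln 40: perfectly collinear
        wc = 0.01 * w
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_allometric_exponents(np.column_stack([wc, w, h]))

    def test_in_sample_mean_lbsi_zero(self, rng):
        arr = self._noise_free(200, rng)
        arr[:, 0] *= np.exp(rng.normal(0, 0.06, 200))
        fit = fit_allometric_exponents(arr)
        lbsi = compute_lbsi(arr, fit.coefficients)
        assert abs(lbsi.mean()) < 1e-10


class TestLBSI:
    def test_identity_case_zero(self):
        c = KOREAN_COEFFS
        w, h = 63.0, 1.60
        wc = math.exp(c.intercept_c) * w**c.weight_exp_a * h**c.height_exp_b
        assert compute_lbsi(Anthropometry(wc, w, h)) == pytest.approx(0.0, abs=1e-14)

    def test_reference_value(self):
        # typical Korean adult anthropometry, consistent with the reference
        # population mean of about -0.02
        got = compute_lbsi(Anthropometry(0.825, 63.0, 1.60))
        assert got == pytest.approx(-0.0287, abs=0.0005)

    @given(plausible_anthro, st.floats(0.001, 0.05))
    @settings(max_examples=50, deadline=None)
    def test_strict_monotonicities(self, base, delta):
        wc, w, h = base
        v0 = compute_lbsi(np.array([[wc, w, h]]))[0]
        assert compute_lbsi(np.array([[wc + delta, w, h]]))[0] > v0
        assert compute_lbsi(np.array([[wc, w + delta * 50, h]]))[0] < v0
        assert compute_lbsi(np.array([[wc, w, h + delta]]))[0] > v0


class TestStandardization:
    def test_reference_mean_maps_to_zero(self):
        assert standardize_lbsi(-0.02) == pytest.approx(0.0)

    def test_one_sd_above(self):
        assert standardize_lbsi(0.04) == pytest.approx(1.0)

    def test_example_value(self):
        assert standardize_lbsi(-0.0287) == pytest.approx(-0.145, abs=1e-10)

    def test_estimate_two_values(self):
        c = estimate_standardization([-0.08, 0.04])
        assert c.mean_lbsi == pytest.approx(-0.02)
        assert c.sd_lbsi == pytest.approx(0.0849, abs=5e-5)

    def test_constant_vector_degenerate(self):
        with pytest.raises(ValueError, match="zero variance"):
            estimate_standardization([0.1] * 5)

    def test_too_few(self):
        with pytest.raises(ValueError):
            estimate_standardization([0.1])

    def test_round_trip(self, rng):
        vals = rng.normal(-0.02, 0.06, 500)
        z = standardize_lbsi(vals, estimate_standardization(vals))
        assert abs(z.mean()) < 1e-10
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_sd_must_be_positive(self):
        with pytest.raises(ValueError):
            StandardizationConstants(0.0, 0.0)


class TestLBSIZRankInvariance:
    def test_spearman_identical_for_lbsi_and_lbsiz(self, rng):
        lbsi = rng.normal(-0.02, 0.06, 300)
        other = rng.normal(size=300)
        z = standardize_lbsi(lbsi, KOREAN_STANDARDIZATION)
        rho1 = stats.spearmanr(lbsi, other).statistic
        rho2 = stats.spearmanr(z, other).statistic
        assert rho1 == pytest.approx(rho2, abs=1e-14)


class TestFriedewald:
    @pytest.mark.parametrize(
        "tc, hdl, tg, expected",
        [
            (190.4, 44.7, 160.8, 113.5),  # non-event group lipid means
            (196.2, 43.3, 181.6, 116.6),  # event group lipid means
        ],
    )
    def test_group_mean_values(self, tc, hdl, tg, expected):
        assert friedewald_ldl(tc, hdl, tg) == pytest.approx(expected, abs=0.05)

    def test_degenerate_zero(self):
        assert friedewald_ldl(100.0, 100.0, 0.0) == 0.0

    def test_validity_limit(self):
        with pytest.raises(FriedewaldValidityError):
            friedewald_ldl(220.0, 40.0, 400.0)

    def test_linearity_mean_of_ldl_equals_ldl_of_means(self, rng):
        tc = rng.normal(190, 30, 200)
        hdl = rng.normal(45, 8, 200)
        tg = rng.uniform(50, 350, 200)
        per_record = friedewald_ldl(tc, hdl, tg)
        assert per_record.mean() == pytest.approx(
            friedewald_ldl(tc.mean(), hdl.mean(), tg.mean()), abs=1e-9
        )


def test_reference_constants_roundtrip():
    coeffs, constants = load_reference_constants("korean_kns_2018")
    assert (coeffs.intercept_c, coeffs.weight_exp_a, coeffs.height_exp_b) == (
        -2.69,
        0.73,
        -1.06,
    )
    assert (constants.mean_lbsi, constants.sd_lbsi) == (-0.02, 0.06)
    with pytest.raises(KeyError):
        load_reference_constants("nope")


def test_coefficients_must_be_finite():
    with pytest.raises(ValueError):
        AllometricCoefficients(float("nan"), 0.7, -1.0)
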