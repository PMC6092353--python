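"""Anthropometric indices: BMI, ABSI, LBSI, LBSIZ, and Friedewald LDL-C.

A Body Shape Index (ABSI) normalizes waist circumference (WC) for weight and
height through allometric scaling exponents estimated by a log-log regression
of WC on weight and height.  The log-transformed ABSI (LBSI) computed with
population-specific exponents is the residual of that regression, i.e. the
part of abdominal girth not explained by overall body size.  Its z-score
(LBSIZ) standardizes LBSI with a reference population's mean and SD so that
the index is comparable across cohorts and directly usable as a regression
covariate.

Units are canonical throughout: waist circumference and height in metres,
weight in kilograms, natural logarithms.  With the Korean reference
coefficients (intercept -2.69, weight exponent 0.73, height exponent -1.06)
this convention reproduces the published reference mean LBSI of about -0.02
for typical Korean adult anthropometry.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml

__all__ = [
    "Anthropometry",
    "AllometricCoefficients",
    "StandardizationConstants",
    "AllometricFit",
    "PlausibilityWarning",
    "FriedewaldValidityError",
    "KOREAN_COEFFS",
    "KOREAN_STANDARDIZATION",
    "load_reference_constants",
    "compute_bmi",
    "compute_absi",
    "fit_allometric_exponents",
    "compute_lbsi",
    "standardize_lbsi",
    "estimate_standardization",
    "friedewald_ldl",
]

# Plausible adult ranges; values outside trigger a warning, never an error.
_PLAUSIBLE = {
    "wc_m": (0.40, 1.80),
    "weight_kg": (25.0, 250.0),
    "height_m": (1.20, 2.20),
}


class PlausibilityWarning(UserWarning):
    """Anthropometry outside plausible adult ranges (still accepted)."""


class FriedewaldValidityError(ValueError):
    """Triglycerides at or above 400 mg/dL: Friedewald LDL-C is not valid."""


@dataclass(frozen=True)
class Anthropometry:
    """One participant's body measurements in canonical units.

    Attributes
    ----------
    wc_m : float
        Waist circumference in metres.
    weight_kg : float
        Body weight in kilograms.
    height_m : float
        Standing height in metres.
    """

    wc_m: float
    weight_kg: float
    height_m: float

    def __post_init__(self) -> None:
        for name in ("wc_m", "weight_kg", "height_m"):
            value = getattr(self, name)
            if not math.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
            lo, hi = _PLAUSIBLE[name]
            if not lo <= value <= hi:
                warnings.warn(
                    f"{name}={value:g} outside plausible adult range [{lo}, {hi}]",
                    PlausibilityWarning,
                    stacklevel=3,
                )


@dataclass(frozen=True)
class AllometricCoefficients:
    """Intercept and scaling exponents of the log-log WC model.

    ln(WC) = intercept_c + weight_exp_a * ln(weight) + height_exp_b * ln(height)
    """

    intercept_c: float
    weight_exp_a: float
    height_exp_b: float
    source_label: str = "unspecified"

    def __post_init__(self) -> None:
        for name in ("intercept_c", "weight_exp_a", "height_exp_b"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass(frozen=True)
class StandardizationConstants:
    """Reference mean and SD of LBSI used to form the z-score."""

    mean_lbsi: float
    sd_lbsi: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mean_lbsi):
            raise ValueError("mean_lbsi must be finite")
        if not math.isfinite(self.sd_lbsi) or self.sd_lbsi <= 0:
            raise ValueError(f"sd_lbsi must be strictly positive, got {self.sd_lbsi!r}")


@dataclass(frozen=True)
class AllometricFit:
    """OLS estimate of allometric coefficients with fit diagnostics."""

    coefficients: AllometricCoefficients
    r_squared: float
    residual_sd: float
    n: int
    residuals: np.ndarray = field(repr=False, default=None)


def load_reference_constants(name: str = "korean_kns_2018"):
    """Load a named coefficient set from the packaged reference-constants file.

    Returns ``(AllometricCoefficients, StandardizationConstants)``.
    """
    text = (
        importlib.resources.files("lbsiz.data")
        .joinpath("reference_constants.yaml")
        .read_text()
    )
    table = yaml.safe_load(text)
    if name not in table:
        raise KeyError(
            f"unknown reference set {name!r}; available: {sorted(table)}"
        )
    entry = table[name]
    coeffs = AllometricCoefficients(
        intercept_c=float(entry["intercept_c"]),
        weight_exp_a=float(entry["weight_exp_a"]),
        height_exp_b=float(entry["height_exp_b"]),
        source_label=name,
    )
    constants = StandardizationConstants(
        mean_lbsi=float(entry["mean_lbsi"]), sd_lbsi=float(entry["sd_lbsi"])
    )
    return coeffs, constants


#: Korean reference allometric coefficients (rounded published values).
KOREAN_COEFFS = AllometricCoefficients(-2.69, 0.73, -1.06, "korean_kns_2018")
#: Korean reference standardization constants.
KOREAN_STANDARDIZATION = StandardizationConstants(-0.02, 0.06)


def compute_bmi(weight_kg, height_m):
    """Body mass index, weight (kg) divided by height squared (m^2).

    Accepts scalars or arrays; raises on non-positive input.
    """
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_m = np.asarray(height_m, dtype=float)
    if np.any(weight_kg <= 0) or np.any(height_m <= 0):
        raise ValueError("weight and height must be strictly positive")
    out = weight_kg / height_m**2
    return float(out) if out.ndim == 0 else out


def compute_absi(anthro: Anthropometry, convention: str = "krakauer") -> float:
    """Original (dimensionless-scale) ABSI for one participant.

    Two conventions are supported because the literature prints the height
    exponent with both signs:

    - ``"krakauer"`` (default): WC / (BMI^(2/3) * height^(1/2))
      = WC * height^(5/6) / weight^(2/3), the standard definition.
    - ``"as_printed"``: WC / (weight^(2/3) * height^(5/6)), i.e. the height
      exponent in the denominator, as the formula is sometimes typeset.

    The two differ only in the sign of the height exponent; a warning is
    emitted for ``as_printed`` since the standard definition is almost
    certainly what is meant.
    """
    wc, w, h = anthro.wc_m, anthro.weight_kg, anthro.height_m
    if convention == "krakauer":
        return wc * h ** (5.0 / 6.0) / w ** (2.0 / 3.0)
    if convention == "as_printed":
        warnings.warn(
            "convention='as_printed' uses height^(-5/6); the standard ABSI "
            "definition is convention='krakauer'",
            UserWarning,
            stacklevel=2,
        )
        return wc / (w ** (2.0 / 3.0) * h ** (5.0 / 6.0))
    raise ValueError(
        f"unknown ABSI convention {convention!r}; use 'krakauer' or 'as_printed'"
    )


def fit_allometric_exponents(
    cohort: Sequence[Anthropometry] | np.ndarray,
    source_label: str = "fitted",
) -> AllometricFit:
    """Estimate allometric coefficients by OLS of ln(WC) on ln(weight), ln(height).

    Parameters
    ----------
    cohort : sequence of Anthropometry or (n, 3) array
        Array columns are (wc_m, weight_kg, height_m).

    Returns
    -------
    AllometricFit
        Coefficients with R^2, residual SD (n-1 denominator on residuals of a
        3-parameter fit would be n-3; we report the root mean squared residual
        with n-3 df, the OLS convention) and the residual vector.
    """
    arr = _as_anthro_array(cohort)
    n = arr.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 participants to fit, got {n}")
    X = np.column_stack([np.ones(n), np.log(arr[:, 1]), np.log(arr[:, 2])])
    y = np.log(arr[:, 0])
    # guard against collinearity of ln(weight) and ln(height)
    if np.linalg.matrix_rank(X) < 3:
        raise np.linalg.LinAlgError(
            "design matrix is singular: ln(weight) and ln(height) are "
            "collinear across the cohort (or constant)"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    resid_sd = math.sqrt(ss_res / (n - 3)) if n > 3 else 0.0
    coeffs = AllometricCoefficients(
        intercept_c=float(beta[0]),
        weight_exp_a=float(beta[1]),
        height_exp_b=float(beta[2]),
        source_label=source_label,
    )
    return AllometricFit(coeffs, r2, resid_sd, n, resid)


def compute_lbsi(anthro, coeffs: AllometricCoefficients = KOREAN_COEFFS):
    """Log-transformed ABSI: the allometric regression residual.

    LBSI = ln(WC) - c - a*ln(weight) - b*ln(height), with WC and height in
    metres and weight in kg.  Accepts a single :class:`Anthropometry` or an
    (n, 3) array of (wc_m, weight_kg, height_m).
    """
    arr = _as_anthro_array(anthro)
    out = (
        np.log(arr[:, 0])
        - coeffs.intercept_c
        - coeffs.weight_exp_a * np.log(arr[:, 1])
        - coeffs.height_exp_b * np.log(arr[:, 2])
    )
    return float(out[0]) if isinstance(anthro, Anthropometry) else out


def standardize_lbsi(lbsi, constants: StandardizationConstants = KOREAN_STANDARDIZATION):
    """LBSIZ: z-score of LBSI, (LBSI - mean) / SD."""
    lbsi = np.asarray(lbsi, dtype=float)
    out = (lbsi - constants.mean_lbsi) / constants.sd_lbsi
    return float(out) if out.ndim == 0 else out


def estimate_standardization(lbsi_values) -> StandardizationConstants:
    """Sample mean and SD (n-1 denominator) of LBSI values for re-derivation."""
    values = np.asarray(lbsi_values, dtype=float)
    if values.ndim != 1:
        values = values.ravel()
    if values.size < 2:
        raise ValueError(f"need at least 2 values, got {values.size}")
    if not np.all(np.isfinite(values)):
        raise ValueError("LBSI values must be finite")
    sd = float(values.std(ddof=1))
    if sd == 0:
        raise ValueError("degenerate data: LBSI values have zero variance")
    return StandardizationConstants(float(values.mean()), sd)


def friedewald_ldl(tc, hdl, tg):
    """Friedewald LDL-C (mg/dL): TC - HDL - TG/5, valid only for TG < 400.

    Raises :class:`FriedewaldValidityError` if any TG is at or above
    400 mg/dL (the equation's standard validity limit).
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    if np.any(tc < 0) or np.any(hdl < 0) or np.any(tg < 0):
        raise ValueError("lipid concentrations must be non-negative")
    if np.any(tg >= 400):
        raise FriedewaldValidityError(
            "triglycerides >= 400 mg/dL: Friedewald LDL-C withheld"
        )
    out = tc - hdl - tg / 5.0
    return float(out) if out.ndim == 0 else out


def _as_anthro_array(obj) -> np.ndarray:
    """Coerce Anthropometry / sequence of Anthropometry / array to (n, 3) floats."""
    if isinstance(obj, Anthropometry):
        arr = np.array([[obj.wc_m, obj.weight_kg, obj.height_m]], dtype=float)
    elif len(obj) > 0 and isinstance(obj[0], Anthropometry):
        arr = np.array(
            [[a.wc_m, a.weight_kg, a.height_m] for a in obj], dtype=float
        )
    else:
        arr = np.atleast_2d(np.asarray(obj, dtype=float))
    if arr.shape[1] != 3:
        raise ValueError("expected columns (wc_m, weight_kg, height_m)")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("anthropometry must be finite and strictly positive")
    return arr
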