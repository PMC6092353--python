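"""Framingham 10-year cardiovascular risk score (continuous Cox form).

The default coefficient set is the D'Agostino 2008 general-CVD formulation
(sex-specific coefficients on log age, log total cholesterol, log HDL-C,
log systolic blood pressure split by antihypertensive treatment, current
smoking and diabetes), chosen because a composite endpoint spanning coronary,
cerebrovascular, heart-failure and peripheral arterial events matches
"general CVD" better than the older hard-CHD score.  Alternative coefficient
tables with the same schema can be loaded from a YAML file by path.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = ["FRSCoefficients", "load_frs_coefficients", "frs_linear_predictor", "frs_risk10"]

_TERMS = (
    "ln_age",
    "ln_tc",
    "ln_hdl",
    "ln_sbp_untreated",
    "ln_sbp_treated",
    "smoker",
    "diabetes",
)

_REQUIRED_FIELDS = ("sex", "age", "tc", "hdl", "sbp", "bp_treated", "smoker", "diabetes")


@dataclass(frozen=True)
class FRSCoefficients:
    """Sex-specific Framingham coefficient set.

    ``male`` / ``female`` map term names to coefficients plus ``s0_10yr``
    (10-year baseline survival, in (0, 1)) and ``mean_lp`` (the cohort mean
    linear predictor the score is centred on).
    """

    version_id: str
    male: Mapping[str, float]
    female: Mapping[str, float]

    def __post_init__(self) -> None:
        for sex in ("male", "female"):
            table = getattr(self, sex)
            missing = [t for t in _TERMS + ("s0_10yr", "mean_lp") if t not in table]
            if missing:
                raise ValueError(f"{sex} coefficient table missing {missing}")
            if not 0 < table["s0_10yr"] < 1:
                raise ValueError("s0_10yr must be in (0, 1)")
            for key, value in table.items():
                if not math.isfinite(value):
                    raise ValueError(f"{sex}.{key} must be finite")

    def for_sex(self, sex: str) -> Mapping[str, float]:
        sex = _canonical_sex(sex)
        return self.male if sex == "male" else self.female


def load_frs_coefficients(path=None) -> FRSCoefficients:
    """Load FRS coefficients from YAML; defaults to the packaged 2008 table."""
    if path is None:
        text = (
            importlib.resources.files("lbsiz.data")
            .joinpath("framingham_dagostino2008.yaml")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return FRSCoefficients(
        version_id=str(raw["version_id"]),
        male={k: float(v) for k, v in raw["male"].items()},
        female={k: float(v) for k, v in raw["female"].items()},
    )


_DEFAULT = load_frs_coefficients()


def _canonical_sex(sex) -> str:
    s = str(sex).strip().lower()
    if s in ("male", "m", "1"):
        return "male"
    if s in ("female", "f", "0", "2"):
        return "female"
    raise ValueError(f"unrecognized sex value {sex!r}")


def _get(record, name):
    try:
        value = record[name]
    except (KeyError, IndexError, TypeError):
        value = getattr(record, name, None)
    if value is None or (np.isscalar(value) and pd.isna(value)):
        raise ValueError(f"record missing required field {name!r}")
    return value


def frs_linear_predictor(record, coeffs: FRSCoefficients = _DEFAULT) -> float:
    """Framingham linear predictor for one record.

    ``record`` is any mapping/namespace with fields ``sex``, ``age`` (years),
    ``tc``/``hdl`` (mg/dL), ``sbp`` (mmHg), ``bp_treated``, ``smoker``,
    ``diabetes`` (booleans or 0/1).
    """
    values = {name: _get(record, name) for name in _REQUIRED_FIELDS}
    table = coeffs.for_sex(values["sex"])
    age, tc, hdl, sbp = (float(values[k]) for k in ("age", "tc", "hdl", "sbp"))
    for name, v in (("age", age), ("tc", tc), ("hdl", hdl), ("sbp", sbp)):
        if v <= 0:
            raise ValueError(f"{name} must be positive for log transform, got {v}")
    sbp_coef = (
        table["ln_sbp_treated"] if bool(values["bp_treated"]) else table["ln_sbp_untreated"]
    )
    return (
        table["ln_age"] * math.log(age)
        + table["ln_tc"] * math.log(tc)
        + table["ln_hdl"] * math.log(hdl)
        + sbp_coef * math.log(sbp)
        + table["smoker"] * float(bool(values["smoker"]))
        + table["diabetes"] * float(bool(values["diabetes"]))
    )


def frs_risk10(record, coeffs: FRSCoefficients = _DEFAULT) -> float:
    """10-year CVD risk, 1 - S0 ^ exp(lp - mean_lp), in (0, 1)."""
    table = coeffs.for_sex(_get(record, "sex"))
    lp = frs_linear_predictor(record, coeffs)
    return 1.0 - table["s0_10yr"] ** math.exp(lp - table["mean_lp"])


def frs_table(df: pd.DataFrame, coeffs: FRSCoefficients = _DEFAULT) -> pd.DataFrame:
    """Vectorized helper: linear predictor and 10-year risk for a cohort frame.

    Returns a DataFrame with columns ``frs_lp`` and ``frs_risk10`` aligned to
    ``df.index``.
    """
    lp = np.array(
        [frs_linear_predictor(row, coeffs) for row in df.to_dict("records")]
    )
    sexes = [_canonical_sex(s) for s in df["sex"]]
    s0 = np.array([coeffs.for_sex(s)["s0_10yr"] for s in sexes])
    mean_lp = np.array([coeffs.for_sex(s)["mean_lp"] for s in sexes])
    risk = 1.0 - s0 ** np.exp(lp - mean_lp)
    return pd.DataFrame({"frs_lp": lp, "frs_risk10": risk}, index=df.index)
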