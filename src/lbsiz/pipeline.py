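"""Cohort I/O, descriptive statistics, and the end-to-end analysis pipeline.

The pipeline mirrors a standard prospective-cohort obesity analysis:

1. load (or simulate) the cohort and normalize units;
2. score every participant: BMI, WC, LBSI/LBSIZ, Framingham linear
   predictor and 10-year risk;
3. baseline characteristics by event status (t-test / chi-square);
4. Spearman correlations of LBSIZ with the other anthropometric measures;
5. ROC/AUC for each obesity measure and FRS, DeLong paired comparisons,
   and the FRS-plus-parameter integrated AUCs;
6. Kaplan-Meier curves and log-rank tests by obesity groupings;
7. decile hazard ratios and restricted-cubic-spline dose-response curves,
   adjusted for age, sex, smoking, systolic blood pressure, hypertension,
   diabetes, LDL-C and lipid-lowering medication.

Everything is deterministic given the simulation seed, and every table is a
plain DataFrame serializable to CSV.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _pkg_version
from .anthro import (
    KOREAN_COEFFS,
    KOREAN_STANDARDIZATION,
    compute_bmi,
    compute_lbsi,
    friedewald_ldl,
    standardize_lbsi,
)
from .discrimination import delong_compare, integrated_auc, roc_curve
from .framingham import frs_table, load_frs_coefficients
from .simulate import CohortConfig, generate_cohort
from .survival import (
    SplineSpec,
    decile_hazard_ratios,
    kaplan_meier,
    logrank_test,
    spline_hazard_curve,
)

logger = logging.getLogger("lbsiz")

__all__ = [
    "REQUIRED_COLUMNS",
    "AnalysisReport",
    "load_cohort",
    "score_cohort",
    "baseline_table",
    "index_correlations",
    "run_full_analysis",
    "write_report",
    "write_figures",
]

#: canonical column set of the cohort CSV dialect (canonical units:
#: metres, kg, mg/dL, mmHg, years)
REQUIRED_COLUMNS = (
    "sex",
    "age",
    "height_m",
    "weight_kg",
    "wc_m",
    "sbp",
    "tc",
    "hdl",
    "tg",
    "smoking",
    "diabetes",
    "hypertension",
    "lipid_med",
    "bp_treated",
    "event",
    "follow_up_years",
)

#: multivariable adjuster set used for decile HRs and spline curves
ADJUSTERS = (
    "age",
    "male",
    "smoking_ex",
    "smoking_current",
    "sbp",
    "hypertension",
    "diabetes",
    "ldl",
    "lipid_med",
)

#: obesity dichotomization defaults for the Kaplan-Meier contrasts:
#: BMI >= 25 kg/m^2 (Asian-Pacific obesity cutoff), WC >= 90 cm (men) /
#: 85 cm (women), LBSIZ >= 0 (reference mean)
KM_CUTOFFS = {"bmi": 25.0, "wc_cm_male": 90.0, "wc_cm_female": 85.0, "lbsiz": 0.0}


def load_cohort(path, column_map=None, units=None) -> pd.DataFrame:
    """Read a cohort CSV, normalize units and drop incomplete rows.

    Parameters
    ----------
    column_map : dict, optional
        Maps canonical column names to the file's headers,
        e.g. ``{"wc_m": "waist"}``.
    units : dict, optional
        Unit annotations for ``wc_m`` / ``height_m`` (``"m"`` or ``"cm"``)
        and ``weight_kg`` (``"kg"``); centimetres are converted to metres on
        load.  Defaults to canonical units, so loading canonical data is a
        no-op (idempotent).

    Rows missing any required column are excluded and the exclusion count is
    logged, mirroring the usual complete-case rule of cohort analyses.
    """
    df = pd.read_csv(path)
    if column_map:
        missing = [v for v in column_map.values() if v not in df.columns]
        if missing:
            raise ValueError(
                f"column map refers to absent headers {missing}; "
                f"file has {list(df.columns)}"
            )
        df = df.rename(columns={v: k for k, v in column_map.items()})
    absent = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if absent:
        raise ValueError(
            f"required columns missing from {path}: {absent}; "
            f"candidates present: {list(df.columns)}"
        )
    units = units or {}
    for col in ("wc_m", "height_m"):
        unit = units.get(col, "m")
        if unit == "cm":
            df[col] = df[col] / 100.0
        elif unit != "m":
            raise ValueError(f"unsupported unit {unit!r} for {col}")
    if units.get("weight_kg", "kg") != "kg":
        raise ValueError("weight must be supplied in kg")
    n0 = len(df)
    df = df.dropna(subset=list(REQUIRED_COLUMNS)).reset_index(drop=True)
    excluded = n0 - len(df)
    if excluded:
        logger.info("excluded %d of %d rows with incomplete data", excluded, n0)
    if df.empty:
        raise ValueError("no complete rows remain after exclusions")
    bad = (df[["wc_m", "height_m", "weight_kg", "follow_up_years"]] <= 0).any(axis=1)
    if bad.any():
        raise ValueError(f"{int(bad.sum())} rows have non-positive measurements")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event column must be binary 0/1")
    if "ldl" not in df.columns or df["ldl"].isna().any():
        df["ldl"] = friedewald_ldl(
            df["tc"].to_numpy(), df["hdl"].to_numpy(), df["tg"].to_numpy()
        )
    logger.info("loaded cohort: %d rows", len(df))
    return df


def score_cohort(
    df: pd.DataFrame,
    coeffs=KOREAN_COEFFS,
    standardization=KOREAN_STANDARDIZATION,
    frs_coeffs=None,
) -> pd.DataFrame:
    """Add derived scores: bmi, lbsi, lbsiz, wc_cm, frs_lp, frs_risk10, male,
    smoking indicators."""
    out = df.copy()
    out["bmi"] = compute_bmi(out["weight_kg"].to_numpy(), out["height_m"].to_numpy())
    out["lbsi"] = compute_lbsi(
        out[["wc_m", "weight_kg", "height_m"]].to_numpy(), coeffs
    )
    out["lbsiz"] = standardize_lbsi(out["lbsi"].to_numpy(), standardization)
    out["wc_cm"] = out["wc_m"] * 100.0
    out["male"] = (out["sex"].astype(str).str.lower().isin(["male", "m", "1"])).astype(int)
    out["smoking_ex"] = (out["smoking"] == "ex").astype(int)
    out["smoking_current"] = (out["smoking"] == "current").astype(int)
    frs_coeffs = frs_coeffs or load_frs_coefficients()
    frs_in = out.rename(columns={"smoking_current": "smoker"})[
        ["sex", "age", "tc", "hdl", "sbp", "bp_treated", "smoker", "diabetes"]
    ]
    scores = frs_table(frs_in, frs_coeffs)
    out["frs_lp"] = scores["frs_lp"].to_numpy()
    out["frs_risk10"] = scores["frs_risk10"].to_numpy()
    return out


_CONTINUOUS = (
    "age",
    "bmi",
    "wc_cm",
    "lbsiz",
    "sbp",
    "dbp",
    "glucose",
    "hba1c",
    "tc",
    "hdl",
    "tg",
    "ldl",
)
_CATEGORICAL = ("male", "smoking", "diabetes", "hypertension", "dyslipidemia")


def baseline_table(
    cohort: pd.DataFrame, group_col: str = "event", welch: bool = False
) -> pd.DataFrame:
    """Baseline characteristics by group with t-test / chi-square p-values.

    Continuous variables: mean +/- SD per group, equal-variance two-sample
    t-test (``welch=True`` switches to Welch).  Categorical variables:
    n (%) per level, Pearson chi-square without continuity correction.
    """
    groups = sorted(cohort[group_col].unique())
    if len(groups) != 2:
        raise ValueError("baseline table expects exactly two groups")
    g0 = cohort[cohort[group_col] == groups[0]]
    g1 = cohort[cohort[group_col] == groups[1]]
    rows = []
    for var in _CONTINUOUS:
        if var not in cohort.columns:
            continue
        a, b = g0[var].dropna(), g1[var].dropna()
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            p = np.nan
        else:
            _, p = stats.ttest_ind(a, b, equal_var=not welch)
        rows.append(
            {
                "variable": var,
                "level": "",
                f"group_{groups[0]}": f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
                f"group_{groups[1]}": f"{b.mean():.2f} ± {b.std(ddof=1):.2f}",
                "p": p,
            }
        )
    for var in _CATEGORICAL:
        if var not in cohort.columns:
            continue
        table = pd.crosstab(cohort[var], cohort[group_col])
        if table.shape[0] < 2:
            p = np.nan
        else:
            chi2, p, _, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
        for i, level in enumerate(table.index):
            rows.append(
                {
                    "variable": var,
                    "level": str(level),
                    f"group_{groups[0]}": f"{table.loc[level, groups[0]]} "
                    f"({table.loc[level, groups[0]] / len(g0) * 100:.1f}%)",
                    f"group_{groups[1]}": f"{table.loc[level, groups[1]]} "
                    f"({table.loc[level, groups[1]] / len(g1) * 100:.1f}%)",
                    "p": p if i == 0 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def index_correlations(cohort: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlations of LBSIZ with WC, BMI, weight and height."""
    if len(cohort) < 3:
        raise ValueError("need at least 3 rows for rank correlations")
    rows = []
    for other in ("wc_cm", "bmi", "weight_kg", "height_m"):
        x = cohort["lbsiz"].to_numpy()
        y = cohort[other].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append({"pair": f"lbsiz~{other}", "rho": np.nan, "p": np.nan})
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append({"pair": f"lbsiz~{other}", "rho": float(rho), "p": float(p)})
    return pd.DataFrame(rows).set_index("pair")


@dataclass
class AnalysisReport:
    """Bundle of every analysis table plus run metadata."""

    baseline: pd.DataFrame
    correlations: pd.DataFrame
    auc_table: pd.DataFrame
    auc_comparisons: pd.DataFrame
    integrated: pd.DataFrame
    km_curves: dict
    logrank: pd.DataFrame
    decile_hr: dict
    spline_curves: dict
    spline_tests: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _km_group(scored: pd.DataFrame, measure: str) -> np.ndarray:
    if measure == "bmi":
        return (scored["bmi"] >= KM_CUTOFFS["bmi"]).to_numpy()
    if measure == "wc_cm":
        cut = np.where(
            scored["male"] == 1, KM_CUTOFFS["wc_cm_male"], KM_CUTOFFS["wc_cm_female"]
        )
        return (scored["wc_cm"].to_numpy() >= cut)
    if measure == "lbsiz":
        return (scored["lbsiz"] >= KM_CUTOFFS["lbsiz"]).to_numpy()
    raise ValueError(measure)


def run_full_analysis(
    config: CohortConfig | None = None,
    cohort: pd.DataFrame | None = None,
    spline_spec: SplineSpec = SplineSpec(),
) -> AnalysisReport:
    """Run the complete analysis on a simulated or supplied cohort."""
    if cohort is None:
        if config is None:
            config = CohortConfig()
        cohort = generate_cohort(config)
        logger.info("simulated cohort n=%d seed=%d", config.n, config.seed)
    scored = score_cohort(cohort)
    y = scored["event"].to_numpy(dtype=int)
    measures = ("bmi", "wc_cm", "lbsiz")

    baseline = baseline_table(scored)
    correlations = index_correlations(scored)

    roc = {m: roc_curve(scored[m].to_numpy(), y) for m in measures}
    roc["frs"] = roc_curve(scored["frs_lp"].to_numpy(), y)
    auc_rows = []
    for name, r in roc.items():
        lo, hi = r.auc_ci()
        auc_rows.append(
            {"score": name, "auc": r.auc, "ci_lower": lo, "ci_upper": hi}
        )
    auc_table = pd.DataFrame(auc_rows).set_index("score")

    cmp_rows = []
    for a, b in (("lbsiz", "wc_cm"), ("lbsiz", "bmi"), ("wc_cm", "bmi")):
        res = delong_compare(scored[a].to_numpy(), scored[b].to_numpy(), y)
        cmp_rows.append({"comparison": f"{a} vs {b}", **res})
    auc_comparisons = pd.DataFrame(cmp_rows).set_index("comparison")

    int_rows = []
    for m in measures:
        res = integrated_auc(scored["frs_lp"].to_numpy(), scored[m].to_numpy(), y)
        res.pop("coefficients")
        int_rows.append({"parameter": m, **res})
    integrated = pd.DataFrame(int_rows).set_index("parameter")

    km_curves = {}
    lr_rows = []
    times = scored["follow_up_years"].to_numpy()
    for m in measures:
        high = _km_group(scored, m)
        for label, mask in (("high", high), ("low", ~high)):
            km_curves[f"{m}_{label}"] = kaplan_meier(times[mask], y[mask])
        chi2, dof, p = logrank_test(times, y, high.astype(int))
        lr_rows.append({"measure": m, "chi2": chi2, "df": dof, "p": p})
    logrank_df = pd.DataFrame(lr_rows).set_index("measure")

    decile_hr = {}
    spline_curves = {}
    spline_rows = []
    for m in measures:
        table, _ = decile_hazard_ratios(scored, m, ADJUSTERS)
        decile_hr[m] = table
        curve, info = spline_hazard_curve(scored, m, ADJUSTERS, spline_spec)
        spline_curves[m] = curve
        spline_rows.append(
            {
                "measure": m,
                "reference": info["reference"],
                "nonlinear_chi2": info["nonlinear_chi2"],
                "nonlinear_df": info["nonlinear_df"],
                "nonlinear_p": info["nonlinear_p"],
            }
        )
    spline_tests = pd.DataFrame(spline_rows).set_index("measure")

    metadata = {
        "package_version": _pkg_version,
        "n": int(len(scored)),
        "events": int(y.sum()),
        "frs_version": load_frs_coefficients().version_id,
        "roc_outcome": "binary event indicator over the fixed follow-up window",
        "km_cutoffs": KM_CUTOFFS,
        "adjusters": list(ADJUSTERS),
    }
    if config is not None:
        cfg_yaml = json.dumps(
            {"n": config.n, "seed": config.seed}, sort_keys=True
        )
        metadata["seed"] = config.seed
        metadata["config_hash"] = hashlib.sha256(
            repr(config).encode()
        ).hexdigest()[:16]
        metadata["config_summary"] = cfg_yaml
    return AnalysisReport(
        baseline=baseline,
        correlations=correlations,
        auc_table=auc_table,
        auc_comparisons=auc_comparisons,
        integrated=integrated,
        km_curves=km_curves,
        logrank=logrank_df,
        decile_hr=decile_hr,
        spline_curves=spline_curves,
        spline_tests=spline_tests,
        metadata=metadata,
    )


def write_report(report: AnalysisReport, outdir) -> None:
    """Write the report bundle: CSV tables plus JSON metadata."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.baseline.to_csv(out / "baseline.csv", index=False)
    report.correlations.to_csv(out / "correlations.csv")
    report.auc_table.to_csv(out / "auc.csv")
    report.auc_comparisons.to_csv(out / "auc_comparisons.csv")
    report.integrated.to_csv(out / "integrated_auc.csv")
    report.logrank.to_csv(out / "logrank.csv")
    report.spline_tests.to_csv(out / "spline_tests.csv")
    for name, curve in report.km_curves.items():
        curve.to_csv(out / f"km_{name}.csv")
    for name, table in report.decile_hr.items():
        table.to_csv(out / f"decile_hr_{name}.csv")
    for name, curve in report.spline_curves.items():
        curve.to_csv(out / f"spline_{name}.csv", index=False)
    with open(out / "metadata.json", "w") as fh:
        json.dump(report.metadata, fh, indent=2, sort_keys=True)
    logger.info("report written to %s", out)


def write_figures(report: AnalysisReport, outdir, fmt: str = "svg") -> None:
    """Render the report's KM, decile-HR and spline tables as figures."""
    from pathlib import Path

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    measures = sorted({k.rsplit("_", 1)[0] for k in report.km_curves})

    fig, axes = plt.subplots(1, len(measures), figsize=(4 * len(measures), 3.2),
                             sharey=True)
    for ax, m in zip(np.atleast_1d(axes), measures):
        for label in ("low", "high"):
            km = report.km_curves[f"{m}_{label}"]
            ax.step(km.index, km["survival"], where="post", label=label)
        ax.set_title(f"{m} (log-rank p={report.logrank.loc[m, 'p']:.3g})")
        ax.set_xlabel("years")
        ax.legend()
    axes_flat = np.atleast_1d(axes)
    axes_flat[0].set_ylabel("event-free survival")
    fig.tight_layout()
    fig.savefig(out / f"km.{fmt}")
    plt.close(fig)

    for name, maker in (("decile_hr", report.decile_hr),
                        ("spline", report.spline_curves)):
        fig, axes = plt.subplots(1, len(maker), figsize=(4 * len(maker), 3.2))
        for ax, (m, table) in zip(np.atleast_1d(axes), maker.items()):
            if name == "decile_hr":
                ax.errorbar(
                    table.index,
                    table["hr"],
                    yerr=[
                        (table["hr"] - table["hr_lower"]).fillna(0),
                        (table["hr_upper"] - table["hr"]).fillna(0),
                    ],
                    fmt="o",
                )
                ax.set_xlabel(f"{m} decile")
            else:
                x = table.iloc[:, 0]
                ax.plot(x, table["hr"])
                ax.fill_between(x, table["hr_lower"], table["hr_upper"], alpha=0.25)
                ax.set_xlabel(m)
            ax.axhline(1.0, ls="--", lw=0.8, color="grey")
            ax.set_yscale("log")
            ax.set_ylabel("hazard ratio")
        fig.tight_layout()
        fig.savefig(out / f"{name}.{fmt}")
        plt.close(fig)
    logger.info("figures written to %s", out)
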