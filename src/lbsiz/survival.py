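"""Survival analysis: follow-up construction, Kaplan-Meier, log-rank, Cox
proportional hazards (Efron/Breslow ties), decile hazard ratios and
restricted-cubic-spline dose-response curves.

The Cox partial likelihood is maximized by damped Newton iterations written
here (so that both tie corrections, convergence metadata and the exact
likelihood are available); Kaplan-Meier estimation and the log-rank test are
delegated to lifelines.  All confidence intervals are Wald intervals on the
log-hazard scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

__all__ = [
    "CoxFit",
    "SplineSpec",
    "follow_up_years",
    "kaplan_meier",
    "logrank_test",
    "fit_cox",
    "decile_groups",
    "decile_hazard_ratios",
    "rcs_basis",
    "spline_hazard_curve",
]

END_OF_FOLLOWUP = date(2012, 12, 31)
DAYS_PER_YEAR = 365.25
_Z95 = 1.959963984540054


# ---------------------------------------------------------------------------
# follow-up construction


def _to_date(d) -> date:
    if isinstance(d, datetime):
        return d.date()
    if isinstance(d, pd.Timestamp):
        return d.date()
    if isinstance(d, date):
        return d
    return pd.Timestamp(d).date()


def follow_up_years(baseline_date, event_date=None, end_of_followup=END_OF_FOLLOWUP):
    """Follow-up time in years and event indicator under administrative censoring.

    Time runs from baseline to the event date or the end of follow-up,
    whichever comes first, in days / 365.25.  The indicator is 1 only when an
    event occurred on or before the end of follow-up.

    Returns ``(years, event)``.
    """
    baseline = _to_date(baseline_date)
    end = _to_date(end_of_followup)
    if baseline > end:
        raise ValueError("baseline date is after the end of follow-up")
    if event_date is not None:
        ev = _to_date(event_date)
        if ev < baseline:
            raise ValueError("event date precedes baseline date")
        if ev <= end:
            return (ev - baseline).days / DAYS_PER_YEAR, 1
    return (end - baseline).days / DAYS_PER_YEAR, 0


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank


def kaplan_meier(times, events, alpha: float = 0.05) -> pd.DataFrame:
    """Product-limit survival estimate with plain Greenwood confidence bands.

    Returns a DataFrame indexed by event/censoring time with columns
    ``survival``, ``ci_lower``, ``ci_upper``, ``at_risk``, ``observed``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival data")
    if np.any(times <= 0):
        raise ValueError("times must be strictly positive")
    km = KaplanMeierFitter()
    km.fit(times, events)
    table = km.event_table.iloc[1:] if 0.0 in km.event_table.index else km.event_table
    surv = km.survival_function_["KM_estimate"].reindex(table.index).to_numpy()
    at_risk = table["at_risk"].to_numpy(float)
    observed = table["observed"].to_numpy(float)
    # Greenwood: var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        incr = np.where(
            at_risk > observed, observed / (at_risk * (at_risk - observed)), np.inf
        )
    var = surv**2 * np.cumsum(incr)
    se = np.sqrt(np.where(np.isfinite(var), var, 0.0))
    z = stats.norm.ppf(1 - alpha / 2)
    return pd.DataFrame(
        {
            "survival": surv,
            "ci_lower": np.clip(surv - z * se, 0.0, 1.0),
            "ci_upper": np.clip(surv + z * se, 0.0, 1.0),
            "at_risk": at_risk.astype(int),
            "observed": observed.astype(int),
        },
        index=pd.Index(table.index, name="time"),
    )


def logrank_test(times, events, groups):
    """Log-rank test across two or more groups.

    Returns ``(chi2, df, p)``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), int(res.degrees_of_freedom), float(res.p_value)


# ---------------------------------------------------------------------------
# Cox proportional hazards (Newton on the partial likelihood)


@dataclass
class CoxFit:
    """Result of a Cox partial-likelihood fit.

    ``summary`` has one row per covariate: coef, se, hr, hr_lower, hr_upper,
    z, p.  ``covariance`` is the inverse observed information.
    """

    coefficients: pd.Series
    covariance: pd.DataFrame
    summary: pd.DataFrame
    ties: str
    iterations: int
    converged: bool
    log_likelihood: float

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coefficients)


def _cox_loglik(beta, X, groups, ties):
    """Partial log-likelihood, gradient and Hessian.

    ``X`` must be sorted by descending follow-up time so the risk set at any
    event time is a prefix of the rows; ``groups`` is a list of
    ``(event_rows, m)`` with ``m`` the size of that prefix.  Risk-set sums
    are then prefix sums, making one evaluation O(n p^2).
    """
    p = X.shape[1]
    eta = X @ beta
    eta -= eta.max()  # guard overflow; the PL is invariant to the shift
    w = np.exp(eta)
    wX = w[:, None] * X
    cum0 = np.cumsum(w)
    cum1 = np.cumsum(wX, axis=0)
    cum2 = np.cumsum(np.einsum("ij,ik->ijk", wX, X), axis=0)
    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for ev, m in groups:
        d = len(ev)
        s0 = cum0[m - 1]
        s1 = cum1[m - 1]
        s2 = cum2[m - 1]
        xev_sum = X[ev].sum(axis=0)
        ll += float(eta[ev].sum())
        if ties == "breslow" or d == 1:
            ll -= d * math.log(s0)
            mean1 = s1 / s0
            grad += xev_sum - d * mean1
            hess -= d * (s2 / s0 - np.outer(mean1, mean1))
        else:  # efron
            sd0 = w[ev].sum()
            sd1 = wX[ev].sum(axis=0)
            sd2 = X[ev].T @ wX[ev]
            grad += xev_sum
            for l in range(d):
                f = l / d
                a0 = s0 - f * sd0
                a1 = s1 - f * sd1
                a2 = s2 - f * sd2
                ll -= math.log(a0)
                grad -= a1 / a0
                hess -= a2 / a0 - np.outer(a1 / a0, a1 / a0)
    return ll, grad, hess


def _risk_groups(time, event):
    """Sorted-prefix risk sets: rows sorted by descending time.

    Returns ``(order, groups)`` where ``groups`` pairs the (sorted-frame)
    event rows at each unique event time with the prefix length m of rows
    still at risk at that time.
    """
    order = np.argsort(-time, kind="stable")
    ts = time[order]
    es = event[order]
    groups = []
    for t in np.unique(time[event == 1]):
        m = int(np.searchsorted(-ts, -t, side="right"))
        ev = np.nonzero((ts == t) & (es == 1))[0]
        groups.append((ev, m))
    return order, groups


def fit_cox(
    data: pd.DataFrame,
    covariates,
    time_col: str = "follow_up_years",
    event_col: str = "event",
    ties: str = "efron",
    max_iter: int = 50,
) -> CoxFit:
    """Fit a Cox PH model by damped Newton iterations on the partial likelihood.

    Ties are handled by the Efron (default) or Breslow correction.  Step
    halving enforces a non-decreasing log-likelihood; convergence requires
    the gradient max-norm to fall below 1e-6.

    Raises on missing values, absence of events, or a rank-deficient
    (collinear) design.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"unknown ties method {ties!r}")
    covariates = list(covariates)
    cols = covariates + [time_col, event_col]
    sub = data[cols]
    if sub.isna().any().any():
        raise ValueError("missing values in survival data")
    X = sub[covariates].to_numpy(dtype=float)
    time = sub[time_col].to_numpy(dtype=float)
    event = sub[event_col].to_numpy(dtype=int)
    if event.sum() < 1:
        raise ValueError("no events: cannot fit a Cox model")
    Xc = X - X.mean(axis=0)
    if np.linalg.matrix_rank(Xc) < X.shape[1]:
        raise np.linalg.LinAlgError(
            "collinear covariates: the design matrix is rank deficient"
        )
    # centre and scale to unit variance for conditioning; the partial
    # likelihood is invariant to centring and the fit is transformed back
    scale_ = Xc.std(axis=0, ddof=0)
    scale_[scale_ == 0] = 1.0
    order, groups = _risk_groups(time, event)
    X = (Xc / scale_)[order]
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _cox_loglik(beta, X, groups, ties)
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        step = np.linalg.solve(-hess, grad)
        factor = 1.0
        for _ in range(30):  # step halving: never decrease the likelihood
            cand = beta + factor * step
            ll_new, grad_new, hess_new = _cox_loglik(cand, X, groups, ties)
            if ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        beta, ll, grad, hess = cand, ll_new, grad_new, hess_new
        # gradient criterion, plus a step criterion for large cohorts where
        # the gradient's floating-point floor sits above the tolerance
        if np.max(np.abs(grad)) < 1e-6 or np.max(np.abs(factor * step)) < 1e-10:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"Cox fit did not converge in {max_iter} iterations "
            f"(|grad|_max = {np.max(np.abs(grad)):.3g}, ll = {ll:.6f})"
        )
    cov = np.linalg.inv(-hess)
    # back-transform to the original covariate scale
    beta = beta / scale_
    cov = cov / np.outer(scale_, scale_)
    se = np.sqrt(np.diag(cov))
    coef = pd.Series(beta, index=covariates, name="coef")
    z = beta / se
    with np.errstate(over="ignore"):  # near-empty strata can give huge CIs
        summary = pd.DataFrame(
            {
                "coef": beta,
                "se": se,
                "hr": np.exp(beta),
                "hr_lower": np.exp(beta - _Z95 * se),
                "hr_upper": np.exp(beta + _Z95 * se),
                "z": z,
                "p": 2 * stats.norm.sf(np.abs(z)),
            },
            index=covariates,
        )
    return CoxFit(
        coefficients=coef,
        covariance=pd.DataFrame(cov, index=covariates, columns=covariates),
        summary=summary,
        ties=ties,
        iterations=iterations,
        converged=bool(converged),
        log_likelihood=float(ll),
    )


# ---------------------------------------------------------------------------
# deciles


def decile_groups(values) -> np.ndarray:
    """Decile index (1..10) per value; ties at a boundary go to the lower decile."""
    values = np.asarray(values, dtype=float)
    if values.size < 10:
        raise ValueError("need at least 10 values to form deciles")
    boundaries = np.quantile(values, np.arange(1, 10) / 10.0)
    if np.any(np.diff(boundaries) <= 0):
        raise ValueError("degenerate quantiles: tied decile boundaries")
    return 1 + np.sum(values[:, None] > boundaries[None, :], axis=1)


def decile_hazard_ratios(
    data: pd.DataFrame,
    exposure: str,
    adjusters=(),
    time_col: str = "follow_up_years",
    event_col: str = "event",
    ties: str = "efron",
):
    """Hazard ratio with 95% CI per decile of ``exposure``, decile 1 = reference.

    Fits a single Cox model with nine decile indicators plus the adjusters.
    Returns ``(table, fit)`` where the table has one row per decile with
    columns hr, hr_lower, hr_upper, n, events (decile 1 has HR 1 and no CI).
    """
    adjusters = list(adjusters)
    dec = decile_groups(data[exposure].to_numpy())
    work = data[[time_col, event_col] + adjusters].copy()
    ind_cols = []
    for d in range(2, 11):
        col = f"{exposure}_d{d}"
        work[col] = (dec == d).astype(float)
        ind_cols.append(col)
    fit = fit_cox(work, ind_cols + adjusters, time_col, event_col, ties)
    rows = [
        {
            "decile": 1,
            "hr": 1.0,
            "hr_lower": np.nan,
            "hr_upper": np.nan,
            "n": int((dec == 1).sum()),
            "events": int(data.loc[dec == 1, event_col].sum()),
        }
    ]
    for d, col in zip(range(2, 11), ind_cols):
        s = fit.summary.loc[col]
        rows.append(
            {
                "decile": d,
                "hr": s["hr"],
                "hr_lower": s["hr_lower"],
                "hr_upper": s["hr_upper"],
                "n": int((dec == d).sum()),
                "events": int(data.loc[dec == d, event_col].sum()),
            }
        )
    return pd.DataFrame(rows).set_index("decile"), fit


# ---------------------------------------------------------------------------
# restricted cubic splines


@dataclass(frozen=True)
class SplineSpec:
    """Restricted-cubic-spline specification.

    ``n_knots`` knots placed at ``percentiles`` of the exposure (defaults:
    4 knots at the 5/35/65/95th percentiles, the standard placement), linear
    beyond the boundary knots.  ``reference`` is the exposure value mapped to
    HR = 1 (default: the sample median).
    """

    n_knots: int = 4
    percentiles: tuple = (5.0, 35.0, 65.0, 95.0)
    reference: float | None = None

    def __post_init__(self):
        if self.n_knots < 3:
            raise ValueError("restricted cubic splines need at least 3 knots")
        if len(self.percentiles) != self.n_knots:
            raise ValueError("percentiles length must equal n_knots")
        if np.any(np.diff(self.percentiles) <= 0):
            raise ValueError("percentiles must be strictly increasing")

    def knots_for(self, values) -> np.ndarray:
        knots = np.percentile(np.asarray(values, float), self.percentiles)
        if np.any(np.diff(knots) <= 0):
            raise ValueError("knots are not strictly increasing for these data")
        return knots


def rcs_basis(x, knots) -> np.ndarray:
    """Restricted cubic spline basis (truncated-power form, normalized).

    Column 0 is the linear term; columns 1..k-2 are the restricted cubic
    terms, constrained so the function is linear beyond the boundary knots.
    The cubic terms are scaled by (t_k - t_1)^2 for numerical balance.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    k = len(knots)
    if k < 3 or np.any(np.diff(knots) <= 0):
        raise ValueError("need at least 3 strictly increasing knots")
    t1, tkm1, tk = knots[0], knots[-2], knots[-1]
    norm = (tk - t1) ** 2

    def cube(v):
        return np.clip(v, 0.0, None) ** 3

    cols = [x]
    for tj in knots[:-2]:
        term = (
            cube(x - tj)
            - cube(x - tkm1) * (tk - tj) / (tk - tkm1)
            + cube(x - tk) * (tkm1 - tj) / (tk - tkm1)
        ) / norm
        cols.append(term)
    return np.column_stack(cols)


def spline_hazard_curve(
    data: pd.DataFrame,
    exposure: str,
    adjusters=(),
    spec: SplineSpec = SplineSpec(),
    grid=None,
    time_col: str = "follow_up_years",
    event_col: str = "event",
    ties: str = "efron",
):
    """Adjusted spline dose-response curve: HR(x) relative to a reference value.

    Fits a Cox model on the restricted-cubic-spline basis of ``exposure``
    plus ``adjusters``; HR(x) = exp(f(x) - f(ref)) with delta-method Wald
    CIs from the basis contrast.  Also reports the joint Wald test of the
    nonlinear terms (null: log-linear dose-response).

    Returns ``(curve, info)``; ``curve`` has columns exposure value, hr,
    hr_lower, hr_upper; ``info`` carries the fit, knots, reference and the
    nonlinearity chi2/df/p.
    """
    adjusters = list(adjusters)
    xvals = data[exposure].to_numpy(dtype=float)
    knots = spec.knots_for(xvals)
    reference = float(np.median(xvals)) if spec.reference is None else spec.reference
    basis = rcs_basis(xvals, knots)
    ncols = basis.shape[1]
    basis_cols = [f"{exposure}_rcs{i}" for i in range(ncols)]
    work = data[[time_col, event_col] + adjusters].copy()
    for i, col in enumerate(basis_cols):
        work[col] = basis[:, i]
    fit = fit_cox(work, basis_cols + adjusters, time_col, event_col, ties)
    if grid is None:
        grid = np.linspace(np.percentile(xvals, 1), np.percentile(xvals, 99), 101)
    grid = np.asarray(grid, dtype=float)
    contrast = rcs_basis(grid, knots) - rcs_basis(np.array([reference]), knots)
    beta = fit.coefficients[basis_cols].to_numpy()
    cov = fit.covariance.loc[basis_cols, basis_cols].to_numpy()
    log_hr = contrast @ beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", contrast, cov, contrast))
    curve = pd.DataFrame(
        {
            exposure: grid,
            "hr": np.exp(log_hr),
            "hr_lower": np.exp(log_hr - _Z95 * se),
            "hr_upper": np.exp(log_hr + _Z95 * se),
        }
    )
    # joint Wald test of the nonlinear (cubic) terms
    nl_cols = basis_cols[1:]
    b_nl = fit.coefficients[nl_cols].to_numpy()
    cov_nl = fit.covariance.loc[nl_cols, nl_cols].to_numpy()
    chi2 = float(b_nl @ np.linalg.solve(cov_nl, b_nl))
    df_nl = len(nl_cols)
    info = {
        "fit": fit,
        "knots": knots,
        "reference": reference,
        "nonlinear_chi2": chi2,
        "nonlinear_df": df_nl,
        "nonlinear_p": float(stats.chi2.sf(chi2, df_nl)),
    }
    return curve, info
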