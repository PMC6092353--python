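"""ROC curves, Mann-Whitney AUC, DeLong comparison of correlated AUCs, and
the FRS-plus-parameter integrated AUC.

The AUC is computed from midranks (the Mann-Whitney U statistic divided by
the number of case/control pairs), which handles ties correctly and equals
the trapezoidal integral of the empirical ROC curve.  Variances and the
paired comparison use DeLong's structural components: per-case and
per-control placement values whose empirical covariance estimates the joint
sampling covariance of the correlated AUCs.

The outcome here is the binary event indicator over the fixed follow-up
window; censoring time is deliberately ignored (appropriate when follow-up
is administratively complete), which the result metadata records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["ROCResult", "roc_curve", "auc_mann_whitney", "delong_compare", "integrated_auc"]


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    uniq = np.unique(labels)
    if not np.isin(uniq, [0, 1]).all():
        raise ValueError("labels must be binary 0/1")
    if uniq.size < 2:
        raise ValueError("both classes must be present")
    return scores, labels.astype(int)


def _placements(scores, labels):
    """DeLong structural components.

    V10[i] = P-hat(score_case_i > random control) (ties count 1/2);
    V01[j] = P-hat(random case > score_control_j).
    """
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    m, n = cases.size, controls.size
    ranks_all = stats.rankdata(np.concatenate([cases, controls]))
    v10 = (ranks_all[:m] - stats.rankdata(cases)) / n
    v01 = 1.0 - (ranks_all[m:] - stats.rankdata(controls)) / m
    return v10, v01


@dataclass
class ROCResult:
    """Empirical ROC curve with DeLong machinery retained for paired tests."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    delong_variance: float
    v10: np.ndarray = field(repr=False)
    v01: np.ndarray = field(repr=False)

    @property
    def auc_se(self) -> float:
        return float(np.sqrt(self.delong_variance))

    def auc_ci(self, alpha: float = 0.05):
        z = stats.norm.ppf(1 - alpha / 2)
        half = z * self.auc_se
        return (self.auc - half, self.auc + half)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )


def auc_mann_whitney(scores, labels) -> float:
    """Midrank Mann-Whitney AUC: P(case > control) + P(tie)/2."""
    scores, labels = _validate(scores, labels)
    v10, _ = _placements(scores, labels)
    return float(v10.mean())


def roc_curve(scores, labels) -> ROCResult:
    """Empirical ROC curve over all distinct thresholds, with DeLong variance."""
    scores, labels = _validate(scores, labels)
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores, drop_intermediate=False)
    v10, v01 = _placements(scores, labels)
    auc = float(v10.mean())
    var = _delong_var(v10, v01)
    return ROCResult(
        thresholds=thresholds,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        delong_variance=var,
        v10=v10,
        v01=v01,
    )


def _delong_var(v10, v01) -> float:
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def delong_compare(scores_a, scores_b, labels):
    """DeLong paired comparison of two correlated AUCs on the same subjects.

    Returns a dict with ``auc_a``, ``auc_b``, ``delta`` (= auc_a - auc_b),
    ``variance``, ``z`` and the two-sided normal ``p``.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("score vectors must have the same length")
    _, labels = _validate(scores_a, labels)
    va10, va01 = _placements(scores_a, labels)
    vb10, vb01 = _placements(scores_b, labels)
    m, n = va10.size, va01.size
    auc_a, auc_b = float(va10.mean()), float(vb10.mean())
    delta = auc_a - auc_b
    if m > 1:
        s10 = np.cov(np.vstack([va10, vb10]), ddof=1)
    else:
        s10 = np.zeros((2, 2))
    if n > 1:
        s01 = np.cov(np.vstack([va01, vb01]), ddof=1)
    else:
        s01 = np.zeros((2, 2))
    var = float(
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    if var <= 0:
        z = 0.0 if delta == 0 else np.sign(delta) * np.inf
    else:
        z = delta / np.sqrt(var)
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return {
        "auc_a": auc_a,
        "auc_b": auc_b,
        "delta": delta,
        "variance": var,
        "z": float(z),
        "p": p,
    }


def integrated_auc(frs_values, parameter_values, labels):
    """Discrimination of FRS combined with one obesity parameter.

    The combined score is the in-sample linear predictor of a logistic
    regression of the event on the FRS linear predictor and the parameter;
    its AUC is compared against FRS alone with the DeLong paired test.

    Returns a dict with ``auc_frs``, ``auc_combined``, ``delta``, ``z``,
    ``p`` and the fitted logistic coefficients.
    """
    frs_values = np.asarray(frs_values, dtype=float)
    parameter_values = np.asarray(parameter_values, dtype=float)
    _, y = _validate(frs_values, labels)
    X = sm.add_constant(np.column_stack([frs_values, parameter_values]))
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as exc:  # perfect separation etc.
        raise RuntimeError(f"integrated-model logistic fit failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError("integrated-model logistic fit did not converge")
    combined = X @ fit.params
    cmp = delong_compare(combined, frs_values, y)
    return {
        "auc_frs": cmp["auc_b"],
        "auc_combined": cmp["auc_a"],
        "delta": cmp["delta"],
        "variance": cmp["variance"],
        "z": cmp["z"],
        "p": cmp["p"],
        "coefficients": {
            "const": float(fit.params[0]),
            "frs": float(fit.params[1]),
            "parameter": float(fit.params[2]),
        },
    }
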