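"""Cohort-level statistics: 2x2 Pearson chi-square, ROC cut-off selection,
Kaplan-Meier estimation, the log-rank test, and Cox proportional-hazards
regression with backward stepwise elimination.

Conventions: the chi-square is the uncorrected Pearson statistic on 1 d.f.
(no Yates continuity correction); the ROC cut-off maximizes sensitivity +
specificity (Youden's J + 1) with ties resolved toward the smaller
threshold; Cox fits use Efron's tie handling; all p-values are two-tailed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import logrank_test
from scipy import stats

__all__ = [
    "chi2_2x2",
    "roc_optimal_cutoff",
    "km_estimate",
    "logrank",
    "cox_fit",
    "ROCResult",
    "KMEstimate",
    "CoxResult",
    "SeparationError",
]


class SeparationError(RuntimeError):
    """Raised when a Cox fit fails to converge, e.g. under complete
    separation (a covariate perfectly orders events)."""


def chi2_2x2(table) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table, 1 d.f.

    Rows are the score groups, columns the outcome; returns ``(chi2, p)``
    with the p-value from the chi-square survival function.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {t.shape}")
    if np.any(t < 0) or not np.all(t == np.round(t)):
        raise ValueError("table entries must be nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("chi-square is undefined for a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    optimal_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float


def roc_optimal_cutoff(scores, labels) -> ROCResult:
    """Empirical ROC with the cut-off that maximizes sensitivity + specificity.

    A subject is called positive when ``score >= threshold``.  Thresholds
    are midpoints between consecutive distinct scores plus ±inf; AUC is the
    trapezoidal area under the empirical curve (equal to the Mann-Whitney
    rank statistic).  Ties in Youden's J are broken toward the smaller
    cut-off.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")

    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2 if uniq.size > 1 else np.empty(0)
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))

    pos = scores[labels == 1]
    neg = scores[labels == 0]
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])

    fpr = 1 - spec
    order = np.lexsort((sens, fpr))
    auc = float(np.trapezoid(sens[order], fpr[order]))

    j = sens + spec
    best = int(np.flatnonzero(j == j.max())[0])  # thresholds ascend: first = smallest
    return ROCResult(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        optimal_cutoff=float(thresholds[best]),
        sens_at_cutoff=float(sens[best]),
        spec_at_cutoff=float(spec[best]),
    )


@dataclass
class KMEstimate:
    timeline: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0


def km_estimate(times, events) -> KMEstimate:
    """Product-limit (Kaplan-Meier) survival estimate with right censoring."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one subject")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    survival = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(timeline).to_numpy(dtype=float)
    return KMEstimate(timeline=timeline, survival=survival, at_risk=at_risk)


def logrank(times, events, group) -> tuple[float, float]:
    """Mantel-Cox log-rank test between two groups, 1 d.f.

    Returns ``(statistic, p)``.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels.size}")
    a = group == levels[0]
    res = logrank_test(times[a], times[~a], events[a], events[~a])
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    summary: pd.DataFrame  # per covariate: hr, ci_lower, ci_upper, p, coef
    dropped: list = field(default_factory=list)  # backward-eliminated covariates

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def _fit_cox(df: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            cph.fit(
                df[["time", "event", *covariates]],
                duration_col="time",
                event_col="event",
            )
        except (ConvergenceError, ConvergenceWarning, ValueError) as exc:
            raise SeparationError(
                f"Cox fit did not converge (possible separation): {exc}"
            ) from exc
    s = cph.summary
    return pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lower": s["exp(coef) lower 95%"],
            "ci_upper": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )


def cox_fit(
    times,
    events,
    covariates: pd.DataFrame,
    backward: bool = False,
    alpha_remove: float = 0.05,
) -> CoxResult:
    """Cox proportional-hazards fit (Efron ties, Wald CIs and p-values).

    With ``backward=True`` the covariate with the largest Wald p-value is
    dropped while that p-value exceeds ``alpha_remove``, refitting after
    each removal (removal-only stepwise selection).

    Raises
    ------
    ValueError
        If there are no events or a covariate is constant.
    SeparationError
        If the partial-likelihood maximization does not converge, e.g.
        under complete separation.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        raise ValueError("no events: the partial likelihood is uninformative")
    covariates = pd.DataFrame(covariates).reset_index(drop=True)
    for col in covariates.columns:
        if covariates[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} is constant: no information")
    df = covariates.copy()
    df["time"] = times
    df["event"] = events

    cols = list(covariates.columns)
    summary = _fit_cox(df, cols)
    dropped: list[str] = []
    if backward:
        while len(cols) > 1 and summary["p"].max() > alpha_remove:
            worst = summary["p"].idxmax()
            cols.remove(worst)
            dropped.append(worst)
            summary = _fit_cox(df, cols)
    return CoxResult(summary=summary, dropped=dropped)
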