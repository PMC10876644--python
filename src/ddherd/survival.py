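"""Survival analysis: Kaplan-Meier, log-rank, Cox PH, and the maximally
selected survival cutpoint used to define the "ultrahigh" ERBB2 group.

Kaplan-Meier estimation, the log-rank test, and Cox proportional-hazards
fitting (Efron handling of ties, Wald confidence intervals) are provided
through lifelines behind this module's interface.  The optimal-cutpoint
search is implemented here: over all candidate splits of a continuous marker
(midpoints of sorted unique values, each side holding at least ``minprop``
of the cohort), it returns the split maximizing the absolute standardized
two-sample log-rank statistic — the procedure used to derive the published
ultrahigh ERBB2 CN cutoff of 19.7 in trastuzumab-treated patients.  No
selection-bias correction of the resulting p-value is applied.

Also included: the top-fraction classifier used for the RNA-seq surrogate
cohort (highest ceil(fraction * n) values positive) and the between-protocol
expression normalization (log2(x + 0.1), per-protocol mean centering to a
reference protocol's baseline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "KMResult",
    "CutpointResult",
    "CoxFit",
    "TopFractionResult",
    "km_estimator",
    "logrank_test",
    "cox_fit",
    "univariable_screen",
    "select_covariates",
    "optimal_cutpoint",
    "top_fraction_classifier",
    "normalize_protocol_batches",
]


@dataclass
class KMResult:
    """Product-limit survival estimate with an at-risk table."""

    survival: pd.DataFrame  # index: time; column: survival probability
    risk_table: pd.DataFrame  # at-risk / events / censored per event time
    median_survival: float

    def at(self, t: float) -> float:
        """S(t): right-continuous step-function lookup."""
        s = self.survival.iloc[:, 0]
        eligible = s[s.index <= t]
        return float(eligible.iloc[-1]) if len(eligible) else 1.0


@dataclass
class CutpointResult:
    """Maximally selected survival split of a continuous marker."""

    cutpoint: float
    standardized_statistic: float
    minprop: float
    candidates: pd.DataFrame  # cutpoint, statistic per candidate


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary (per-covariate rows)."""

    summary: pd.DataFrame  # coef, hazard_ratio, ci_lower, ci_upper, p
    converged: bool
    n: int
    n_events: int

    def hazard_ratio(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hazard_ratio"])


@dataclass
class TopFractionResult:
    """Top-fraction binary classification of a continuous marker."""

    labels: np.ndarray
    threshold: float
    achieved_fraction: float


def _check_times(time) -> np.ndarray:
    time = np.asarray(time, dtype=float)
    if len(time) == 0:
        raise ValueError("at least one subject is required")
    if np.any(time <= 0) or np.any(~np.isfinite(time)):
        raise ValueError("survival times must be positive and finite")
    return time


def km_estimator(time, event) -> KMResult:
    """Kaplan-Meier product-limit estimate: S(0)=1, right-continuous,
    non-increasing."""
    time = _check_times(time)
    event = np.asarray(event).astype(int)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    surv = kmf.survival_function_
    event_times = np.unique(time)
    at_risk = np.array([(time >= t).sum() for t in event_times])
    d = np.array([((time == t) & (event == 1)).sum() for t in event_times])
    c = np.array([((time == t) & (event == 0)).sum() for t in event_times])
    risk = pd.DataFrame(
        {"at_risk": at_risk, "events": d, "censored": c}, index=event_times
    )
    risk.index.name = "time"
    return KMResult(
        survival=surv,
        risk_table=risk,
        median_survival=float(kmf.median_survival_time_),
    )


def logrank_test(time, event, group) -> tuple[float, float]:
    """Log-rank test across >= 2 groups; returns (chi-square statistic, p).

    For two groups this is the standard 1-df observed-minus-expected test.
    """
    time = _check_times(time)
    event = np.asarray(event).astype(int)
    group = np.asarray(group)
    if len(np.unique(group)) < 2:
        raise ValueError("log-rank test requires at least two groups")
    if event.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = multivariate_logrank_test(time, group, event)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str] | None = None,
) -> CoxFit:
    """Cox proportional-hazards fit (partial likelihood, Efron ties, Wald CIs).

    Non-convergence / monotone-likelihood problems are reported through the
    ``converged`` flag rather than raised, with NaN estimates.
    """
    cols = covariates if covariates is not None else [
        c for c in data.columns if c not in (duration_col, event_col)
    ]
    if not cols:
        raise ValueError("no covariates to fit")
    sub = data[[duration_col, event_col, *cols]].dropna()
    _check_times(sub[duration_col])
    if sub[event_col].sum() == 0:
        raise ValueError("Cox fit requires at least one event")
    for c in cols:
        if sub[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant")

    cph = CoxPHFitter()
    try:
        cph.fit(sub, duration_col=duration_col, event_col=event_col)
        s = cph.summary
        summary = pd.DataFrame(
            {
                "coef": s["coef"],
                "hazard_ratio": s["exp(coef)"],
                "ci_lower": np.exp(s["coef lower 95%"]),
                "ci_upper": np.exp(s["coef upper 95%"]),
                "p": s["p"],
            }
        )
        converged = bool(np.isfinite(summary["coef"]).all())
    except ConvergenceError:
        summary = pd.DataFrame(
            {
                "coef": [math.nan] * len(cols),
                "hazard_ratio": [math.nan] * len(cols),
                "ci_lower": [math.nan] * len(cols),
                "ci_upper": [math.nan] * len(cols),
                "p": [math.nan] * len(cols),
            },
            index=cols,
        )
        converged = False
    return CoxFit(
        summary=summary,
        converged=converged,
        n=len(sub),
        n_events=int(sub[event_col].sum()),
    )


def univariable_screen(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: list[str],
) -> pd.DataFrame:
    """One single-covariate Cox fit per candidate; returns the summary rows."""
    rows = []
    for c in covariates:
        fit = cox_fit(data, duration_col, event_col, [c])
        row = fit.summary.loc[c].to_dict()
        row["covariate"] = c
        rows.append(row)
    return pd.DataFrame(rows).set_index("covariate")


def select_covariates(
    data: pd.DataFrame,
    endpoints: list[tuple[str, str]],
    covariates: list[str],
    alpha: float = 0.1,
) -> list[str]:
    """Multivariable covariate selection: keep covariates with univariable
    p < ``alpha`` for *any* endpoint (each endpoint a (duration, event) pair)."""
    keep: list[str] = []
    for c in covariates:
        for duration_col, event_col in endpoints:
            p = univariable_screen(data, duration_col, event_col, [c])["p"].iloc[0]
            if np.isfinite(p) and p < alpha:
                keep.append(c)
                break
    return keep


def _logrank_oev(time, event, ingroup) -> tuple[float, float, float]:
    """Observed events, expectation, and variance for one group of a
    two-sample log-rank test (hypergeometric increments at event times)."""
    o = e = v = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        n1 = (at_risk & ingroup).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & ingroup).sum()
        o += d1
        e += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o, e, v


def optimal_cutpoint(values, time, event, minprop: float = 0.1) -> CutpointResult:
    """Maximally selected survival cutpoint of a continuous marker.

    Candidate splits are the midpoints of consecutive sorted unique marker
    values for which both sides retain at least ``minprop`` of the subjects;
    the returned cutpoint maximizes |standardized log-rank statistic|
    (O - E)/sqrt(V) for the above-cutpoint group, ties broken toward the
    smallest cutpoint.
    """
    values = np.asarray(values, dtype=float)
    time = _check_times(time)
    event = np.asarray(event).astype(int)
    if not 0 < minprop < 0.5:
        raise ValueError("minprop must lie in (0, 0.5)")
    n = len(values)
    uniq = np.unique(values)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    floor = minprop * n
    candidates = [c for c in mids if (values > c).sum() >= floor and (values <= c).sum() >= floor]
    if not candidates:
        raise ValueError("too few distinct values to satisfy minprop")

    rows = []
    best = None
    for c in candidates:
        high = values > c
        o, e, v = _logrank_oev(time, event, high)
        z = (o - e) / math.sqrt(v) if v > 0 else 0.0
        rows.append({"cutpoint": c, "statistic": z})
        if best is None or abs(z) > abs(best[1]) + 1e-12:
            best = (c, z)
    return CutpointResult(
        cutpoint=float(best[0]),
        standardized_statistic=float(best[1]),
        minprop=minprop,
        candidates=pd.DataFrame(rows),
    )


def top_fraction_classifier(values, fraction: float) -> TopFractionResult:
    """Label the highest ceil(fraction * n) values positive (minimum one).

    Ties at the boundary are all included and the achieved fraction is
    reported alongside the labels.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        raise ValueError("empty values")
    k = max(1, math.ceil(fraction * n))
    threshold = np.sort(values)[n - k]
    labels = values >= threshold
    return TopFractionResult(
        labels=labels,
        threshold=float(threshold),
        achieved_fraction=float(labels.mean()),
    )


def normalize_protocol_batches(
    expr, protocol_labels, reference_protocol: str = "dUTP"
) -> np.ndarray:
    """Between-protocol expression normalization.

    Applies log2(x + 0.1) (the offset keeps zero expression finite), then
    centers each protocol at the reference protocol's mean:
    out = log2(x + 0.1) - mean(protocol) + mean(reference).
    """
    expr = np.asarray(expr, dtype=float)
    protocol_labels = np.asarray(protocol_labels)
    if expr.shape != protocol_labels.shape:
        raise ValueError("expr and protocol_labels must have equal length")
    if reference_protocol not in set(protocol_labels):
        raise ValueError(f"reference protocol {reference_protocol!r} not present")
    logv = np.log2(expr + 0.1)
    ref_mean = logv[protocol_labels == reference_protocol].mean()
    out = np.empty_like(logv)
    for p in np.unique(protocol_labels):
        mask = protocol_labels == p
        out[mask] = logv[mask] - logv[mask].mean() + ref_mean
    return out
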