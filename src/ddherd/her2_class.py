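"""HER2 status classification from ddPCR copy-number metrics.

Two continuous metrics drive classification: total ERBB2 copies per genome
(ERBB2 CN, referenced to the copy-number-stable region) and the dual-probe
ISH analogue ERBB2/CEP17 ratio.  Thresholds for calling amplification are
derived on a training cohort by ROC analysis with the maximum Youden index
J = sensitivity + specificity - 1 (published values: CN >= 3.05, ratio >=
1.55; both boundaries inclusive).

Samples are then assigned to four diagnostic groups analogous to dual-probe
ISH reporting:

====== ============ ============= =========================================
group  ERBB2 CN     ERBB2/CEP17   interpretation
====== ============ ============= =========================================
1      >= 3.05      >= 1.55       classic HER2 amplified
2      <  3.05      >= 1.55       monosomy 17 pattern
3      >= 3.05      <  1.55       CEP17 co-amplification (prev. polysomy)
5      <  3.05      <  1.55       classic HER2 non-amplified
====== ============ ============= =========================================

No equivocal group (4) is ever emitted.  Predictive values against clinical
ISH follow the published row convention: the PPV numerator counts
ISH-amplified cases, the NPV numerator counts cases *not* ISH-amplified
(normal or missing), and ISH-missing cases remain in every denominator.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ThresholdSet",
    "RocResult",
    "PerfMetrics",
    "GroupTable",
    "roc_curve",
    "youden_threshold",
    "classify_her2",
    "assign_group",
    "performance_metrics",
    "group_table",
    "table3_counts",
    "table3_samples",
]

IHC_LEVELS = ("0-1+", "2+", "3+")
ISH_LEVELS = ("amplified", "normal", "missing")


@dataclass(frozen=True)
class ThresholdSet:
    """Classification thresholds: CN and ratio cutoffs plus the survival-derived
    ultrahigh CN cutoff (defaults are the published values)."""

    cn_threshold: float = 3.05
    ratio_threshold: float = 1.55
    ultrahigh_cutoff: float = 19.7

    def __post_init__(self) -> None:
        if min(self.cn_threshold, self.ratio_threshold, self.ultrahigh_cutoff) <= 0:
            raise ValueError("all thresholds must be positive")
        if self.ultrahigh_cutoff <= self.cn_threshold:
            raise ValueError("ultrahigh_cutoff must exceed cn_threshold")


@dataclass
class RocResult:
    """ROC sweep: per-threshold operating points, trapezoidal AUC, and the
    Youden-optimal threshold."""

    points: pd.DataFrame  # columns: threshold, sensitivity, specificity
    auc: float
    optimal_threshold: float
    optimal_youden: float


@dataclass
class PerfMetrics:
    """Confusion counts and derived diagnostic metrics.

    Undefined ratios (zero denominator) are reported as NaN, never 0.
    ``n_missing_reference`` counts samples excluded for lacking a reference
    label.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    n_missing_reference: int = 0

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else math.nan

    @property
    def accuracy(self) -> float:
        total = self.tp + self.fp + self.tn + self.fn
        return (self.tp + self.tn) / total if total else math.nan

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else math.nan

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if (self.tn + self.fn) else math.nan

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "ppv": self.ppv, "npv": self.npv,
            "n_missing_reference": self.n_missing_reference,
        }


def roc_curve(scores, labels) -> RocResult:
    """ROC analysis of a continuous score against a binary reference.

    Candidate thresholds are the midpoints of consecutive sorted unique
    scores plus sentinels below the minimum and above the maximum; a sample
    is called positive when score >= threshold.  Tied scores therefore always
    fall on the same side of every candidate.  AUC is the trapezoidal area
    of the resulting curve (equal to the Mann-Whitney pair-counting
    statistic), and the optimal threshold maximizes the Youden index with
    ties broken toward the smallest threshold (favoring sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present for ROC analysis")

    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))

    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    sens = np.array([(scores[labels] >= t).sum() / n_pos for t in thresholds])
    spec = np.array([(scores[~labels] < t).sum() / n_neg for t in thresholds])

    # walking thresholds from high to low makes (fpr, sens) jointly
    # non-decreasing, which is the correct polyline for the trapezoid area
    fpr = 1.0 - spec
    order = np.argsort(-thresholds, kind="stable")
    auc = float(np.trapezoid(sens[order], fpr[order]))

    finite = np.isfinite(thresholds)
    j = sens + spec - 1.0
    j_finite = j[finite]
    t_finite = thresholds[finite]
    if len(t_finite):
        # J values within 1e-12 are ties (guards float fuzz from the two
        # rate computations); ties break toward the smallest threshold,
        # favoring sensitivity
        jmax = float(j_finite.max())
        tied = j_finite >= jmax - 1e-12
        optimal_threshold = float(t_finite[tied].min())
        optimal_youden = jmax
    else:  # constant scores: no finite candidate, J is 0 everywhere
        optimal_threshold = float(uniq[0])
        optimal_youden = 0.0

    points = pd.DataFrame(
        {"threshold": thresholds, "sensitivity": sens, "specificity": spec}
    )
    return RocResult(
        points=points,
        auc=auc,
        optimal_threshold=optimal_threshold,
        optimal_youden=optimal_youden,
    )


def youden_threshold(roc: RocResult) -> tuple[float, float]:
    """The Youden-optimal (threshold, J) of a computed ROC curve."""
    return roc.optimal_threshold, roc.optimal_youden


def _metric(sample, name: str) -> float:
    """Fetch erbb2_cn / erbb2_cep17_ratio from a SampleCN, mapping, or row."""
    if hasattr(sample, name):
        value = getattr(sample, name)
    else:
        try:
            value = sample[name]
        except (KeyError, TypeError, IndexError):
            value = None
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValueError(f"sample is missing required field {name!r}")
    return float(value)


def classify_her2(sample, thresholds: ThresholdSet, criterion: str = "combination") -> bool:
    """Binary HER2 status under one of three criteria.

    ``cn``: ERBB2 CN >= cn_threshold.  ``ratio``: ERBB2/CEP17 >=
    ratio_threshold.  ``combination``: positive if either criterion is
    positive (the logical-OR reading of the combined metric, equivalent to
    membership in groups 1, 2 or 3).  Boundaries are inclusive.
    """
    if criterion not in {"cn", "ratio", "combination"}:
        raise ValueError(f"unknown criterion {criterion!r}")
    if criterion in {"cn", "combination"}:
        cn_pos = _metric(sample, "erbb2_cn") >= thresholds.cn_threshold
        if criterion == "cn":
            return bool(cn_pos)
    if criterion in {"ratio", "combination"}:
        ratio_pos = _metric(sample, "erbb2_cep17_ratio") >= thresholds.ratio_threshold
        if criterion == "ratio":
            return bool(ratio_pos)
    return bool(cn_pos or ratio_pos)


def assign_group(sample, thresholds: ThresholdSet) -> int:
    """Assign one of the four diagnostic groups {1, 2, 3, 5} (total partition)."""
    cn_pos = _metric(sample, "erbb2_cn") >= thresholds.cn_threshold
    ratio_pos = _metric(sample, "erbb2_cep17_ratio") >= thresholds.ratio_threshold
    if cn_pos and ratio_pos:
        return 1
    if not cn_pos and ratio_pos:
        return 2
    if cn_pos and not ratio_pos:
        return 3
    return 5


def performance_metrics(predicted, reference) -> PerfMetrics:
    """Confusion counts and diagnostic metrics of paired binary vectors.

    ``reference`` entries that are None/NaN are excluded from the confusion
    table and tallied in ``n_missing_reference``.
    """
    pred = list(predicted)
    ref = list(reference)
    if len(pred) != len(ref):
        raise ValueError("predicted and reference must have equal length")
    tp = fp = tn = fn = missing = 0
    for p, r in zip(pred, ref):
        if r is None or (isinstance(r, float) and math.isnan(r)):
            missing += 1
            continue
        p, r = bool(p), bool(r)
        if p and r:
            tp += 1
        elif p and not r:
            fp += 1
        elif not p and r:
            fn += 1
        else:
            tn += 1
    if tp + fp + tn + fn == 0:
        raise ValueError("no samples with a reference label")
    return PerfMetrics(tp=tp, fp=fp, tn=tn, fn=fn, n_missing_reference=missing)


@dataclass
class GroupTable:
    """Contingency summary of ddPCR groups against clinical IHC and ISH.

    ``counts`` holds one row per group with IHC and ISH tallies.  ``ppv``
    (groups 1-3) and ``npv`` (groups 2, 3, 5) are fractions following the
    published convention: PPV numerator = ISH-amplified, NPV numerator =
    ISH-normal + ISH-missing, denominators = full group size.
    ``group_shares`` are group sizes over the total cohort.
    """

    counts: pd.DataFrame
    ppv: dict[int, float] = field(default_factory=dict)
    npv: dict[int, float] = field(default_factory=dict)
    group_shares: dict[int, float] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return int(self.counts["n"].sum())


def _predictive_values(counts: pd.DataFrame) -> GroupTable:
    counts = counts.copy()
    counts["n"] = counts[["ihc_0_1", "ihc_2", "ihc_3"]].sum(axis=1)
    total = counts["n"].sum()
    ppv, npv, shares = {}, {}, {}
    for g, row in counts.iterrows():
        n = row["n"]
        shares[int(g)] = row["n"] / total if total else math.nan
        if int(g) in (1, 2, 3):
            ppv[int(g)] = row["ish_amplified"] / n if n else math.nan
        if int(g) in (2, 3, 5):
            npv[int(g)] = (row["ish_normal"] + row["ish_missing"]) / n if n else math.nan
    return GroupTable(counts=counts, ppv=ppv, npv=npv, group_shares=shares)


def group_table(groups, ihc, ish) -> GroupTable:
    """Tabulate per-sample group labels against IHC scores and ISH states.

    ``groups`` are integers in {1, 2, 3, 5}; ``ihc`` in {"0-1+", "2+", "3+"};
    ``ish`` in {"amplified", "normal", "missing"}.
    """
    df = pd.DataFrame({"group": groups, "ihc": ihc, "ish": ish})
    bad_ihc = set(df["ihc"]) - set(IHC_LEVELS)
    bad_ish = set(df["ish"]) - set(ISH_LEVELS)
    if bad_ihc:
        raise ValueError(f"unknown IHC levels: {sorted(bad_ihc)}")
    if bad_ish:
        raise ValueError(f"unknown ISH levels: {sorted(bad_ish)}")
    rows = {}
    for g in (1, 2, 3, 5):
        sub = df[df["group"] == g]
        rows[g] = {
            "ihc_0_1": int((sub["ihc"] == "0-1+").sum()),
            "ihc_2": int((sub["ihc"] == "2+").sum()),
            "ihc_3": int((sub["ihc"] == "3+").sum()),
            "ish_amplified": int((sub["ish"] == "amplified").sum()),
            "ish_normal": int((sub["ish"] == "normal").sum()),
            "ish_missing": int((sub["ish"] == "missing").sum()),
        }
    counts = pd.DataFrame.from_dict(rows, orient="index")
    counts.index.name = "group"
    return _predictive_values(counts)


def table3_counts() -> GroupTable:
    """The packaged published four-group contingency counts (909 tumors)."""
    with resources.files("ddherd.data").joinpath("table3_counts.json").open() as fh:
        raw = json.load(fh)
    counts = pd.DataFrame.from_dict(
        {int(g): row for g, row in raw["groups"].items()}, orient="index"
    )
    counts.index.name = "group"
    return _predictive_values(counts)


def table3_samples() -> pd.DataFrame:
    """Expand the packaged contingency counts to one synthetic row per tumor.

    IHC and ISH labels are assigned independently within each group so the
    marginal tallies reproduce the printed table exactly; joint IHC x ISH
    structure within groups is not published and not represented.
    """
    table = table3_counts()
    frames = []
    for g, row in table.counts.iterrows():
        ihc = (["0-1+"] * row["ihc_0_1"] + ["2+"] * row["ihc_2"] + ["3+"] * row["ihc_3"])
        ish = (
            ["amplified"] * row["ish_amplified"]
            + ["normal"] * row["ish_normal"]
            + ["missing"] * row["ish_missing"]
        )
        frames.append(pd.DataFrame({"group": g, "ihc": ihc, "ish": ish}))
    return pd.concat(frames, ignore_index=True)
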