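"""End-to-end orchestration: simulate -> quantify -> classify -> survival.

One :func:`run_full` call reproduces the whole analysis on a synthetic
cohort: generate patient truths, simulate and quantify one ddPCR well per
patient, fit classification thresholds on a 70/30 training split by
ROC/Youden, evaluate the four-group classification on the validation split,
and run the ultrahigh-ERBB2 survival analysis on the trastuzumab-treated
subcohort.  Every stage is seeded hierarchically from one root seed and the
report records the seed and a hash of the configuration, so a fixed
(config, seed) pair regenerates the report bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import __version__
from .cohort_sim import CohortConfig, sample_truths, simulate_cohort
from .ddpcr_sim import AssayConfig, simulate_droplets
from .droplet_quant import quantify_well
from .her2_class import (
    ThresholdSet,
    assign_group,
    classify_her2,
    group_table,
    performance_metrics,
    roc_curve,
)
from .survival import cox_fit, km_estimator, logrank_test, optimal_cutpoint

__all__ = ["RunConfig", "StageError", "train_validate_split", "run_full", "load_run_config"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial report."""

    def __init__(self, stage: str, report: dict, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.report = report
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one full pipeline run.

    ``thresholds`` fixes the classification thresholds; ``None`` fits them on
    the training split by ROC/Youden.  ``cutpoint`` is either a number or
    ``"auto"`` (maximally selected log-rank search).  ``measure_by_droplets``
    switches between droplet-level measurement of each sample and using the
    simulated true copy numbers directly (fast mode for large cohorts).
    """

    seed: int = 0
    split_fraction: float = 0.70
    cohort: CohortConfig = field(default_factory=CohortConfig)
    assay: AssayConfig = field(default_factory=AssayConfig)
    thresholds: ThresholdSet | None = None
    cutpoint: float | str = "auto"
    measure_by_droplets: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")

    def config_hash(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(type(o))

        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def train_validate_split(n: int, fraction: float = 0.70, seed: int = 0):
    """Seeded disjoint exhaustive split of ``range(n)``.

    The training size is ``round(fraction * n)`` (banker's rounding, as in
    round()); n=909 at fraction 0.70 gives 636/273.
    """
    if n < 2:
        raise ValueError("need at least two samples to split")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    k = int(round(fraction * n))
    k = min(max(k, 1), n - 1)  # both sides non-empty
    return np.sort(perm[:k]), np.sort(perm[k:])


def _measure_cohort(cohort, truths, config: RunConfig, seed_seq) -> None:
    """Attach measured erbb2_cn / ratio columns, per-sample droplet sims."""
    if config.measure_by_droplets:
        from .droplet_quant import SaturationError

        children = seed_seq.spawn(len(truths))
        cn, ratio, cep17 = [], [], []
        for truth, child in zip(truths, children):
            # saturated wells (extreme amplification) are re-run at a
            # dilution, as they would be in the laboratory
            assay = config.assay
            for dilution in (1, 4, 16, 64):
                well_seed, child = child.spawn(2)
                d = simulate_droplets(truth, assay, seed=well_seed, well_id=truth.label)
                try:
                    s = quantify_well(d, assay, sample_id=truth.label)
                    break
                except SaturationError:
                    assay = assay.with_(dna_mass_ng=config.assay.dna_mass_ng / (4 * dilution))
            else:
                raise SaturationError(f"sample {truth.label} saturated at all dilutions")
            cn.append(s.erbb2_cn)
            ratio.append(s.erbb2_cep17_ratio)
            cep17.append(s.cep17_cn)
        cohort["erbb2_cn"] = cn
        cohort["erbb2_cep17_ratio"] = ratio
        cohort["cep17_cn"] = cep17
    else:
        cohort["erbb2_cn"] = cohort["true_cn_erbb2"]
        cohort["erbb2_cep17_ratio"] = cohort["true_ratio"]
        cohort["cep17_cn"] = cohort["true_cn_cep17"]


def run_full(config: RunConfig | None = None) -> dict[str, Any]:
    """Execute the full pipeline; returns a JSON-serializable report."""
    config = config or RunConfig()
    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    root = np.random.SeedSequence(config.seed)
    cohort_seed, droplet_seed, split_seed = root.spawn(3)

    stage = "cohort_sim"
    try:
        cohort = simulate_cohort(config.cohort, seed=cohort_seed.generate_state(1)[0] % 2**31)
        truths = sample_truths(cohort, seed=cohort_seed.generate_state(2)[1] % 2**31)
        report["stages"]["cohort_sim"] = {
            "n_total": len(cohort),
            "n_trastuzumab": int(cohort["trastuzumab"].sum()),
            "cep17_gain_fraction": float((cohort["true_cn_cep17"] > 3).mean()),
        }

        stage = "droplet_measurement"
        _measure_cohort(cohort, truths, config, droplet_seed)
        report["stages"]["droplet_measurement"] = {
            "mode": "droplets" if config.measure_by_droplets else "truth",
        }

        stage = "threshold_fit"
        train_idx, valid_idx = train_validate_split(
            len(cohort), config.split_fraction, seed=split_seed.generate_state(1)[0] % 2**31
        )
        train = cohort.iloc[train_idx]
        valid = cohort.iloc[valid_idx]
        if config.thresholds is None:
            labeled = train[train["ish"] != "missing"]
            labels = (labeled["ish"] == "amplified").to_numpy()
            roc_cn = roc_curve(labeled["erbb2_cn"].to_numpy(), labels)
            roc_ratio = roc_curve(labeled["erbb2_cep17_ratio"].to_numpy(), labels)
            thresholds = ThresholdSet(
                cn_threshold=roc_cn.optimal_threshold,
                ratio_threshold=roc_ratio.optimal_threshold,
            )
            report["stages"]["threshold_fit"] = {
                "cn_threshold": thresholds.cn_threshold,
                "ratio_threshold": thresholds.ratio_threshold,
                "auc_cn": roc_cn.auc,
                "auc_ratio": roc_ratio.auc,
                "youden_cn": roc_cn.optimal_youden,
                "youden_ratio": roc_ratio.optimal_youden,
            }
        else:
            thresholds = config.thresholds
            report["stages"]["threshold_fit"] = {
                "cn_threshold": thresholds.cn_threshold,
                "ratio_threshold": thresholds.ratio_threshold,
                "fixed": True,
            }

        stage = "classification"
        perf = {}
        for name, sub in (("training", train), ("validation", valid)):
            ref = [
                None if s == "missing" else (s == "amplified") for s in sub["ish"]
            ]
            block = {}
            for criterion in ("cn", "ratio", "combination"):
                pred = [
                    classify_her2(row, thresholds, criterion)
                    for _, row in sub.iterrows()
                ]
                block[criterion] = performance_metrics(pred, ref).as_dict()
            perf[name] = block
        groups = [assign_group(row, thresholds) for _, row in cohort.iterrows()]
        cohort["ddpcr_group"] = groups
        gt = group_table(groups, cohort["ihc"], cohort["ish"])
        report["stages"]["classification"] = {
            "performance": perf,
            "group_counts": {int(g): int(n) for g, n in gt.counts["n"].items()},
            "ppv": {int(k): v for k, v in gt.ppv.items()},
            "npv": {int(k): v for k, v in gt.npv.items()},
        }

        stage = "survival"
        tz = cohort[cohort["trastuzumab"] == 1].reset_index(drop=True)
        surv_report: dict[str, Any] = {"n": len(tz)}
        if len(tz) >= 20 and tz["rfs_event"].sum() > 0:
            if config.cutpoint == "auto":
                cp = optimal_cutpoint(
                    tz["erbb2_cn"].to_numpy(),
                    tz["rfs_time"].to_numpy(),
                    tz["rfs_event"].to_numpy(),
                )
                cut = cp.cutpoint
                surv_report["cutpoint_statistic"] = cp.standardized_statistic
            else:
                cut = float(config.cutpoint)
            surv_report["cutpoint"] = cut
            tz["ultrahigh_called"] = (tz["erbb2_cn"] > cut).astype(int)
            surv_report["n_ultrahigh"] = int(tz["ultrahigh_called"].sum())
            if 0 < tz["ultrahigh_called"].sum() < len(tz):
                for endpoint, (tcol, ecol) in {
                    "rfs": ("rfs_time", "rfs_event"),
                    "os": ("os_time", "os_event"),
                }.items():
                    stat, p = logrank_test(tz[tcol], tz[ecol], tz["ultrahigh_called"])
                    fit = cox_fit(
                        tz[[tcol, ecol, "ultrahigh_called"]], tcol, ecol,
                        ["ultrahigh_called"],
                    )
                    row = fit.summary.loc["ultrahigh_called"]
                    km = km_estimator(tz[tcol], tz[ecol])
                    surv_report[endpoint] = {
                        "logrank_statistic": stat,
                        "logrank_p": p,
                        "hazard_ratio": float(row["hazard_ratio"]),
                        "ci95": [float(row["ci_lower"]), float(row["ci_upper"])],
                        "cox_p": float(row["p"]),
                        "median_survival": km.median_survival
                        if math.isfinite(km.median_survival)
                        else None,
                    }
        report["stages"]["survival"] = surv_report
    except Exception as exc:  # noqa: BLE001 - atomic per-stage failure reporting
        raise StageError(stage, report, exc) from exc

    return report


def load_run_config(path) -> RunConfig:
    """Build a RunConfig from a YAML file of (nested) keyword overrides."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs: dict[str, Any] = {}
    if "cohort" in raw:
        kwargs["cohort"] = CohortConfig(**raw.pop("cohort"))
    if "assay" in raw:
        kwargs["assay"] = AssayConfig(**raw.pop("assay"))
    if "thresholds" in raw and raw["thresholds"] is not None:
        kwargs["thresholds"] = ThresholdSet(**raw.pop("thresholds"))
    kwargs.update(raw)
    return RunConfig(**kwargs)
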