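"""Droplet calling and Poisson absolute quantification.

Turns raw two-channel droplet amplitudes into per-target positive/negative
tallies (nearest-centroid assignment against the 16-cluster composite grid),
converts positive fractions to mean molecules per droplet via the digital-PCR
Poisson correction lambda = -ln(1 - p), and reports copy numbers per genome
relative to the CNS-2p13.1 reference region assumed present at 2 copies:

    CN_t        = 2 * lambda_t / lambda_CNS
    ERBB2 CN    = 2 * (lambda_G + lambda_C) / lambda_CNS
    ERBB2/CEP17 = (lambda_G + lambda_C) / lambda_CEP17

The rs1058808 genotype is called from the allele balance: minor-allele
fraction < 0.05 is treated as homozygous, and amplified samples with an
imbalanced but non-homozygous allele ratio are flagged as monoallelic
amplification (cutoffs are package conventions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ddpcr_sim import TARGETS, AssayConfig, DropletSet, composite_centers

__all__ = [
    "TargetCounts",
    "QuantResult",
    "SampleCN",
    "SaturationError",
    "ReferenceSignalError",
    "call_droplets",
    "poisson_lambda",
    "copies_per_genome",
    "erbb2_metrics",
    "call_genotype",
    "quantify_well",
    "quantify_wells",
]

#: Wells with fewer analyzed droplets than this are flagged (not rejected).
QC_MIN_DROPLETS = 10000

#: Wells with any target positive fraction above this are rejected as
#: saturated (the Poisson correction becomes numerically unstable).
SATURATION_FRACTION = 0.99

GENOTYPE_MINOR_FRACTION = 0.05
MONOALLELIC_MINOR_FRACTION = 0.25
AMPLIFICATION_CN = 3.05


class SaturationError(ValueError):
    """Raised when a target is (nearly) all-positive; the sample needs dilution."""


class ReferenceSignalError(ValueError):
    """Raised when the CNS-2p13.1 reference shows no signal."""


@dataclass
class TargetCounts:
    """Positive-droplet tallies per target for one well."""

    well_id: str
    positives: dict[str, int]
    total_droplets: int
    qc_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.total_droplets <= 0:
            raise ValueError("total_droplets must be positive")
        for t, k in self.positives.items():
            if not 0 <= k <= self.total_droplets:
                raise ValueError(f"positives[{t}]={k} outside [0, total_droplets]")


@dataclass
class QuantResult:
    """Poisson-corrected concentrations and copy numbers for one well."""

    well_id: str
    lam: dict[str, float]
    lam_se: dict[str, float]
    copies_per_genome: dict[str, float]
    qc_flags: list[str] = field(default_factory=list)


@dataclass
class SampleCN:
    """Per-sample ERBB2 dosage metrics.

    ``erbb2_cn`` is total ERBB2 copies per genome (both alleles), ``ratio``
    the dual-probe ISH analogue ERBB2/CEP17.  ``ratio`` is NaN with a
    ``cep17_zero`` QC flag when CEP17 shows no signal.
    """

    sample_id: str
    erbb2_cn: float
    cep17_cn: float
    erbb2_cep17_ratio: float
    allele_g_cn: float
    allele_c_cn: float
    genotype: str
    monoallelic_amplification: bool = False
    qc_flags: list[str] = field(default_factory=list)


def call_droplets(
    droplets: DropletSet,
    gates: AssayConfig | dict[str, tuple[float, float]],
    negative_center: tuple[float, float] | None = None,
    qc_min_droplets: int = QC_MIN_DROPLETS,
) -> TargetCounts:
    """Assign each droplet to its nearest composite cluster and tally positives.

    ``gates`` is either an :class:`AssayConfig` (whose cluster geometry is
    used directly) or a map of single-positive centers, in which case
    ``negative_center`` must be given.  A droplet counts positive for every
    target implied by its assigned cluster's occupancy pattern, so the
    assignments partition the droplet set and per-target positives are
    consistent by construction.
    """
    if len(droplets) == 0:
        raise ValueError("empty droplet set")
    if isinstance(gates, AssayConfig):
        config = gates
    else:
        if negative_center is None:
            raise ValueError("negative_center is required with a raw gates map")
        config = AssayConfig(cluster_centers=dict(gates), negative_center=negative_center)

    patterns, centers = composite_centers(config)
    amp = droplets.amplitudes
    # chunked nearest-centroid to bound memory on large wells
    assign = np.empty(len(amp), dtype=np.intp)
    for start in range(0, len(amp), 200_000):
        block = amp[start : start + 200_000]
        d2 = ((block[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
        assign[start : start + len(block)] = d2.argmin(axis=1)

    pos_patterns = patterns[assign]
    positives = {t: int(pos_patterns[:, j].sum()) for j, t in enumerate(TARGETS)}
    flags = []
    if len(droplets) < qc_min_droplets:
        flags.append("low_droplet_count")
    return TargetCounts(
        well_id=droplets.well_id,
        positives=positives,
        total_droplets=len(droplets),
        qc_flags=flags,
    )


def poisson_lambda(positives: int, total: int) -> tuple[float, float]:
    """Poisson-corrected mean molecules per droplet and its delta-method SE.

    lambda = -ln(1 - p) with p = positives/total; SE = sqrt(p / (n (1 - p))).
    All-positive wells saturate the correction and raise
    :class:`SaturationError` (the remedy is sample dilution).
    """
    if total <= 0:
        raise ValueError("total droplet count must be positive")
    if not 0 <= positives <= total:
        raise ValueError("positives must lie in [0, total]")
    if positives == total:
        raise SaturationError(
            "all droplets positive: lambda is unbounded; dilute the sample"
        )
    p = positives / total
    lam = -math.log1p(-p)
    se = math.sqrt(p / (total * (1.0 - p)))
    return lam, se


def copies_per_genome(counts: TargetCounts) -> QuantResult:
    """Copy numbers per genome with the reference region fixed at 2 copies.

    cn_t = 2 * lambda_t / lambda_CNS for every target.  Rejects saturated
    wells (any positive fraction > 0.99) and wells with no reference signal.
    """
    for t, k in counts.positives.items():
        if k / counts.total_droplets > SATURATION_FRACTION:
            raise SaturationError(
                f"target {t} positive fraction exceeds {SATURATION_FRACTION}"
            )
    if counts.positives.get("CNS2p13", 0) == 0:
        raise ReferenceSignalError("no CNS-2p13.1 reference signal in well")

    lam, lam_se = {}, {}
    for t in TARGETS:
        lam[t], lam_se[t] = poisson_lambda(counts.positives[t], counts.total_droplets)
    cn = {t: 2.0 * lam[t] / lam["CNS2p13"] for t in TARGETS}
    return QuantResult(
        well_id=counts.well_id,
        lam=lam,
        lam_se=lam_se,
        copies_per_genome=cn,
        qc_flags=list(counts.qc_flags),
    )


def call_genotype(
    allele_g_cn: float,
    allele_c_cn: float,
    amplification_cn: float = AMPLIFICATION_CN,
) -> tuple[str, bool]:
    """rs1058808 genotype and monoallelic-amplification flag from allele CNs.

    Minor-allele fraction f = min/(g+c): f < 0.05 calls the major-allele
    homozygote, otherwise the heterozygote GC.  Amplified samples
    (total CN >= ``amplification_cn``) with f < 0.25 are additionally flagged
    as monoallelic amplification.  Both alleles absent -> ``undetermined``.
    """
    if allele_g_cn < 0 or allele_c_cn < 0:
        raise ValueError("allele copy numbers must be non-negative")
    total = allele_g_cn + allele_c_cn
    if total == 0:
        return "undetermined", False
    f = min(allele_g_cn, allele_c_cn) / total
    if f < GENOTYPE_MINOR_FRACTION:
        genotype = "GG" if allele_g_cn >= allele_c_cn else "CC"
    else:
        genotype = "GC"
    monoallelic = total >= amplification_cn and f < MONOALLELIC_MINOR_FRACTION
    return genotype, monoallelic


def erbb2_metrics(q: QuantResult, sample_id: str | None = None) -> SampleCN:
    """Collapse a per-well quantification into the sample-level ERBB2 metrics."""
    lam_erbb2 = q.lam["ERBB2_G"] + q.lam["ERBB2_C"]
    erbb2_cn = 2.0 * lam_erbb2 / q.lam["CNS2p13"]
    cep17_cn = q.copies_per_genome["CEP17"]
    flags = list(q.qc_flags)
    if q.lam["CEP17"] > 0:
        ratio = lam_erbb2 / q.lam["CEP17"]
    else:
        ratio = math.nan
        flags.append("cep17_zero")
    allele_g = q.copies_per_genome["ERBB2_G"]
    allele_c = q.copies_per_genome["ERBB2_C"]
    genotype, monoallelic = call_genotype(allele_g, allele_c)
    return SampleCN(
        sample_id=sample_id if sample_id is not None else q.well_id,
        erbb2_cn=erbb2_cn,
        cep17_cn=cep17_cn,
        erbb2_cep17_ratio=ratio,
        allele_g_cn=allele_g,
        allele_c_cn=allele_c,
        genotype=genotype,
        monoallelic_amplification=monoallelic,
        qc_flags=flags,
    )


def quantify_well(
    droplets: DropletSet,
    gates: AssayConfig | dict[str, tuple[float, float]],
    negative_center: tuple[float, float] | None = None,
    sample_id: str | None = None,
) -> SampleCN:
    """Call, Poisson-correct, and summarize one well in a single step."""
    counts = call_droplets(droplets, gates, negative_center=negative_center)
    return erbb2_metrics(copies_per_genome(counts), sample_id=sample_id)


def quantify_wells(wells, gates, negative_center=None):
    """Quantify a list of wells; returns a pandas DataFrame (one row per well)."""
    import pandas as pd

    rows = []
    for w in wells:
        s = quantify_well(w, gates, negative_center=negative_center)
        rows.append(
            {
                "sample_id": s.sample_id,
                "erbb2_cn": s.erbb2_cn,
                "cep17_cn": s.cep17_cn,
                "erbb2_cep17_ratio": s.erbb2_cep17_ratio,
                "allele_g_cn": s.allele_g_cn,
                "allele_c_cn": s.allele_c_cn,
                "genotype": s.genotype,
                "monoallelic_amplification": s.monoallelic_amplification,
                "qc_flags": ";".join(s.qc_flags),
            }
        )
    return pd.DataFrame(rows)
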