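"""Droplet-level simulator for a four-target, two-channel multiplex ddPCR assay.

The assay quantifies ERBB2 gene dosage in breast tumor DNA using a single
multiplex reaction that measures four targets: the two alleles of an ERBB2
coding SNP (``ERBB2_G``, ``ERBB2_C``), the chromosome 17 centromere
(``CEP17``), and a copy-number-stable autosomal reference region on 2p13.1
(``CNS2p13``, assumed present at 2 copies per genome).  Input DNA is
partitioned into ~20,000 nanoliter droplets; each target's molecules land in
droplets independently (Poisson), droplets are PCR-amplified to endpoint, and
a two-channel fluorescence readout places each droplet in one of up to
2^4 = 16 clusters according to which targets it contains.

This module generates synthetic droplet amplitude data with known
ground-truth copy numbers so that the downstream calling and quantification
chain can be validated end to end.  Cluster geometry is a package convention:
no public amplitude-unit calibration exists for the assay, so the default
layout simply provides four well-separated single-positive clusters on an
amplitude-multiplexed two-channel plane (high/mid positions per channel).

Droplet fluorescence is modeled as an additive superposition: each target
present in a droplet (>= 1 molecule; probe signal saturates in molecule
count) adds its characteristic per-channel contribution above the
double-negative baseline, producing the full 16-cluster combination grid
observed on real multiplex amplitude plots.  Gaussian amplitude noise and an
optional "rain" process (partial-amplification droplets displaced toward the
negative cluster) complete the model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TARGETS",
    "AssayConfig",
    "SampleTruth",
    "DropletSet",
    "AssayConfigError",
    "expected_lambda",
    "simulate_droplets",
    "simulate_replicate_wells",
    "builtin_control_profiles",
    "control_profile",
    "composite_centers",
    "write_droplet_csv",
    "read_droplet_csv",
]

#: Target order used for every per-target array in the package.
TARGETS: tuple[str, ...] = ("ERBB2_G", "ERBB2_C", "CEP17", "CNS2p13")

#: Default single-positive cluster centers (ch1, ch2), arbitrary fluorescence
#: units.  ERBB2_G high / CEP17 mid on channel 1; ERBB2_C high / CNS2p13 mid
#: on channel 2.  Negative droplets sit near the origin.
DEFAULT_CLUSTER_CENTERS: dict[str, tuple[float, float]] = {
    "ERBB2_G": (6000.0, 500.0),
    "ERBB2_C": (500.0, 6000.0),
    "CEP17": (3000.0, 500.0),
    "CNS2p13": (500.0, 3000.0),
}

DEFAULT_NEGATIVE_CENTER: tuple[float, float] = (500.0, 500.0)


class AssayConfigError(ValueError):
    """Raised when an :class:`AssayConfig` fails validation."""


@dataclass(frozen=True)
class AssayConfig:
    """Physical and readout parameters of one multiplex ddPCR reaction.

    Defaults reproduce the published assay scale: 10 ng input DNA in a 20 ul
    reaction, a mean of 19738 analyzed droplets per well (SD 3491), and a
    3.3 pg haploid genome mass.  ``droplet_volume_nl`` is carried for
    concentration reporting only; copy-number ratios cancel it.
    """

    n_droplets_mean: float = 19738.0
    n_droplets_sd: float = 3491.0
    n_droplets_min: int = 5000
    droplet_volume_nl: float = 0.85
    dna_mass_ng: float = 10.0
    pg_per_haploid_genome: float = 3.3
    cluster_centers: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLUSTER_CENTERS)
    )
    negative_center: tuple[float, float] = DEFAULT_NEGATIVE_CENTER
    amplitude_sd: float = 150.0
    rain_fraction: float = 0.002

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_droplets_mean <= 0:
            raise AssayConfigError("n_droplets_mean must be positive")
        if self.n_droplets_sd < 0:
            raise AssayConfigError("n_droplets_sd must be non-negative")
        if self.dna_mass_ng <= 0:
            raise AssayConfigError("dna_mass_ng must be positive")
        if self.pg_per_haploid_genome <= 0:
            raise AssayConfigError("pg_per_haploid_genome must be positive")
        if not 0.0 <= self.rain_fraction < 0.5:
            raise AssayConfigError("rain_fraction must lie in [0, 0.5)")
        if self.amplitude_sd < 0:
            raise AssayConfigError("amplitude_sd must be non-negative")
        missing = set(TARGETS) - set(self.cluster_centers)
        if missing:
            raise AssayConfigError(f"cluster_centers missing targets: {sorted(missing)}")
        neg = np.asarray(self.negative_center, dtype=float)
        for t in TARGETS:
            c = np.asarray(self.cluster_centers[t], dtype=float)
            if np.allclose(c, neg):
                raise AssayConfigError(
                    f"cluster center for {t} coincides with the negative center"
                )
        # every occupancy pattern must map to a distinct composite center,
        # otherwise droplet calling cannot be exact even without noise
        centers = composite_centers(self)[1]
        d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() <= 0:
            raise AssayConfigError("composite cluster centers are not distinct")

    def with_(self, **kwargs) -> "AssayConfig":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SampleTruth:
    """Ground-truth copy numbers (copies per genome) for one sample.

    Copy numbers are expressed relative to the CNS-2p13.1 reference region
    fixed at its biological value of 2 copies per genome, i.e. on the same
    scale the quantification chain reports (CN = 2 * target / reference).
    """

    cn_erbb2_g: float
    cn_erbb2_c: float
    cn_cep17: float
    cn_cns: float = 2.0
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("cn_erbb2_g", "cn_erbb2_c", "cn_cep17", "cn_cns"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.cn_cns <= 0:
            raise ValueError("cn_cns must be positive (reference region)")

    @property
    def cn_erbb2(self) -> float:
        return self.cn_erbb2_g + self.cn_erbb2_c

    def copy_numbers(self) -> dict[str, float]:
        return {
            "ERBB2_G": self.cn_erbb2_g,
            "ERBB2_C": self.cn_erbb2_c,
            "CEP17": self.cn_cep17,
            "CNS2p13": self.cn_cns,
        }


@dataclass
class DropletSet:
    """Per-droplet two-channel amplitudes for one reaction well.

    ``truth_occupancy`` (droplets x targets, molecule counts) is retained by
    the simulator so oracle tests can compare called positives against the
    exact per-droplet ground truth.
    """

    well_id: str
    amplitudes: np.ndarray  # shape (n, 2)
    truth_occupancy: np.ndarray | None = None  # shape (n, 4) int

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.ndim != 2 or self.amplitudes.shape[1] != 2:
            raise ValueError("amplitudes must have shape (n_droplets, 2)")
        if len(self.amplitudes) < 1:
            raise ValueError("a DropletSet needs at least one droplet")
        if self.truth_occupancy is not None:
            self.truth_occupancy = np.asarray(self.truth_occupancy)
            if len(self.truth_occupancy) != len(self.amplitudes):
                raise ValueError("truth_occupancy length must match amplitudes")

    def __len__(self) -> int:
        return len(self.amplitudes)


def composite_centers(config: AssayConfig) -> tuple[np.ndarray, np.ndarray]:
    """Enumerate all 16 occupancy patterns and their composite cluster centers.

    Returns ``(patterns, centers)`` where ``patterns`` is a (16, 4) boolean
    array over :data:`TARGETS` and ``centers`` is the (16, 2) array of
    expected amplitudes: negative baseline plus the sum of per-target
    contributions for the targets present.
    """
    neg = np.asarray(config.negative_center, dtype=float)
    contrib = np.array(
        [np.asarray(config.cluster_centers[t], dtype=float) - neg for t in TARGETS]
    )
    patterns = np.array(list(itertools.product([False, True], repeat=len(TARGETS))))
    centers = neg + patterns.astype(float) @ contrib
    return patterns, centers


def expected_lambda(truth: SampleTruth, config: AssayConfig) -> dict[str, float]:
    """Mean molecules per droplet for each target at the configured loading.

    lambda_t = cn_t * n_genomes / n_droplets, with the number of haploid
    genome equivalents given by the input DNA mass divided by the per-genome
    mass (10 ng / 3.3 pg ~ 3030 genomes by default) and the droplet count
    taken at its configured mean.  Deterministic.
    """
    genomes = config.dna_mass_ng * 1000.0 / config.pg_per_haploid_genome
    per_copy = genomes / config.n_droplets_mean
    return {t: cn * per_copy for t, cn in truth.copy_numbers().items()}


def _draw_droplet_count(rng: np.random.Generator, config: AssayConfig) -> int:
    n = int(round(rng.normal(config.n_droplets_mean, config.n_droplets_sd)))
    return max(config.n_droplets_min, n)


def simulate_droplets(
    truth: SampleTruth,
    config: AssayConfig | None = None,
    seed: int | np.random.SeedSequence | None = 0,
    well_id: str = "well",
) -> DropletSet:
    """Simulate one reaction well of multiplex droplet amplitudes.

    The analyzed droplet count is drawn around its configured mean (truncated
    normal).  Each analyzed droplet receives independent Poisson molecule
    counts per target with mean :func:`expected_lambda` -- the occupancy rate
    is set by DNA concentration and the nominal partition count, so wells
    where fewer droplets survive analysis lose precision but keep the same
    per-droplet occupancy.  Amplitudes follow the additive superposition
    model plus Gaussian noise.  A ``rain_fraction`` of positive droplets is
    displaced toward the negative cluster by a uniform (0.2, 0.8) factor.
    All randomness flows from ``seed``.
    """
    config = config or AssayConfig()
    rng = np.random.default_rng(seed)
    n = _draw_droplet_count(rng, config)

    lam = np.array([expected_lambda(truth, config)[t] for t in TARGETS])
    occupancy = rng.poisson(lam, size=(n, len(TARGETS)))

    neg = np.asarray(config.negative_center, dtype=float)
    contrib = np.array(
        [np.asarray(config.cluster_centers[t], dtype=float) - neg for t in TARGETS]
    )
    present = occupancy > 0
    amplitudes = neg + present.astype(float) @ contrib
    if config.amplitude_sd > 0:
        amplitudes = amplitudes + rng.normal(0.0, config.amplitude_sd, size=(n, 2))

    if config.rain_fraction > 0:
        positive = present.any(axis=1)
        rained = positive & (rng.random(n) < config.rain_fraction)
        k = int(rained.sum())
        if k:
            f = rng.uniform(0.2, 0.8, size=k)[:, None]
            amplitudes[rained] = neg + f * (amplitudes[rained] - neg)

    return DropletSet(well_id=well_id, amplitudes=amplitudes, truth_occupancy=occupancy)


def simulate_replicate_wells(
    truth: SampleTruth,
    n_wells: int,
    config: AssayConfig | None = None,
    seed: int = 0,
    well_prefix: str = "well",
) -> list[DropletSet]:
    """Simulate ``n_wells`` independent replicate wells of the same sample.

    Per-well seeds are spawned from one root seed so replicates are
    independent but the whole set is reproducible.
    """
    children = np.random.SeedSequence(seed).spawn(n_wells)
    return [
        simulate_droplets(truth, config, seed=child, well_id=f"{well_prefix}_{i:02d}")
        for i, child in enumerate(children)
    ]


def builtin_control_profiles() -> dict[str, SampleTruth]:
    """Ground-truth profiles for the assay's run controls.

    * ``NS12911`` -- Coriell normal human genomic DNA; near-diploid at every
      target (published replicate means: ERBB2 2.08, CEP17 1.89).  Modeled as
      an rs1058808 heterozygote so both ERBB2 allele clusters appear.
    * ``SKBR3`` -- SK-BR-3 ERBB2-amplified breast cancer cell line with CEP17
      gain (published replicate means: ERBB2 CN 19.83, CEP17 CN 3.03,
      ERBB2/CEP17 ratio 6.55).  ERBB2 amplification is monoallelic, so the
      amplified dose is placed on the G allele with one retained C copy.
    """
    return {
        "NS12911": SampleTruth(
            cn_erbb2_g=1.04, cn_erbb2_c=1.04, cn_cep17=1.89, cn_cns=2.0,
            label="NS12911",
        ),
        "SKBR3": SampleTruth(
            cn_erbb2_g=18.83, cn_erbb2_c=1.00, cn_cep17=3.03, cn_cns=2.0,
            label="SKBR3",
        ),
    }


def control_profile(name: str) -> SampleTruth:
    """Look up a built-in control profile by name (KeyError if unknown)."""
    profiles = builtin_control_profiles()
    if name not in profiles:
        raise KeyError(
            f"unknown control profile {name!r}; available: {sorted(profiles)}"
        )
    return profiles[name]


def write_droplet_csv(droplets: DropletSet, path) -> None:
    """Write a droplet table as CSV (well_id, ch1, ch2 [, truth_<target>...])."""
    import pandas as pd

    data = {
        "well_id": np.repeat(droplets.well_id, len(droplets)),
        "ch1": droplets.amplitudes[:, 0],
        "ch2": droplets.amplitudes[:, 1],
    }
    if droplets.truth_occupancy is not None:
        for j, t in enumerate(TARGETS):
            data[f"truth_{t}"] = droplets.truth_occupancy[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def read_droplet_csv(path) -> list[DropletSet]:
    """Read a droplet CSV (possibly multiple wells) back into DropletSets."""
    import pandas as pd

    df = pd.read_csv(path)
    truth_cols = [f"truth_{t}" for t in TARGETS]
    has_truth = all(c in df.columns for c in truth_cols)
    out = []
    for well_id, sub in df.groupby("well_id", sort=False):
        occ = sub[truth_cols].to_numpy() if has_truth else None
        out.append(
            DropletSet(
                well_id=str(well_id),
                amplitudes=sub[["ch1", "ch2"]].to_numpy(),
                truth_occupancy=occ,
            )
        )
    return out
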