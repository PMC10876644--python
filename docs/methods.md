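# Methods

This note documents the models behind `ddherd`, the conventions adopted
where the underlying assay and cohort publications leave details open, and
what the synthetic-data layer does and does not establish.

## The assay model

The simulated assay is a single-reaction multiplex ddPCR measuring four
targets: the two alleles of an ERBB2 coding SNP (rs1058808; `ERBB2_G`,
`ERBB2_C`), the chromosome 17 centromere (`CEP17`), and a copy-number-stable
autosomal region on 2p13.1 (`CNS2p13`) assumed to be present at 2 copies per
genome in any cell.

**Partitioning.** A reaction loads `dna_mass_ng` (default 10 ng) of genomic
DNA, i.e. `dna_mass / 3.3 pg` ≈ 3030 haploid genome equivalents, into
droplets.  Molecules of each target land in droplets independently, so the
per-droplet molecule count for target *t* is Poisson with mean

    lambda_t = cn_t x n_genomes / n_droplets ,

with `n_droplets` taken at its nominal mean (19 738; per-well analyzed
counts are drawn from N(19 738, 3491) truncated at 5000, reflecting
read/QC losses that change precision but not per-droplet occupancy).
Droplet volume (0.85 nl) is carried only for completeness; every copy-number
quantity in the package is a ratio of lambdas, in which volume cancels.

**Readout geometry.** No amplitude-unit calibration for the assay is public,
so cluster coordinates are a package convention: on a two-channel plane, the
single-positive clusters sit at high/mid positions per channel (`ERBB2_G`
(6000, 500), `CEP17` (3000, 500) on channel 1; `ERBB2_C` (500, 6000),
`CNS2p13` (500, 3000) on channel 2; negatives at (500, 500)).  A droplet
containing several targets fluoresces at the negative baseline plus the
*sum* of the per-target contributions (presence-based: additional molecules
of the same target do not add signal).  Additivity makes all 2^4 = 16
occupancy patterns land on distinct composite centers — the combination grid
seen on real multiplex amplitude plots — which is what makes nearest-centroid
calling exact in the noise-free limit.  A per-channel maximum (full
saturation) rule was considered and rejected: it collapses e.g. {ERBB2_G}
and {ERBB2_G, CEP17} onto one center, making the mid-amplitude targets
unidentifiable exactly in the regime (strong amplification) the assay is
for.

**Noise and rain.** Gaussian amplitude noise (SD 150 units, ~6% of the
minimum inter-cluster distance of 2500) keeps clusters cleanly separable, as
described for the real assay.  "Rain" — partially amplified droplets falling
between clusters — is modeled by displacing a small fraction of positive
droplets toward the negative baseline by a uniform (0.2, 0.8) factor.  The
default rain fraction is 0.002: the uniform-to-origin geometry is a
worst case (most displaced droplets are miscalled), so a low rate is what
matches an assay with reportedly distinct clusters.  Rain is the one defect
mode that biases quantification (it deflates the highest-occupancy target's
lambda); at the default rate the bias on the amplified control is below 1%.

**Controls.**  Two ground-truth profiles ship with the simulator, with
copy numbers expressed relative to the reference region fixed at 2 (the
scale the quantification reports): `NS12911`, near-diploid normal DNA
(ERBB2 2.08, CEP17 1.89, modeled heterozygous at rs1058808), and `SKBR3`,
the ERBB2-amplified cell line (ERBB2 19.83 with monoallelic amplification,
CEP17 3.03, ratio 6.55).  The published raw copies-per-genome of the normal
control (reference measured at 1.98 rather than 2.00) reflect
DNA-concentration measurement error in reaction loading, which cancels in
copy-number ratios and is therefore not part of the profile truth.

## Quantification

Calling is nearest-centroid against the 16 composite centers, with supplied
gates (the simulator's true geometry) as the default; per-well re-estimation
of gates is deliberately out of scope since the original analysis used
instrument-software gating whose parameters are unpublished.  Counts are
Poisson-corrected per target, `lambda = -ln(1 - p)`, with delta-method
standard error `sqrt(p / (n (1-p)))`.  Copy numbers:

    CN_t        = 2 lambda_t / lambda_CNS
    ERBB2 CN    = 2 (lambda_G + lambda_C) / lambda_CNS
    ERBB2/CEP17 = (lambda_G + lambda_C) / lambda_CEP17

ERBB2 alleles are summed on the lambda scale before normalization
(equivalent to CN addition; stated for determinism).  Guards: wells under
10 000 droplets are flagged (not rejected); any target above 99% positive
raises a saturation error whose remedy is dilution; a silent reference
channel is a hard error.  Genotype: minor-allele fraction f = min/(g+c);
f < 0.05 calls a homozygote, otherwise GC; amplified samples
(CN >= 3.05) with f < 0.25 are flagged as monoallelic amplification.  The
two cutoffs are package conventions — the source analyses report only that
amplification is monoallelic, not a numeric rule.

## Classification

Thresholds are fitted on a training cohort by ROC analysis against ISH
labels: candidate thresholds at midpoints of consecutive sorted unique
scores (plus infinite sentinels), positivity at score >= threshold, AUC by
trapezoid (exactly the Mann-Whitney statistic under this sweep), optimum at
maximal Youden J with ties broken toward the smaller threshold.  The
published operating points, CN >= 3.05 and ratio >= 1.55, are the package
defaults.  The four diagnostic groups partition the (CN, ratio) plane with
inclusive boundaries; no equivocal group exists.  The "combination"
criterion is the logical OR of the CN and ratio criteria — the published
description ("a metric combining" the two) does not pin the rule down, but
OR reproduces the reported direction of the sensitivity gain and equals
membership in groups 1–3.

Predictive values against ISH follow the published contingency-table
convention exactly: PPV numerators count ISH-amplified cases only, NPV
numerators count all non-ISH-amplified cases (normal *or* missing), and
ISH-missing cases stay in every denominator.  The packaged
`table3_counts.json` ships the published aggregate counts (four groups x
{three IHC rows, three ISH rows}; no patient-level data).

## Cohort simulator

The generator reproduces the structure the downstream statistics assume,
with these defaults:

| parameter | default | basis |
|---|---|---|
| cohort size | 909 | published cohort |
| IHC mix 0-1+/2+/3+ | 437/236/236 of 909 | published Table 1 marginals |
| ERBB2 CN, 0-1+ | gamma, mean 2.00, SD 0.39 | published group moments |
| ERBB2 CN, 2+ | gamma, mean 2.58, SD 1.99 | published group moments |
| ERBB2 CN, 3+ | log-normal, mean 12.0, SD 9.11 | published group moments |
| CEP17 gain (CN > 3) | 6.7% | published prevalence |
| ISH truth rule | CN >= 4.0 | gives ~29% ISH-amplified marginal |
| ISH discordance | 2% each direction | ~6 discordant group-1 cases of 909 |
| ISH missing | 18% | published marginal |
| trastuzumab uptake | 177/264 of clinically positive | published subcohort |
| ultrahigh rule | true CN > 19.7 | published survival cutpoint |
| RFS / OS hazard (classic) | 0.04 / 0.03 per year | see below |
| ultrahigh hazard ratio | 3.3 (RFS), 3.6 (OS) | published Cox estimates |
| censoring | uniform on (0, 14) years | see below |

Families are package conventions: only means/SDs are published per group.
The non-amplified groups use a moment-matched gamma (positive support and
*exact* configured moments; a zero-truncated normal would inflate the
skewed 2+ group's mean by ~0.4 copies).  The amplified group uses a
moment-matched log-normal, whose upper tail incidentally yields
P(CN > 19.7) ~ 0.14 among amplified cases — consistent with the 13.6%
ultrahigh fraction observed in the trastuzumab subcohort without any
additional tuning.  Survival is exponential with independent uniform
censoring; baseline hazards and the 14-year censoring horizon were chosen so
a default run shows a ~5.3–5.4-year median observed follow-up and a
realistic event count (~25%/~47% events in classic/ultrahigh over follow-up)
for an adjuvant HER2-positive cohort accrued over ~13 years.  Ki67 is forced
high in ultrahigh cases (as observed); all other covariates are independent
draws matching published marginals, which is a deliberate simplification.

`simulate_trastuzumab_cohort` draws the treated subcohort directly
(Bernoulli 13.6% ultrahigh, CN from the amplified log-normal truncated on
the matching side of 19.7) and is the generator for hazard-ratio
parameter-recovery studies.  `simulate_expression_cohort` emulates the
RNA-seq surrogate cohort: a latent log2-expression signal, additive
per-protocol offsets (dUTP/TruSeq/NeoPrep), multiplicative observation on
the TPM scale, and survival tied to the top-fraction latent group.

**What passing tests show — and don't.**  The simulator establishes that the
pipeline's statistics are unbiased and correctly calibrated *under the
generating model*: independent Poisson partitioning, Gaussian clusters,
exponential hazards, independent censoring, covariate independence.  Real
tumors violate several of these (intratumoral heterogeneity and stromal
dilution compress CN toward 2; ISH discordance is not symmetric noise;
hazards are not constant in time — the published survival curves separate
only after 2–3 years, which an exponential model cannot express).  Recovery
of the published per-group accuracies from real data is therefore out of
reach by construction, and the package instead demonstrates arithmetic
fidelity on the published aggregate counts plus parameter recovery at the
published effect sizes.

## Survival analysis

Kaplan-Meier, log-rank, and Cox proportional hazards are provided through
lifelines (Efron tie handling — no tie convention is published, and at the
synthetic cohorts' continuous times the Efron/Breslow difference is
negligible; Wald 95% CIs; two-tailed tests at alpha 0.05).  Multivariable
covariate selection keeps variables with univariable p < 0.1 on either
endpoint.

The maximally selected cutpoint ("ultrahigh" definition) is implemented in
the package: over candidate splits at midpoints of sorted unique marker
values, with both sides holding at least `minprop` (default 0.1) of the
subjects, it maximizes |O - E| / sqrt(V) of the two-sample log-rank
statistic; ties break toward the smaller cutpoint, and no selection-bias
correction of the resulting p-value is applied (matching the original
analysis, which reports none).  The default endpoint for cutpoint search is
RFS (the original report does not say which endpoint was used; this is
configurable).  Exhaustive per-split log-rank computation with an
independent library serves as the test oracle.

The top-fraction expression classifier labels the highest
`ceil(fraction x n)` values positive (minimum one), includes all boundary
ties, and reports the achieved fraction.  Protocol normalization is
`log2(x + 0.1)` (offset keeps zeros finite) followed by per-protocol mean
centering to the reference protocol's (dUTP) mean.

## Pipeline and reproducibility

`run_full` chains cohort simulation, per-sample droplet measurement,
ROC/Youden threshold fitting on a seeded 70/30 split (909 -> 636/273),
four-group classification, and the trastuzumab survival analysis; all
randomness descends from one root seed via `numpy.random.SeedSequence`
spawning, and the report embeds the seed and a configuration hash, making
reports bit-reproducible.  Droplet wells saturated by extreme amplification
are automatically re-run at 4x serial dilutions, the laboratory remedy.
Numerical conventions worth knowing: the training-split size is
`round(fraction x n)`; group assignment uses inclusive thresholds; Poisson
correction refuses all-positive wells rather than clamping.

## Problem sizes used in the shipped analyses

The acceptance analysis averages the recovered ERBB2 CN of the amplified
control over 9-well replicate sets at 50 seeds (450 wells of ~20 000
droplets), and estimates the ultrahigh hazard ratio as the geometric mean
over 200 seeded trastuzumab cohorts of n = 177 — the geometric mean is the
natural average for hazard ratios, whose sampling distribution is
log-symmetric.  These sizes give Monte-Carlo error comfortably inside the
tolerances being checked while keeping a full run in tens of seconds.

## Known limitations

- No EM/probabilistic droplet deconvolution; calling is hard-assignment
  nearest-centroid with known gates.
- No thermocycling chemistry, droplet-volume variation, or instrument file
  formats.
- The expression cohort is an additive-batch toy for one gene, not a model
  of real RNA-seq distributions.
- Exponential survival cannot reproduce delayed curve separation; competing
  risks and landmark analyses are out of scope.
- Proportional-hazards diagnostics (Schoenfeld residuals) are not included.
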