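# ddherd

**Multiplex ddPCR simulation, ERBB2 copy-number quantification, HER2 group
classification, and trastuzumab survival analysis.**

`ddherd` is a research toolkit for the statistics behind droplet digital
PCR (ddPCR) determination of HER2/ERBB2 status in breast cancer.  It is
aimed at assay developers and biostatisticians who want a tested, seedable
implementation of the full analysis chain — from droplet-level fluorescence
data with known ground truth, through Poisson absolute quantification and
diagnostic threshold derivation, to survival dichotomization — without
access to patient-level data.

## The model

In ddPCR, input DNA is partitioned into ~20 000 nanoliter droplets, each
amplified to endpoint; a target's concentration follows from the fraction
*p* of positive droplets via the Poisson correction

&nbsp;&nbsp;&nbsp;&nbsp;λ = −ln(1 − p),&nbsp;&nbsp; SE(λ) = √( p / (n(1−p)) ).

The simulated assay multiplexes four targets in two fluorescence channels —
both alleles of the ERBB2 SNP rs1058808, the chromosome 17 centromere
(CEP17), and a copy-number-stable reference on 2p13.1 (CNS, assumed 2
copies/genome) — giving the 16-cluster combination grid characteristic of
amplitude-multiplexed ddPCR.  Copy numbers are referenced to CNS:

&nbsp;&nbsp;&nbsp;&nbsp;ERBB2 CN = 2 (λ_G + λ_C) / λ_CNS,&nbsp;&nbsp;
ERBB2/CEP17 = (λ_G + λ_C) / λ_CEP17.

HER2 classification thresholds are fitted by ROC analysis with the maximum
Youden index J = sensitivity + specificity − 1 (defaults CN ≥ 3.05,
ratio ≥ 1.55), and samples fall into the four dual-probe diagnostic groups:
1 (classic amplified: both above), 2 (monosomy pattern: ratio only),
3 (CEP17 co-amplification: CN only), 5 (classic non-amplified: neither).
An "ultrahigh" ERBB2 group (CN above a maximally selected log-rank
cutpoint, default 19.7) carries an elevated hazard under adjuvant
trastuzumab, quantified by Kaplan–Meier/log-rank and Cox proportional
hazards.  A synthetic cohort generator provides patient-level data with
this exact structure, and the published four-group contingency counts for
909 tumors ship as a package fixture.

See `docs/methods.md` for the full model description and the conventions
adopted where the underlying publications leave details open.

## Worked example

Quantify nine simulated replicate wells of the built-in ERBB2-amplified
SK-BR-3 control:

```python
from ddherd import AssayConfig, control_profile, simulate_replicate_wells, quantify_wells

config = AssayConfig()                      # 10 ng input, ~19738 droplets/well
truth = control_profile("SKBR3")            # ERBB2 19.83, CEP17 3.03
wells = simulate_replicate_wells(truth, 9, config, seed=1)
df = quantify_wells(wells, config)
print(df[["erbb2_cn", "cep17_cn", "erbb2_cep17_ratio"]].mean().round(2))
```

```
erbb2_cn             19.60
cep17_cn              3.04
erbb2_cep17_ratio     6.44
```

The mean recovered ERBB2 CN (19.60) and ERBB2/CEP17 ratio (6.44) sit within
two replicate SDs of the ground truth (19.83 and 6.55); the ~1% deficit is
the cost of the simulated "rain" droplets, quantified in the methods note.

Run the whole pipeline on a synthetic 909-patient cohort — simulate, measure
every sample at droplet level, fit thresholds on a 70/30 training split,
classify, and analyze survival in the trastuzumab subcohort:

```python
from ddherd import RunConfig, run_full

report = run_full(RunConfig(seed=1))
print(report["stages"]["survival"]["cutpoint"])          # 19.74
print(report["stages"]["survival"]["rfs"]["hazard_ratio"])  # 3.79
```

With the default generator (ultrahigh effect at true CN > 19.7, hazard
ratio 3.3) the maximally selected cutpoint search lands at 19.74 and the
Cox fit on the called ultrahigh group gives HR 3.79 (95% CI 1.97–7.27) —
parameter recovery through the entire measurement chain.

The same functionality is exposed on the command line:

```bash
ddherd simulate-droplets --profile SKBR3 --wells 9 --seed 1 --out wells.csv
ddherd quantify --droplets wells.csv --out cn.tsv
ddherd simulate-cohort --n 909 --seed 5 --out cohort.tsv
ddherd survival --clinical cohort.tsv --value-column true_cn_erbb2 --cutpoint auto --out surv.json
ddherd run --out report.json
ddherd fixtures table3 --out table3.tsv
```

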