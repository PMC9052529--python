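# cordmeth

Cord-blood DNA methylation analysis for preterm-infant cohorts.

Bronchopulmonary dysplasia (BPD) is the chronic lung disease of
prematurity; its strongest risk factors are low gestational age (GA) and
low birth weight. Epigenome-wide association studies (EWAS) in preterm
cord blood are complicated by the highly dynamic fetal hematopoietic
system — in particular by nucleated red blood cells (NRBCs), whose
genome-wide hypomethylation can dominate bulk methylation profiles and
confound every downstream statistic. `cordmeth` packages the full
analysis chain such a study needs, together with a synthetic cohort
generator that carries ground truth for every stage, so that each
statistical component can be validated end to end:

* **preprocessing** — probe QC (sex chromosomes, SNP-overlapping and
  cross-reactive probes), failed-array removal, beta ↔ M transforms
  (M = log₂ β/(1−β)), per-CpG winsorization, and parametric
  empirical-Bayes batch adjustment (location/scale model, verified
  against R's `sva::ComBat`);
* **deconvolution** — seven-cell-type composition (CD8T, CD4T, B, NK,
  monocytes, granulocytes, NRBC) by non-negative projection onto
  reference methylation profiles: per sample, solve
  min‖y − Rw‖² s.t. w ≥ 0 over the discriminating-CpG basis;
* **ewas** — per-CpG Huber robust regression (c = 1.345, MAD scale) of
  M-values on phenotype with covariate adjustment (sex, GA, birth weight,
  smoking, ancestry, hospital, percentile-transformed oxygen days, seven
  cell fractions), Bonferroni/Benjamini-Hochberg control, group
  methylation summaries (dMeth, %), and hypergeometric CpG-set overlap
  tests;
* **sem** — stochastic epigenetic mutations: a value beyond
  Q3 + 3·IQR or Q1 − 3·IQR of a CpG's cross-sample distribution;
  per-sample epimutation load EML = ln(SEM count), recurrence catalogs,
  biweight midcorrelation, and covariate-adjusted EML associations;
* **ega** — linear methylation clocks (EGA = intercept + Σ coefᵢ·βᵢ),
  epigenetic gestational age acceleration (residual of EGA on GA), and
  its phenotype association;
* **synthetic** — cohorts emulating a 107-infant (14 BPD / 93 non-BPD)
  very-low-birth-weight design: GA uniform on 24–35 weeks, birth weight
  with population r² = 0.38 to GA, NRBC fractions moment-calibrated to
  mean 29.9% / SD 24.1% and negatively coupled to birth weight
  (r² = 0.16), genome-wide NRBC hypomethylation, a smoking-biomarker
  CpG, injected disease effects, injected epimutations, and plate batch
  effects.

## Worked example

```sh
cordmeth run --seed 7 --out demo
```

generates a default synthetic cohort (20,000 CpGs × 107 samples), runs
QC → ComBat → deconvolution → EWAS → SEM → EGA, and prints:

```
EWAS: {'n_bonferroni': 47, 'n_fdr_0.01': 51, 'n_fdr_0.05': 53, 'n_nrbc_associated': 4443}
```

i.e. of the 50 injected disease-associated CpGs (5-percentage-point beta
differences), 47 reach genome-wide (Bonferroni) significance and 53 CpGs
pass FDR 5%; 4,443 CpGs associate with the estimated NRBC fraction,
reflecting the generator's genome-wide NRBC hypomethylation. The
`demo/summary.json` it writes also reports, among others:

```
"ega":  corr_ega_ga = 0.999          # clock recovers GA on its own cohort
"sem":  count_min = 157, count_max = 320, eml_adjusted_p = 0.52
```

SEM counts cluster around the injected rate of 200 per sample, and the
covariate-adjusted EML-vs-BPD association is null here because the
default generator injects no group difference in epimutation rate
(`sem_bpd_rate_ratio: 2.0` in a cohort YAML switches one on).

The same stages are available as library functions
(`cordmeth.run_ewas`, `cordmeth.detect_sems`, …) and as individual CLI
subcommands (`cordmeth simulate/preprocess/deconvolve/ewas/sem/ega`)
operating on TSV/CSV interchange files. Annotation coordinates are
1-based inclusive.

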