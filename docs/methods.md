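# Methods

This note documents the statistical models `cordmeth` implements, the
design of its synthetic cohort generator, and the numerical choices that
affect results.

## Scope and data model

The pipeline starts from beta values (methylated proportion per CpG per
sample, in [0, 1]); raw intensity (IDAT) processing, background
correction and dye-bias normalization are out of scope. Matrices are
CpG-by-sample; per-sample covariates travel in a sample sheet with
columns `bpd_status, ga_weeks, birth_weight_g, sex, smoking, ancestry,
hospital, o2_days, batch`. Regressions run on the M scale,
M = log₂(β′/(1−β′)) with β′ clipped to [ε, 1−ε]; ε defaults to 1e-3
(configurable) so that boundary betas stay finite without materially
compressing the scale.

Quantiles everywhere use linear interpolation between order statistics
(numpy default, R type 7). This matters: both the winsorization bounds
and the epimutation fences are quantile-derived, and alternative
quantile rules change counts. Winsorization is exactly idempotent only
when the requested quantile lands on an order statistic; in general a
second pass can move values slightly, which is inherent to
interpolated quantiles rather than an implementation artifact.

## QC filtering

Samples with more than 5% failed probes (per the failure mask) are
dropped; surviving failed entries are imputed with the CpG's row median
so the matrix stays dense for deconvolution and batch adjustment
(dropping or NA-propagation would disqualify whole probes). Probes are
removed if on chrX/chrY, SNP-flagged, or cross-reactive-flagged, with a
fixed counting precedence (chrom > snp > crossreactive) so a
multiply-flagged probe is counted once. The cross-reactive list is an
input mask; the package does not bundle one.

## Batch adjustment

`combat_adjust` implements the parametric empirical-Bayes location/scale
model: per probe, a linear fit with batch indicators plus protected
covariates; standardization by the pooled residual SD; per-batch
location (normal prior) and scale (inverse-gamma prior) shrunk by the
standard moment-matched fixed-point iteration; back-transform. The
implementation agrees with R's `sva::ComBat` to machine precision on
shared inputs (tested). Only the parametric prior is provided. A single
batch is a no-op. Covariates passed to the adjustment (disease status
and GA in the pipeline) are protected, i.e. their fitted effects are
excluded from what the adjustment removes.

Batch adjustment is not cosmetic here: the generator's per-batch scale
jitter makes per-sample noise variances heterogeneous, and the classical
robust-regression covariance (below) assumes homoscedastic errors.
Empirically, skipping ComBat deflates the null EWAS (λ ≈ 0.82 under
permuted labels) while running it restores λ ≈ 1.0; the pipeline
therefore always adjusts before the scan when more than one batch is
present.

## Cell-type deconvolution

Composition is estimated per sample by non-negative least squares
(active-set NNLS) of the sample's betas at the discriminating CpGs on
the reference profile matrix — constrained projection with no
sum-to-one constraint, so row sums can mildly exceed 1; an optional
renormalization is display-only. Discriminating CpGs are chosen per cell
type by two-sample t statistics (that type vs all others) on reference
replicates, taking the top 50 hyper- and 50 hypomethylated CpGs
(per_type = 100). The NRBC CpG association scan regresses M-values on
the *estimated* NRBC fraction over non-BPD samples (robust regression,
Bonferroni at 0.05 over analyzed probes); using the estimated fraction
rather than reference-profile similarity is an interpretation choice,
flagged here because the two formulations differ.

## Robust-regression EWAS

Each CpG is fit by Huber IRLS: ψ tuning c = 1.345, scale = MAD of
residuals about zero (normal-consistent, re-estimated each iteration),
convergence when the largest coefficient change falls below 1e-8, cap
50 iterations (non-converged CpGs are flagged and the last iterate
reported — a small percentage at study scale, from IRLS limit cycles).
Standard errors use the classical corrected robust covariance
(the "H1" form); the implementation matches `statsmodels` RLM to ~1e-10
on shared problems (tested) but is vectorized across all CpGs at once —
shared design matrix, batched weighted least squares — which is what
makes a 5 × 20,000-CpG null calibration feasible on one CPU in minutes.
p-values use the t distribution with n − rank(X) degrees of freedom
(slightly conservative relative to the normal at n = 107).

The design matrix holds intercept, phenotype, continuous covariates,
percentile-transformed covariates (empirical CDF, ties share values,
max ↦ 1 — used for the heavily skewed oxygen-days count), one-hot
categorical covariates against a reference first level with levels under
3 samples pooled into "other" (avoids separation), and the seven
estimated cell fractions. Estimated (unconstrained-sum) fractions do not
lie exactly on the simplex, so including all seven alongside an
intercept is numerically full-rank; exact simplex fractions would not
be.

Multiple-testing control: Bonferroni (min(1, p·m), threshold helper
α/m) and Benjamini-Hochberg step-up. Group summaries report arithmetic
beta means ×100 per group rounded to 2 decimals, with dMeth defined as
the difference of the *reported* means so printed columns are exactly
self-consistent. Overlap between CpG sets uses the one-sided upper-tail
hypergeometric test, with the overlap percentage expressed relative to
the reference set.

## Stochastic epimutations

A SEM is a beta value above Q3 + 3·IQR or below Q1 − 3·IQR of its CpG's
distribution across *all* samples jointly (cases and controls share one
reference distribution; a leave-one-out variant is not implemented).
Constant rows have IQR 0, so any deviation is flagged. Computation is on
beta values by default (`scale="m"` available). EML = ln(count), with
zero counts mapped to 0 under a warning (zero is off-support in real
cohorts). EML associations are reported three ways: unadjusted OLS
correlation, biweight midcorrelation (bicor: median/MAD-based Tukey
biweights, 9·MAD bandwidth, Pearson fallback when a MAD is zero — which
is always the case for a binary phenotype), and covariate-adjusted Huber
regression, plus a univariate covariate screen.

## Epigenetic gestational age

Clocks are linear: EGA = intercept + Σ coefᵢ·βᵢ, read from a CSV whose
first row is `(Intercept)` — compatible with published clock
supplements, which are user-supplied inputs, not bundled. Missing clock
CpGs (≤50%, else error) contribute coef × cohort grand-mean beta by
default so predictions are not systematically shifted. Acceleration is
the OLS residual of EGA on clinical GA (positive = epigenetically
older); residuals are mean-zero and orthogonal to GA by construction.
The phenotype association uses OLS by default (a robust flag exists);
the training helper fits a ridge-penalized regression (α = 1) on the
CpGs most correlated with GA.

## Synthetic cohort generator

Defaults encode the study design the downstream analyses assume:
107 samples, 14 cases assigned deterministically to the highest latent
risk scores (decreasing in GA and birth weight plus noise) so the 14/93
split is exact per cohort; GA ~ Uniform(24, 35) weeks; birth weight
linear in GA (60 g/week around a 1150 g VLBW-cohort mean) with Gaussian
noise scaled so the population r² is 0.38. The NRBC fraction is
expit(latent Gaussian), its mean and SD moment-calibrated to 29.9% /
24.1% by Gauss–Hermite quadrature and root finding, with the latent
correlation to birth weight calibrated the same way to an observed
r² = 0.16; the remaining six fractions split the residual mass by a
Dirichlet draw with granulocyte-dominated cord-blood weights. Oxygen
days increase with disease (+40) and decrease with GA; a smoking
indicator has elevated probability at high NRBC, and the smoking
biomarker CpG (an NRBC-hypomethylated CpG) is reduced by 12 percentage
points in smokers.

Methylation is reference mixture (R·w) plus: 50 disease-effect CpGs at
±5 percentage points in cases (64% hypomethylated, matching the
direction balance the full-scale analysis reports); 500 CpGs tracking GA
directly at ±0.01 beta/week (the developmental signal that makes
gestational-age clocks trainable); batch effects on the M scale as
additive location (SD 0.1) plus multiplicative scale (log-SD = half the
location SD, so `batch_sd = 0` disables batch effects entirely);
observation noise beta-distributed with mean = target and precision
1000 (SD ≈ 0.016 at β = 0.5, typical array-replicate noise; a
logit-normal alternative with matched delta-method variance is a flag;
precision ∞ gives the exact mixture). Epimutations are injected at
Poisson(200) positions per sample (≈1% of the default 20,000 CpGs,
within the per-probe range the full-scale assay implies), magnitude
±0.4 pushed away from the current value; `sem_bpd_rate_ratio` scales
the case rate for power studies and defaults to 1 (no group
difference). All injected positions, effect CpGs, true fractions, GA/BW
and the clock are recorded as ground truth. Defaults scale the CpG count
to 20,000 for desk-size runs; full scale is a config choice, and
`sem_rate` is an absolute per-sample count, so scaled-down runs should
scale it proportionally.

What the generator does *not* emulate: GA dependence of cell fractions
beyond the NRBC–birth-weight coupling; correlation structure between
neighboring CpGs; probe-type chemistry differences; detection p-values
beyond a boolean failure mask; sex-chromosome dosage; and any coupling
of epimutation positions to NRBC-associated CpGs (injected SEMs are
uniform over CpGs, so SEM∩NRBC overlap is at chance in synthetic runs —
the overlap *machinery* is what is exercised). Passing tests therefore
demonstrate the statistical machinery under the stated covariate and
noise structure, not performance on real arrays.

## Numerical notes and degenerate inputs

Betas are clipped to [1e-6, 1−1e-6] after injection, with the clipped
count logged. NNLS ties/degeneracy follow the active-set convention of
lowest column index. A constant phenotype, singular design, all-failed
sample set, too-small reference (< 100 discriminating CpGs per type) and
out-of-range beta files are errors with explicit messages. Perfect-fit
responses (zero residual scale) short-circuit the IRLS and report zero
scale. Determinism: every stochastic step flows from one integer seed;
identical configurations are bit-identical, and the pipeline summary is
byte-identical across reruns with the same seed.

## Known limitations

The robust SE is the classical homoscedastic form, not a
heteroscedasticity-consistent sandwich; it is calibrated here only after
batch-scale adjustment (see above). Reported group means use all
samples, unweighted, and will differ from covariate-adjusted marginal
means. The EWAS treats CpGs independently; no spatial/regional
smoothing. The percentile transform is in-sample (no train/test split
semantics). The deconvolution assumes the reference spans the true cell
populations; unmodeled cell types load onto the nearest profiles.

## Problem sizes used by the test and acceptance runs

Unit and property tests run on 700–2,000-CpG cohorts; calibration,
power, deconvolution-recovery and null-inflation checks run at the study
scale of 20,000 CpGs × 107 samples (5 null cohorts for the pooled
type-I estimate; 20 replicate cohorts for cohort-structure moments).
These sizes are the package's desk-scale defaults; all of them are
config choices.
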