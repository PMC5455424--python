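# Methods notes

## Score construction

The panel score multiplies normalized genotype odds ratios. For a SNP
with per-allele OR *r* and risk-allele frequency *p*, the normalizing
constant is the HWE mean μ = (1−p)² + 2p(1−p)r + p²r², giving the triple
(1/μ, r/μ, r²/μ) with population mean exactly 1 (enforced to 1e−12).
The supplied/published RAF is always used for normalization — it is never
re-estimated from the study sample, which is outcome-selected; the QC
stage is the place where supplied and observed frequencies can be
compared. Scores are accumulated in log space so 88-SNP products cannot
underflow; a missing assay contributes log-factor 0 (population risk 1.0).

Analytic moments of log *S* follow from genotype ∼ Binomial(2, p) per
SNP: mean and variance are sums of per-SNP moments, OR per SD is
exp(sd), and the expected interquartile-range OR uses the normal
approximation exp(sd·(z₀.₇₅ − z₀.₂₅)). The normal approximation is
adequate for panels of ~20+ SNPs (log S is a sum of many small
independent terms); exact quartiles can always be obtained by simulating
genotypes under the panel with a fixed seed.

James–Stein shrinkage of published log-ORs uses the positive-part
estimator toward the panel mean, c = max(0, 1 − (k−3)·mean(se²)/Σ(β−β̄)²),
with SEs derived from published CIs as (log hi − log lo)/(2·1.96). The
degenerate zero-spread case returns full shrinkage (c = 0) with a
warning — the estimator's variance-ratio is undefined there and the
common mean is the only defensible target.

## Quality control

Order is fixed and deterministic: SNP call-rate filter (> 2% failures
excluded, strict inequality), then sample filter (> 10 failed SNPs,
strict), then HWE and the r² screen on the filtered matrix. The HWE
check compares the observed count of homozygotes (both classes jointly)
with the binomial expectation p̂² + (1−p̂)² at the control-estimated
allele frequency; the two-sided p-value is the minimum-likelihood
(small-sample exact) rule. Control-only frequency estimation is the
default because cases are selected on outcome; a flag allows all-sample
estimation. Pairwise r² is the squared Pearson correlation of 0/1/2
dosages over complete pairs — the information a genotype matrix supports
(no haplotype phase).

## Conditional-logit fitting

Newton–Raphson from β = 0 with step-halving, on internally standardized
covariates (within-set deviation SD), analytic gradient and Hessian via
per-set softmax weights. Convergence at max|score| < 1e−8 or step
< 1e−10; covariance is the inverse observed information back-transformed
to the natural scale. Complete separation is detected two ways — a
diverging standardized coefficient norm (> 15) during iteration, or an
exploding standardized SE at a nominally converged optimum — and is
reported (non-converged, with direction), never silently truncated.
Covariates constant within every set have a completely flat likelihood;
β = 0 is returned as the canonical root with infinite variance and a
warning. A covariate that is set-level while others vary is rejected
with an explicit error: matching absorbs set-level main effects, which
therefore enter only through interactions.

IQ-OR quartiles are computed on the log score among controls with the
linear-interpolation quantile definition. CIs are Wald (estimate ±
1.96·SE) to keep the symmetric-on-log-scale reporting convention;
likelihood-ratio χ² statistics are reported alongside. The matched
concordance index pools case-control pairs across sets with ties counted
half; a per-set-averaged variant is available behind a flag and labeled
as such.

## Calibration and recalibration

The calibration slope is the conditional-logit coefficient on the
expected per-subject log-OR; 1 = perfectly calibrated relative risks.
Decile diagnostics bin all subjects at control-score deciles and fit
decile indicators inside the conditional likelihood. Because the
reference level is arbitrary under matching, observed decile ORs are
rescaled so their control-frequency-weighted mean is 1, which makes them
directly comparable to the predicted ORs (mean control score per decile,
for a mean-unity score) without privileging any decile. Deciles without
cases report an absent OR rather than failing. Recalibration raises the
score to the power of the slope. The cohort-mode check uses deciles of
expected risk with the standard Hosmer–Lemeshow variance term
E(1 − E/n) per bin and df = bins − 2; zero-expectation bins merge with a
neighbor (df adjusted, warned).

## Absolute risk and reclassification

Control weight 1, case weight (t/(1−t))·(n_ctrl/n_case) reproduce a
target event fraction t (default 6%) exactly. Per-subject ORs are
anchored by solving the weighted mean of o·OR/(1+o·OR) = t for the
baseline odds o — the mean is strictly increasing in o, so the root is
unique; Brent's method on [1e−8, 1e3] with 1e−12 tolerance. Risks at or
above the 8% threshold are classified "high" (inclusive boundary, the
convention for offering preventive therapy at a stated risk level), and
risks are computed as-if-untreated. The up-vs-down reclassification OR
uses raw counts (a matched-sample association) with a Woolf log-scale CI
and Haldane 0.5 correction for zero cells; weighted counts are reported
descriptively.

## Synthetic-data generator

The generator defines the study conditions: 88 independent biallelic
SNPs under HWE; 277 matched sets with two controls and 82 with one
(derived from the 359 cases / 636 controls split across a large trial
and its pilot); matching on trial, arm and age ±2 years with age uniform
on 35–70; 1:1 randomization to tamoxifen (OR 0.7) or placebo; a
lognormal classic-model OR with mean 1 and log-SD 0.28 (chosen so its
implied IQ-OR ≈ 1.45, the strength a classic risk model shows in such
cohorts), independent of genotype by construction; population mean
10-year risk 6%; 74% of cases ER-positive.

Per-allele ORs span 1.03–1.35. Log effects follow a truncated
exponential (scale 0.045) rather than a flat draw: drawing ORs uniformly
on that range would give an 88-SNP panel with OR per SD ≈ 2.9, far
stronger than any published panel; the exponential tail reproduces the
many-small/few-large shape of genome-wide association effect sizes and
yields OR per SD ≈ 1.6 — the expected strength of real panels this size
(observed IQ-OR of ~1.37 at 46% calibration implies an expected IQ-OR
near 2.0, i.e. SD(log S) ≈ 0.5). A `uniform` option retains the flat
draw. The attenuation parameter λ multiplies true log effects and is
what the calibration-slope estimator targets; an optional ER-specific
mode restricts the genotype effect to the ER-positive disease process
(two competing sub-risks splitting the target rate 74/26) and is off by
default.

Follow-up-time matching is emulated only through the sampling order (the
analysis consumes sets, not event times); there is no LD between SNPs,
no population stratification, and no genotyping-error model beyond
missingness — so passing tests demonstrate correctness of the analysis
chain under its stated assumptions, not robustness to those real-data
features. Power estimation runs the full simulate → sample → score → fit
pipeline per replicate with a two-sided Wald test.

## Problem sizes used in the tests

Monte-Carlo checks use sizes chosen to keep sampling error a small
fraction of the tolerance being asserted: 200,000 subjects for the
mean-unity law, 1,000 replicates for design power, 500 replicates of
300-set studies for test size, 200 replicates for slope-recovery
coverage, and 1,000 random instances for the concordance oracle.
Module-level inference tests draw matched sets directly from the
conditional model (case slot ∝ exp(βx) within each set), which targets
the same likelihood as the full generative pipeline at a fraction of the
cost; the acceptance-level checks use the full pipeline.

## Known limitations

- The classic-model (TC) risk is consumed as an input OR or 10-year
  risk; its internals are out of scope.
- No imputation of failed assays; the missing-genotype rule assigns
  population risk 1.0.
- Wald CIs can undercover at very small set counts or near separation;
  the separation diagnostics flag the latter.
- The Hosmer–Lemeshow cohort check applies to unmatched cohort data
  only, not to the matched sample.
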