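# prsmatch

Polygenic-risk-score analysis for **matched case-control data from
prevention trials**: normalized SNP-score construction, genotype QC,
conditional-logistic inference, calibration-slope estimation and
recalibration, and weighted absolute-risk reclassification — plus a
synthetic-data generator that emulates the nested case-control structure
of two breast-cancer tamoxifen prevention trials so the whole chain is
testable without individual-level trial data.

## Who this is for

Biostatisticians and genetic epidemiologists evaluating whether a panel
of common risk SNPs adds information to a classic risk model (e.g. a
Tyrer–Cuzick-style score) inside a matched case-control study, and
whether the published per-SNP effects need recalibration in a high-risk
population.

## The model

Each biallelic SNP *j* has a published per-allele odds ratio
*r<sub>j</sub>* and risk-allele frequency *p<sub>j</sub>*. Under
Hardy–Weinberg equilibrium the genotype odds ratios (1, *r*, *r*²) are
normalized by

&nbsp;&nbsp;μ<sub>j</sub> = (1−p)² + 2p(1−p)·r + p²·r²

so every genotype OR triple has population mean exactly 1. A woman's
score *S* is the product of her normalized genotype ORs over the panel
(missing assays contribute the population factor 1.0); arithmetic is in
log space.

Inference uses the conditional likelihood for 1:m matched sets
(one case per set, matched on trial, arm and age ±2 years):

&nbsp;&nbsp;ℓ(β) = Σ<sub>sets</sub> [ x<sub>case</sub>·β − log Σ<sub>j∈set</sub> exp(x<sub>j</sub>·β) ]

maximized by Newton–Raphson with analytic gradient and Hessian. Effects
are summarized as the interquartile-range odds ratio
IQ-OR = exp(β̂·(Q3−Q1)) over the control log-score distribution, and the
matched concordance index mC (probability the case outscores a matched
control, ties ½). The **calibration slope** λ is the coefficient from
regressing case status on the expected log-OR: λ = 1 means published
effects hold; λ < 1 means attenuation, and the recalibrated score is
S<sup>λ</sup>. Absolute 10-year risks are recovered by weighting cases
and controls to the cohort's 6% event rate and anchoring
risk = o\*·OR/(1+o\*·OR) so the weighted mean hits the target; an 8%
threshold defines the reclassification table and up-vs-down odds ratio.

## Worked example

Simulate a study with a true attenuation of 0.46 (true SNP effects at 46%
of published strength) and run the full pipeline:

```python
import numpy as np
from prsmatch import RunConfig, run_pipeline
from prsmatch.qc import GenotypeMatrix
from prsmatch.simulate import (SimConfig, simulate_panel, simulate_cohort,
                               nested_case_control_sample)

cfg = SimConfig(attenuation=0.46, missing_rate=0.002)
rng = np.random.default_rng(7)
panel = simulate_panel(cfg, rng)                 # 88 synthetic SNPs
cohort = simulate_cohort(panel, cfg, rng)        # two-trial population
study = nested_case_control_sample(cohort, cfg, rng)  # 277 1:2 + 82 1:1 sets
matrix = GenotypeMatrix(list(study.sample_id), panel.rsids, study.genotypes)
results = run_pipeline(panel, matrix, study.to_dataframe(),
                       RunConfig(output_dir="results_demo", seed=7))
```

This run prints (via `results`):

```
SNP score IQ-OR      1.396  (95% CI 1.161 to 1.679)
matched concordance  0.572
calibration slope    49.6%  (95% CI 22.2% to 77.0%)
Spearman rho (TC,S)  -0.0015  (P = 0.97)
```

The IQ-OR says a woman at the control 75th percentile of the score has
~1.4-fold the odds of a woman at the 25th; the slope estimate recovers
the simulated 46% attenuation (within its CI), i.e. observed risks are
about half of what the published per-SNP effects predict; and the score
is independent of the classic-model risk, so the two can be combined
multiplicatively.

The same stages are available from the shell:

```
prsmatch simulate --seed 7 --out simdata
prsmatch run --seed 7 --out results
prsmatch power --seed 1 --n-sims 1000
```

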