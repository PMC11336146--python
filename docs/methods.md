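# Methods

This note records the statistical model behind `senosig`, the parameters
that matter, the numerical choices, and what the synthetic cohorts do and
do not establish about real data.

## Model and procedure

The analysis treats relapse-free survival as right-censored follow-up
(time in months, event ∈ {0,1}) under proportional hazards. Three layers
sit on top of each other:

**Per-gene screen.** Each gene is assessed individually with a univariate
Cox model on its expression. By default the gene's values are z-scored
before fitting; this leaves the sign of the coefficient (and hence the
gene's weight) unchanged while making the reported per-gene HRs per-SD and
comparable across genes of very different intensity scales. A
median-split variant is available behind a flag for users who prefer a
rank-based screen. The weight rule is deliberately coarse: +1 for HR > 1,
−1 for HR ∈ (0,1), 0 for anything unfittable (constant expression,
non-convergence, HR exactly 1). No shrinkage or multivariable selection is
applied — the coarseness is the method's point: the signature aggregates
directions, not effect sizes.

**Score.** The signature score is the average of weight × expression over
the weighted genes, computed on the normalized (mean-1000) linear
intensities. On that scale high-intensity genes dominate the average; an
optional per-gene z-scoring flag exists for users who want scale-free
aggregation, but it is off by default because the raw-scale weighted mean
is the form the workflow is defined in.

**Cutoff scan.** Candidate thresholds are the distinct observed score
values v with Q₁ ≤ v < Q₃ (quartiles by the linear-interpolation
convention; configurable). Scanning observed values is exhaustive in the
only sense that matters: the group assignment, and therefore the test
statistic, changes only at observed values. Each admissible split (both
groups ≥ `min_group`, default 10% of n with a floor of 5) is scored by the
Wald p of the binary-covariate Cox fit (default) or by the log-rank test;
the per-cutoff p-values are Benjamini–Hochberg adjusted with the scan as
the family, and the minimum-raw-p cutoff is selected (ties break toward
the median score). Minimum-p selection is anti-conservative by
construction; the BH-adjusted minimum is what the reported "FDR" refers
to. A permutation-exact correction (Lausen–Schumacher style) is out of
scope.

**Replication and adjustment.** Per-dataset analysis reuses the weights
fitted once on the integrated cohort — this is the only reading under
which the per-dataset runs validate *the same* signature — and re-scans
the cutoff within each dataset (the global cutoff is available behind a
flag). Datasets with n < 30 or fewer than 10 events are excluded and
listed. Multivariate adjustment is deliberately bivariate: the signature
(dichotomized at the whole-cohort cutoff, matching how its univariate
significance was established) is paired with one encoded clinical
covariate at a time on that covariate's complete cases, because fitting
all covariates jointly would discard most samples to missingness.
Encodings: sex and tumor location binary; T/N/stage/grade ordinal
integers; M binary; microsatellite instability ordinal with the merged
"stable or low" level placed at 0.5 between stable (0) and high (2). All
encodings are configurable.

## Survival primitives

Kaplan–Meier, the two-group log-rank test and Cox fitting are implemented
directly (vectorized numpy) because the cutoff scan and the calibration
simulations need on the order of 10⁴–10⁵ small fits. Choices:

- Risk set at t is {time ≥ t}; at tied times events precede censorings.
- Cox partial likelihood uses the Efron tie correction, maximized by
  Newton–Raphson with step-halving, converged when the log-likelihood
  changes by < 1e-8 (relative) or 100 iterations. The linear predictor is
  max-shifted before exponentiation; the shift cancels exactly in the
  likelihood, gradient and information matrix.
- A fit that converges onto a coefficient plateau with |β| > 15 is flagged
  as monotone likelihood (perfect separation); flagged fits carry their
  last estimates but `converged=False`, and the Wald-based scan skips such
  cutoffs. Structurally impossible fits (constant covariate, zero events)
  raise instead.
- Confidence intervals are Wald on the log scale with z = 1.959964;
  Kaplan–Meier bands use Greenwood's variance on the survival scale,
  clipped to [0,1], with the band collapsing where S reaches 0.
- The unit tests cross-check all three primitives against lifelines and
  against enumeration oracles (hand product-limit tables, literal O−E/V
  accumulation, a 1e-4 grid search of the enumerated partial likelihood).

Percentages in the clinical summary table use round-half-away-from-zero to
two decimals over the non-missing records of each feature, the convention
of printed cohort-characteristics tables.

## Synthetic cohorts

`simulate_cohort` emulates an integrated multi-study microarray cohort:

- **Expression.** Per-gene log-normal intensities with per-gene locations
  drawn log-uniformly over ~50–4000 (MAS5-like right-skewed scales,
  within-gene log-SD 0.5), a per-dataset per-gene multiplicative batch
  shift (log-SD 0.1), and every array scaled to mean 1000 exactly.
- **Survival.** Hazard h₀·exp(Σ_g β_g z_g) with z the within-dataset
  standardized expression, so true effects are scale-free and batch shifts
  cancel in the risk model while still distorting the matrix the analysis
  sees. Defaults: 10 datasets totalling 1130 samples, 40 risk and 40
  protective genes at β = ±0.5 among 200, exponential baseline.
- **Censoring.** Administrative-uniform: censor times are window·U(0,1)
  with the window calibrated by bisection against the drawn event times so
  the realized event fraction hits the target (default 24% events). The
  baseline rate default (0.00042/month) was chosen so that, at the default
  configuration, mean observed follow-up lands near 50 months; it is small
  because 80 effect genes at |β| = 0.5 give the linear predictor an SD of
  ~4.5.
- **Covariates.** Drawn independently of survival at realistic category
  frequencies with per-feature missingness; an optional confounded mode
  ties stage to the true log-hazard for multivariate stress tests.
- Identical configuration (including seed) reproduces the cohort bit for
  bit.

What the generator does **not** emulate: gene–gene correlation beyond the
shared batch shift, probe-level artifacts, non-proportional hazards,
informative censoring, and calibrated effect-size realism (β = ±0.5 per SD
across 80 genes is a strong composite signal). Passing tests therefore
demonstrate that the pipeline recovers the structure it assumes —
directional effects under proportional hazards with independent censoring
— not that any particular real cohort satisfies those assumptions.

## Problem sizes used in the checks

The test suite and `scripts/acceptance.py` run at sizes chosen to make the
statistical properties measurable while keeping each check in seconds: the
estimator-consistency simulation uses n = 5000 uncensored subjects; sign
recovery uses one 600-sample cohort (200 genes); the null-scan calibration
uses 500 replicates of 200-sample null cohorts; pipeline closure uses
three 150-sample datasets. These sizes are part of the study conditions
the package declares, not tuning knobs.

## Known limitations

- The minimum-p cutoff is reported with its BH-adjusted p over the scan;
  this controls the scan-level FDR under positive dependence but does not
  debias the selected HR itself (winner's curse on the effect size).
- Bivariate adjustment cannot rule out confounding by combinations of
  covariates that are never observed jointly.
- The screen tests each gene marginally; strongly correlated genes share
  credit, and the ±1 weights make no attempt to deduplicate them.
- QC thresholds (3'/5' ratio ≤ 3, present calls ≥ 25%, bioBCD spikes
  required) are conventional defaults, not derived from the data; arrays
  flagged `fail` are excluded and `unevaluable` arrays are kept, both
  logged.
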