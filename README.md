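# senosig

Prognostic gene-signature survival analysis for multi-dataset expression
cohorts — built around the senescence-signature workflow used in
gero-oncology: screen every gene of a candidate set (e.g. the SenMayo
senescence gene list) for its individual effect on relapse-free survival,
combine the genes into a single sign-weighted score, dichotomize that score
at the best cutoff between its quartiles with multiple-testing correction,
and check that the resulting risk groups replicate across the datasets that
make up the cohort and survive adjustment for clinical covariates.

## The method

Given a normalized expression matrix X (samples × genes, each array scaled
to mean intensity 1000) and right-censored follow-up (tᵢ, δᵢ):

1. **Directional screen.** For each gene g, fit a univariate Cox
   proportional-hazards model h(t|x) = h₀(t)·exp(β_g x_g). The gene's
   weight is w_g = +1 if HR_g = exp(β_g) > 1, −1 if HR_g ∈ (0, 1), 0
   otherwise (unfittable genes are dropped with a reason).
2. **Signature score.** s(i) = mean over weighted genes of w_g · X[i, g] —
   the average weighted expression, so high scores collect risk-associated
   expression.
3. **Cutoff scan.** Every distinct observed score value v with
   Q₁ ≤ v < Q₃ is tried as a threshold (low = {s ≤ v}, high = {s > v});
   each split is tested (Cox Wald by default, log-rank optionally), the
   p-values are Benjamini–Hochberg adjusted across the scan, and the
   minimum-p cutoff is selected.
4. **Evaluation.** Kaplan–Meier curves, log-rank test and the
   dichotomized-signature Cox HR with 95% CI at the selected cutoff;
   per-dataset replication with the *shared* weights (cutoff re-optimized
   within each sufficient dataset); and paired bivariate Cox models of the
   signature with one clinical covariate at a time on that covariate's
   complete cases, the standard response to patchy clinical annotation.

The survival primitives (product-limit estimator with Greenwood bands,
two-group log-rank, Newton–Raphson Cox fit with Efron tie handling) are
implemented in vectorized numpy so the scan's hundreds of fits and the
null-calibration simulations run in seconds.

A synthetic-cohort generator (`senosig.simulate`) produces multi-dataset
cohorts with known ground truth — log-normal MAS5-like intensities,
per-dataset batch shifts, proportional-hazards survival driven by known
risk/protective genes, censoring calibrated to a target rate — so the whole
pipeline is testable end to end without any external download.

## Worked example

```python
from senosig import (SenescenceSignatureModel, SimulationConfig,
                     simulate_cohort, simulate_clinical_covariates)

cfg = SimulationConfig(n_samples=(150, 150, 150), seed=42)
expr, clin, truth = simulate_cohort(cfg)
clin = simulate_clinical_covariates(clin, eta=truth.eta, seed=43)

results = SenescenceSignatureModel(expr, clin).fit()
print(results.summary())
```

```
Senescence-signature survival analysis
======================================================
samples: 450    events: 108
signature genes: 200 (+1: 99, -1: 101, 0: 0)

cutoff scan (between score quartiles)
  scanned cutoffs : 224
  selected cutoff : 74.3038
  HR range        : 4.79 - 8.07

high vs low signature at the selected cutoff
  HR = 5.60, 95% CI = 3.80-8.25, p = 2.6e-18
  FDR-adjusted minimum p = 1.93e-16
  log-rank: chi2 = 96.47, p = 9.07e-23
```

The cohort carries 40 risk and 40 protective genes at |log-hazard| 0.5, so
the fitted signature splits the 450 samples into a high-score group with
~5.6-fold relapse hazard; every scanned cutoff gives HR > 1 (range
4.8–8.1), i.e. the signature is robust to the cutoff choice. Replication
per dataset:

```python
for r in results.per_dataset()[0]:
    print(r.dataset_id, r.n, r.events, round(r.cox.hr, 2),
          r.cox.format_p(), r.direction_consistent)
```

```
ds01 150 33 6.35 1.1e-06 True
ds02 150 42 6.57 4.8e-09 True
ds03 150 33 5.79 1.4e-06 True
```

Higher signature expression means worse outcome in every dataset.
`results.paired_multivariate("stage")` fits the signature together with one
clinical covariate on its complete cases; `results.plot_km(path)` and
`results.plot_scan(path)` draw the KM plot (with at-risk counts and the
HR/CI/p annotation) and the significance-vs-cutoff profile with the
minimum-p cutoff circled.

The same workflow is scriptable from the shell:

```
senosig simulate --seed 3 --out sim/
senosig scan --expression sim/expression.tsv --clinical sim/clinical.tsv --out scan/
senosig all --config run.yaml --out report/      # full bundle + manifest
```

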