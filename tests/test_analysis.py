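"""Whole-cohort analysis, per-dataset replication and paired Cox models."""

import numpy as np
import pandas as pd
import pytest

from senosig.analysis import (
    CollinearityError,
    analyze_cohort,
    paired_multivariate,
    paired_multivariate_all,
    per_dataset,
)
from senosig.io import ClinicalTable, ExpressionMatrix, ValidationError
from senosig.signature import screen_genes
from senosig.survival import DegenerateDataError, SurvivalData


@pytest.fixture(scope="module")
def fitted(effect_cohort):
    expr, clin, truth = effect_cohort
    weights = screen_genes(expr, SurvivalData.from_clinical(clin))
    return expr, clin, truth, weights


def test_analyze_cohort_significant_with_true_effect(fitted):
    expr, clin, _, weights = fitted
    report = analyze_cohort(expr, clin, weights)
    assert report.scan.selected_p_adj < 0.01
    assert report.cox.hr > 1  # high signature -> worse outcome
    # KM curves separate: high-score survival below low-score survival
    t_star = float(np.median(clin.time))
    assert report.km_high.survival_at(t_star) < report.km_low.survival_at(t_star)


def test_analyze_cohort_tiny_cohort_rejected(fitted):
    expr, clin, _, weights = fitted
    keep = list(expr.sample_ids[:3])
    with pytest.raises((DegenerateDataError, ValidationError)):
        analyze_cohort(expr.subset_samples(keep), clin.subset(keep), weights)


def test_per_dataset_direction_consistency(fitted):
    expr, clin, _, weights = fitted
    results, excluded = per_dataset(expr, clin, weights)
    assert len(results) == 3 and not excluded
    assert all(r.direction_consistent for r in results)
    assert all(r.n == 150 for r in results)


def test_per_dataset_matches_single_dataset_analysis(fitted):
    expr, clin, _, weights = fitted
    results, _ = per_dataset(expr, clin, weights)
    first = results[0]
    mask = clin.data["dataset_id"] == first.dataset_id
    ids = list(clin.data.index[mask])
    report = analyze_cohort(expr.subset_samples(ids), clin.subset(ids), weights)
    assert report.scan.selected_cutoff == pytest.approx(first.selected_cutoff)
    assert report.cox.hr == pytest.approx(first.cox.hr)


def test_per_dataset_sufficiency_filter(fitted):
    expr, clin, _, weights = fitted
    df = clin.data.reset_index().copy()
    # shrink one dataset below min_n and censor another completely
    small = df[df["dataset_id"] == "ds01"].head(8)
    rest = df[df["dataset_id"] != "ds01"].copy()
    rest.loc[rest["dataset_id"] == "ds02", "event"] = 0
    patched = ClinicalTable(pd.concat([small, rest]), clin.vocabulary)
    results, excluded = per_dataset(expr, patched, weights)
    reasons = dict(excluded)
    assert "ds01" in reasons and "n=8" in reasons["ds01"]
    assert "ds02" in reasons and "events=0" in reasons["ds02"]
    assert [r.dataset_id for r in results] == ["ds03"]


def test_paired_multivariate_signature_survives_independent_covariate(fitted):
    expr, clin, _, weights = fitted
    report = analyze_cohort(expr, clin, weights)
    res = paired_multivariate(
        report.scores, clin, "sex", report.scan.selected_cutoff
    )
    assert res.signature.p < 0.01        # true signal retained
    assert res.covariate.p > res.signature.p
    assert res.n_complete == int(clin.data["sex"].notna().sum())


def test_paired_multivariate_all_covers_available_covariates(fitted):
    expr, clin, _, weights = fitted
    report = analyze_cohort(expr, clin, weights)
    results, skipped = paired_multivariate_all(
        report.scores, clin, report.scan.selected_cutoff
    )
    names = {r.covariate_name for r in results} | {n for n, _ in skipped}
    assert names == set(clin.covariates_present())
    for r in results:
        assert r.signature.n == r.covariate.n == r.n_complete


def test_paired_multivariate_missing_and_collinear(fitted):
    expr, clin, _, weights = fitted
    report = analyze_cohort(expr, clin, weights)
    cutoff = report.scan.selected_cutoff
    df = clin.data.reset_index().copy()
    df["msi"] = None
    all_missing = ClinicalTable(df, clin.vocabulary)
    with pytest.raises(DegenerateDataError):
        paired_multivariate(report.scores, all_missing, "msi", cutoff)
    # covariate identical to the dichotomized signature -> collinear
    df2 = clin.data.reset_index().copy()
    high = report.scores.loc[df2["sample_id"]].to_numpy() > cutoff
    df2["sex"] = np.where(high, "male", "female")
    collinear = ClinicalTable(df2, clin.vocabulary)
    with pytest.raises(CollinearityError):
        paired_multivariate(report.scores, collinear, "sex", cutoff)


def test_paired_hr_close_to_univariate_with_independent_covariate():
    """Adding an independent covariate should barely move the signature HR."""
    rng = np.random.default_rng(77)
    n = 2000
    score = rng.normal(size=n)
    sex = rng.integers(0, 2, n)
    t = rng.exponential(1 / np.exp(0.7 * (score > 0))) + 1e-9
    clin = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "time": t,
                "event": 1,
                "sex": np.where(sex == 1, "male", "female"),
            }
        )
    )
    scores = pd.Series(score, index=clin.sample_ids)
    from senosig.survival import cox_fit_single

    uni = cox_fit_single((score > 0).astype(float), SurvivalData(t, np.ones(n, int)))
    paired = paired_multivariate(scores, clin, "sex", 0.0)
    assert abs(paired.signature.hr - uni.hr) / uni.hr < 0.15
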