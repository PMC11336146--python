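"""Cohort-level analysis: whole-cohort signature evaluation, per-dataset
replication with a sufficiency filter, and paired (bivariate) Cox models.

The per-dataset step validates one shared signature: gene weights are fitted
once on the integrated cohort and reused in every dataset, while the
dichotomization cutoff is re-optimized within each dataset (the global
cutoff is available behind a flag).  Paired multivariate models combat
covariate missingness by fitting the signature with one clinical covariate
at a time on that covariate's complete cases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cutoff import CutoffScanResult, scan_cutoffs
from .io import ClinicalTable, ExpressionMatrix, ValidationError
from .signature import GeneWeightTable, score_samples
from .survival import (
    CoxResult,
    DegenerateDataError,
    KMCurve,
    LogrankResult,
    SurvivalData,
    cox_fit,
    km_estimate,
    logrank_test,
)

logger = logging.getLogger(__name__)

#: Numeric encodings for clinical covariates entering Cox models.  Ordinal
#: stages map to their integer codes; the merged microsatellite level
#: "stable or low" sits between stable (0) and high (2).
DEFAULT_ENCODINGS: dict[str, dict[str, float]] = {
    "sex": {"female": 0.0, "male": 1.0},
    "t_stage": {"1": 1.0, "2": 2.0, "3": 3.0, "4": 4.0},
    "n_stage": {"0": 0.0, "1": 1.0, "2": 2.0, "3": 3.0},
    "m_stage": {"0": 0.0, "1": 1.0},
    "stage": {"1": 1.0, "2": 2.0, "3": 3.0, "4": 4.0},
    "grade": {"1": 1.0, "2": 2.0, "3": 3.0},
    "location": {"proximal": 0.0, "distal": 1.0},
    "msi": {"stable": 0.0, "stable_or_low": 0.5, "high": 2.0},
}


class CollinearityError(ValidationError):
    """The two model terms are perfectly collinear on the complete cases."""


@dataclass
class CohortReport:
    """Everything the whole-cohort analysis produces."""

    scores: pd.Series
    scan: CutoffScanResult
    km_low: KMCurve
    km_high: KMCurve
    cox: CoxResult          # dichotomized signature at the selected cutoff
    logrank: LogrankResult
    n: int
    events: int


def align(expr: ExpressionMatrix, clin: ClinicalTable):
    """Samples common to both artifacts, in expression order."""
    common = [s for s in expr.sample_ids if s in set(clin.sample_ids)]
    if len(common) < 2:
        raise ValidationError("fewer than 2 samples shared by expression and clinical")
    dropped = expr.n_samples - len(common)
    if dropped:
        logger.info("align: %d expression sample(s) lack clinical data", dropped)
    return expr.subset_samples(common), clin.subset(common)


def analyze_cohort(
    expr: ExpressionMatrix,
    clin: ClinicalTable,
    weights: GeneWeightTable,
    q_low: float = 0.25,
    q_high: float = 0.75,
    min_group: Optional[int] = None,
    test: str = "cox",
) -> CohortReport:
    """Score -> cutoff scan -> Kaplan-Meier at the selected cutoff."""
    expr, clin = align(expr, clin)
    surv = SurvivalData.from_clinical(clin)
    scores = score_samples(expr, weights)
    scan = scan_cutoffs(scores, surv, q_low, q_high, min_group, test)
    high = scan.high_mask(scores)
    km_low = km_estimate(SurvivalData(surv.time[~high], surv.event[~high]))
    km_high = km_estimate(SurvivalData(surv.time[high], surv.event[high]))
    cox = cox_fit(high.astype(float).reshape(-1, 1), surv, names=["signature_high"])[0]
    lr = logrank_test(high.astype(int), surv)
    return CohortReport(scores, scan, km_low, km_high, cox, lr,
                        n=surv.n, events=surv.n_events)


@dataclass(frozen=True)
class DatasetResult:
    dataset_id: str
    n: int
    events: int
    cox: CoxResult
    selected_cutoff: float
    direction_consistent: bool  # HR > 1 for the high-score group


def per_dataset(
    expr: ExpressionMatrix,
    clin: ClinicalTable,
    weights: GeneWeightTable,
    min_n: int = 30,
    min_events: int = 10,
    q_low: float = 0.25,
    q_high: float = 0.75,
    min_group: Optional[int] = None,
    test: str = "cox",
    global_cutoff: Optional[float] = None,
) -> tuple[list[DatasetResult], list[tuple[str, str]]]:
    """Replicate the signature in each dataset with enough follow-up data.

    Weights are shared (fitted on the integrated cohort); the cutoff is
    re-scanned within each dataset unless ``global_cutoff`` is given.
    Returns retained results plus (dataset, reason) exclusions.
    """
    expr, clin = align(expr, clin)
    results: list[DatasetResult] = []
    excluded: list[tuple[str, str]] = []
    for dataset_id, sub in clin.data.groupby("dataset_id", sort=True):
        n = len(sub)
        events = int(sub["event"].sum())
        if n < min_n:
            excluded.append((str(dataset_id), f"n={n} < {min_n}"))
            continue
        if events < min_events:
            excluded.append((str(dataset_id), f"events={events} < {min_events}"))
            continue
        sub_expr = expr.subset_samples(sub.index)
        surv = SurvivalData(sub["time"].to_numpy(), sub["event"].to_numpy())
        scores = score_samples(sub_expr, weights)
        try:
            if global_cutoff is None:
                scan = scan_cutoffs(scores, surv, q_low, q_high, min_group, test)
                cutoff, cox = scan.selected_cutoff, None
                high = scan.high_mask(scores)
            else:
                cutoff = global_cutoff
                high = scores.to_numpy() > cutoff
                if high.all() or not high.any():
                    raise DegenerateDataError("global cutoff splits nothing")
            cox = cox_fit(high.astype(float).reshape(-1, 1), surv,
                          names=["signature_high"])[0]
        except DegenerateDataError as exc:
            excluded.append((str(dataset_id), str(exc)))
            continue
        results.append(
            DatasetResult(
                dataset_id=str(dataset_id),
                n=n,
                events=events,
                cox=cox,
                selected_cutoff=float(cutoff),
                direction_consistent=cox.hr > 1,
            )
        )
    if not results:
        raise ValidationError("no dataset passed the sufficiency filter")
    if excluded:
        logger.info("per_dataset: excluded %s", excluded)
    return results, excluded


def dataset_results_frame(results: Sequence[DatasetResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "dataset_id": r.dataset_id,
                "n": r.n,
                "events": r.events,
                "hr": r.cox.hr,
                "ci_low": r.cox.ci_low,
                "ci_high": r.cox.ci_high,
                "p": r.cox.p,
                "selected_cutoff": r.selected_cutoff,
                "direction_consistent": r.direction_consistent,
            }
            for r in results
        ]
    )


@dataclass(frozen=True)
class PairedCoxResult:
    """Bivariate Cox of (dichotomized signature, one encoded covariate),
    fitted on that covariate's complete cases."""

    covariate_name: str
    n_complete: int
    events: int
    signature: CoxResult
    covariate: CoxResult


def paired_multivariate(
    scores: pd.Series,
    clin: ClinicalTable,
    covariate_name: str,
    cutoff: float,
    encodings: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> PairedCoxResult:
    """Fit signature (dichotomized at ``cutoff``) + one clinical covariate.

    Complete cases = samples with a non-null covariate value.  Raises
    :class:`CollinearityError` when the two terms are perfectly collinear.
    """
    encodings = dict(DEFAULT_ENCODINGS if encodings is None else encodings)
    if covariate_name not in clin.data.columns:
        raise ValidationError(f"covariate {covariate_name!r} absent from clinical table")
    if covariate_name not in encodings:
        raise ValidationError(f"no encoding declared for {covariate_name!r}")
    scores = scores.loc[clin.sample_ids]
    col = clin.data[covariate_name]
    mask = col.notna().to_numpy()
    if mask.sum() == 0:
        raise DegenerateDataError(f"covariate {covariate_name!r} entirely missing")
    sub = clin.data[mask]
    encoded = sub[covariate_name].map(encodings[covariate_name])
    if encoded.isna().any():
        bad = sub[covariate_name][encoded.isna()].iloc[0]
        raise ValidationError(f"no encoding for level {bad!r} of {covariate_name!r}")
    x_cov = encoded.to_numpy(dtype=float)
    if np.ptp(x_cov) == 0:
        raise DegenerateDataError(
            f"covariate {covariate_name!r} constant on complete cases"
        )
    surv = SurvivalData(sub["time"].to_numpy(), sub["event"].to_numpy())
    x_sig = (scores.to_numpy()[mask] > cutoff).astype(float)
    if np.ptp(x_sig) == 0:
        raise DegenerateDataError("signature indicator constant on complete cases")
    corr = np.corrcoef(x_sig, x_cov)[0, 1]
    if abs(corr) > 1 - 1e-12:
        raise CollinearityError(
            f"signature and {covariate_name!r} are perfectly collinear "
            "on the complete cases"
        )
    X = np.column_stack([x_sig, x_cov])
    sig_res, cov_res = cox_fit(X, surv, names=["signature_high", covariate_name])
    return PairedCoxResult(
        covariate_name=covariate_name,
        n_complete=surv.n,
        events=surv.n_events,
        signature=sig_res,
        covariate=cov_res,
    )


def paired_multivariate_all(
    scores: pd.Series,
    clin: ClinicalTable,
    cutoff: float,
    covariates: Optional[Sequence[str]] = None,
    encodings: Optional[Mapping[str, Mapping[str, float]]] = None,
) -> tuple[list[PairedCoxResult], list[tuple[str, str]]]:
    """One paired model per available covariate; degenerate covariates are
    skipped with a reason, mirroring missingness-driven reporting."""
    if covariates is None:
        covariates = clin.covariates_present()
    results, skipped = [], []
    for name in covariates:
        try:
            results.append(paired_multivariate(scores, clin, name, cutoff, encodings))
        except (DegenerateDataError, ValidationError) as exc:
            skipped.append((name, str(exc)))
            logger.info("paired_multivariate: skipped %s (%s)", name, exc)
    return results, skipped


def paired_results_frame(results: Sequence[PairedCoxResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "covariate": r.covariate_name,
                "n": r.n_complete,
                "events": r.events,
                "hr_signature": r.signature.hr,
                "p_signature": r.signature.p,
                "hr_covariate": r.covariate.hr,
                "p_covariate": r.covariate.p,
            }
            for r in results
        ]
    )
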