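"""Array-level preprocessing: scaling normalization, platform probe
restriction, chosen-probe collapse to gene level, and QC flagging.

The upstream summarization (MAS5-style condensing from raw arrays) is out
of scope; this module starts from nonnegative probe- or gene-level
intensities and makes them comparable across arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ProbeMap, ValidationError

logger = logging.getLogger(__name__)


def scale_normalize(expr: ExpressionMatrix, target_mean: float = 1000.0) -> ExpressionMatrix:
    """Scale every sample (array) so its mean intensity equals ``target_mean``.

    This is the classic microarray scaling step: a single multiplicative
    factor per array, so within-array gene rank order is untouched.
    Idempotent.
    """
    if target_mean <= 0:
        raise ValueError("target_mean must be positive")
    means = expr.data.mean(axis=1)
    zero = means[means <= 0]
    if len(zero):
        raise ValidationError(
            f"sample {zero.index[0]!r} has non-positive mean intensity; "
            "cannot scale"
        )
    scaled = expr.data.mul(target_mean / means, axis=0)
    return ExpressionMatrix(scaled)


class RestrictResult(NamedTuple):
    matrix: ExpressionMatrix
    n_dropped: int


def restrict_probes(expr: ExpressionMatrix, platform_probes: Iterable[str]) -> RestrictResult:
    """Keep only probes present on the reference platform (original column
    order preserved); reports how many were dropped."""
    platform = set(platform_probes)
    if not platform:
        raise ValidationError("platform probe set is empty")
    keep = [p for p in expr.gene_ids if p in platform]
    dropped = expr.n_genes - len(keep)
    if not keep:
        raise ValidationError("no probes in common with the platform")
    if dropped:
        logger.info("restrict_probes: dropped %d probes off-platform", dropped)
    return RestrictResult(ExpressionMatrix(expr.data[keep]), dropped)


def collapse_to_genes(expr: ExpressionMatrix, probe_map: ProbeMap) -> ExpressionMatrix:
    """Collapse a probe-level matrix to genes via each gene's single chosen
    probe (no averaging: every output value exists in the input).

    Genes whose chosen probe is absent from the matrix are omitted with a
    logged warning.
    """
    chosen = probe_map.chosen_probes()
    present = chosen[chosen.isin(expr.gene_ids)]
    missing = len(chosen) - len(present)
    if len(present) == 0:
        raise ValidationError("no chosen probe from the map is present in the matrix")
    if missing:
        logger.warning(
            "collapse_to_genes: %d gene(s) omitted, chosen probe absent", missing
        )
    collapsed = expr.data[present.to_numpy()].copy()
    collapsed.columns = present.index
    return ExpressionMatrix(collapsed)


@dataclass(frozen=True)
class ArrayQCMetrics:
    """Per-array quality metrics; any field may be unavailable (None)."""

    sample_id: str
    background: Optional[float] = None
    noise: Optional[float] = None
    percent_present: Optional[float] = None
    bioBCD_ok: Optional[bool] = None
    gapdh_35_ratio: Optional[float] = None
    actb_35_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("background", "noise"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0 for {self.sample_id!r}")
        if self.percent_present is not None and not (0 <= self.percent_present <= 100):
            raise ValidationError(
                f"percent_present out of [0,100] for {self.sample_id!r}"
            )
        for name in ("gapdh_35_ratio", "actb_35_ratio"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{name} must be > 0 for {self.sample_id!r}")


@dataclass(frozen=True)
class QCThresholds:
    """QC cutoffs.  The housekeeping 3'/5' ratio and present-call defaults
    follow common microarray practice; background/noise checks are only
    applied when a threshold is supplied."""

    max_background: Optional[float] = None
    max_noise: Optional[float] = None
    min_percent_present: float = 25.0
    max_35_ratio: float = 3.0
    require_bioBCD: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.min_percent_present <= 100):
            raise ValidationError("min_percent_present must be in [0,100]")


def qc_flag(
    metrics: Sequence[ArrayQCMetrics], thresholds: QCThresholds = QCThresholds()
) -> pd.DataFrame:
    """Classify each array as pass / fail / unevaluable.

    fail: any non-null metric violates its threshold (reasons listed);
    unevaluable: nothing violates, but >= 1 required metric is null;
    pass: all required metrics present and within thresholds.
    """
    ids = [m.sample_id for m in metrics]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample ids in QC metrics")
    th = thresholds
    checks = []  # (metric name, extractor, violation predicate, required?)
    if th.max_background is not None:
        checks.append(("background", lambda m: m.background,
                       lambda v: v > th.max_background, True))
    if th.max_noise is not None:
        checks.append(("noise", lambda m: m.noise, lambda v: v > th.max_noise, True))
    checks.append(("percent_present", lambda m: m.percent_present,
                   lambda v: v < th.min_percent_present, True))
    checks.append(("gapdh_35_ratio", lambda m: m.gapdh_35_ratio,
                   lambda v: v > th.max_35_ratio, True))
    checks.append(("actb_35_ratio", lambda m: m.actb_35_ratio,
                   lambda v: v > th.max_35_ratio, True))
    checks.append(("bioBCD", lambda m: m.bioBCD_ok,
                   lambda v: not v, th.require_bioBCD))
    rows = []
    for m in metrics:
        reasons = []
        missing_required = False
        for name, get, violates, required in checks:
            value = get(m)
            if value is None:
                if required:
                    missing_required = True
                continue
            if violates(value):
                reasons.append(name)
        if reasons:
            status = "fail"
        elif missing_required:
            status = "unevaluable"
        else:
            status = "pass"
        rows.append({"sample_id": m.sample_id, "status": status,
                     "reasons": ";".join(reasons)})
    return pd.DataFrame(rows)


def read_qc_metrics(path) -> list[ArrayQCMetrics]:
    """TSV with the ArrayQCMetrics columns; blank cells become None."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        def opt(col, cast=float):
            if col not in df.columns or pd.isna(row[col]):
                return None
            if cast is bool:
                return str(row[col]).strip().lower() in ("1", "true", "yes")
            return cast(row[col])

        out.append(
            ArrayQCMetrics(
                sample_id=str(row["sample_id"]),
                background=opt("background"),
                noise=opt("noise"),
                percent_present=opt("percent_present"),
                bioBCD_ok=opt("bioBCD_ok", bool),
                gapdh_35_ratio=opt("gapdh_35_ratio"),
                actb_35_ratio=opt("actb_35_ratio"),
            )
        )
    return out
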