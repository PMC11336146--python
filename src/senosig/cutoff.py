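"""Quartile-bounded exhaustive cutoff scan with FDR correction.

Every distinct observed signature score between the lower and upper
quartiles is tried as a dichotomization threshold; each candidate split is
tested (Cox Wald by default, log-rank optionally), the per-cutoff p-values
are Benjamini-Hochberg adjusted across the scan, and the cutoff minimizing
the raw p-value is selected.  Scanning observed values is exhaustive: the
test statistic only changes when the split itself changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io import ValidationError
from .survival import (
    DegenerateDataError,
    SurvivalData,
    _RiskSetIndex,
    cox_fit,
    logrank_test,
)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to adjust")
    if (p <= 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class CutoffScanResult:
    """Scan table plus the selected (minimum-p) cutoff.

    ``table`` columns: cutoff, hr, p, p_adj, n_low, n_high; groups are
    low = {score <= cutoff}, high = {score > cutoff}, and HR is high vs low
    so HR > 1 means a higher signature carries worse outcome.
    """

    table: pd.DataFrame
    selected_cutoff: float
    selected_hr: float
    selected_p: float
    selected_p_adj: float
    hr_range: tuple[float, float]
    q_bounds: tuple[float, float]
    n: int

    @property
    def cutoffs(self) -> np.ndarray:
        return self.table["cutoff"].to_numpy()

    def high_mask(self, scores) -> np.ndarray:
        return np.asarray(scores, dtype=float) > self.selected_cutoff


def scan_cutoffs(
    scores,
    surv: SurvivalData,
    q_low: float = 0.25,
    q_high: float = 0.75,
    min_group: Optional[int] = None,
    test: str = "cox",
) -> CutoffScanResult:
    """Exhaustively scan observed score values v with Q1 <= v < Q3 as
    dichotomization cutoffs.

    ``min_group`` (default: 10% of n, floor 5) skips cutoffs producing a
    smaller group.  The selected cutoff minimizes the raw p; ties break
    toward the cutoff nearest the median score.
    """
    s = np.asarray(scores, dtype=float)
    if s.shape != surv.time.shape:
        raise ValidationError("scores must align with survival data")
    if not np.isfinite(s).all():
        raise ValidationError("scores must be finite")
    if np.unique(s).size < 4:
        raise DegenerateDataError("need >= 4 distinct score values to scan")
    if test not in ("cox", "logrank"):
        raise ValueError(f"unknown test {test!r}")
    n = s.size
    if min_group is None:
        min_group = max(5, int(np.floor(0.10 * n)))
    q1, q3 = np.quantile(s, [q_low, q_high])  # linear-interpolation quartiles
    candidates = np.unique(s)
    candidates = candidates[(candidates >= q1) & (candidates < q3)]
    index = _RiskSetIndex(surv)  # shared risk sets across all cutoffs
    rows = []
    for v in candidates:
        high = s > v
        n_high = int(high.sum())
        n_low = n - n_high
        if min(n_low, n_high) < min_group:
            continue
        x = high.astype(float)
        try:
            cox = cox_fit(x.reshape(-1, 1), surv, names=["high"], _index=index)[0]
        except DegenerateDataError:
            continue
        if test == "logrank":
            # rank test is well defined even where the Wald fit degenerates
            p = logrank_test(high.astype(int), surv).p
        else:
            if not cox.converged:
                continue
            p = cox.p
        rows.append(
            {"cutoff": float(v), "hr": cox.hr, "p": p,
             "n_low": n_low, "n_high": n_high}
        )
    if not rows:
        raise DegenerateDataError(
            "no admissible cutoff between the quartiles "
            f"(min_group={min_group}, candidates={candidates.size})"
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = fdr_adjust(table["p"].to_numpy())
    table = table[["cutoff", "hr", "p", "p_adj", "n_low", "n_high"]]
    # minimum p; break ties toward the cutoff nearest the median score
    p_min = table["p"].min()
    tied = table[table["p"] == p_min]
    median = float(np.median(s))
    best = tied.iloc[int(np.argmin(np.abs(tied["cutoff"].to_numpy() - median)))]
    return CutoffScanResult(
        table=table,
        selected_cutoff=float(best["cutoff"]),
        selected_hr=float(best["hr"]),
        selected_p=float(best["p"]),
        selected_p_adj=float(best["p_adj"]),
        hr_range=(float(table["hr"].min()), float(table["hr"].max())),
        q_bounds=(float(q1), float(q3)),
        n=n,
    )


def scan_profile(result: CutoffScanResult) -> pd.DataFrame:
    """Significance-vs-cutoff table backing the scan profile plot: one row
    per scanned cutoff with -log10(p) and HR, the selected row flagged."""
    table = result.table
    profile = pd.DataFrame(
        {
            "cutoff": table["cutoff"],
            "neg_log10_p": -np.log10(table["p"]),
            "hr": table["hr"],
            "selected": table["cutoff"] == result.selected_cutoff,
        }
    )
    if int(profile["selected"].sum()) != 1:
        raise AssertionError("exactly one selected cutoff expected")
    return profile
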