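"""Survival primitives: Kaplan-Meier, two-group log-rank, Cox PH.

All three are implemented directly on numpy arrays so that the cutoff scan
and simulation-based checks, which need thousands of small fits, stay fast.

Conventions
-----------
* Risk set at time t is ``{i : time_i >= t}``; at tied times events precede
  censorings, so subjects censored at an event time are still at risk for
  that event.
* Tied event times use the Efron approximation of the partial likelihood.
* Confidence intervals are Wald on the log-hazard scale with z = 1.959964;
  Kaplan-Meier bands use Greenwood's variance on the survival scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

Z95 = 1.959964


class DegenerateDataError(ValueError):
    """Input cannot support the requested estimate (no events, empty group,
    constant covariate)."""


@dataclass(frozen=True)
class SurvivalData:
    """Right-censored follow-up: time in months (> 0) and event in {0, 1}."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        if time.shape != event.shape or time.ndim != 1:
            raise ValueError("time and event must be equal-length 1-d arrays")
        if time.size < 2:
            raise DegenerateDataError("need at least 2 subjects")
        if not np.isfinite(time).all() or (time <= 0).any():
            raise ValueError("times must be finite and strictly positive")
        if not np.isin(event, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(int))

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    @classmethod
    def from_clinical(cls, clin) -> "SurvivalData":
        return cls(clin.time, clin.event)


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    ci_lower: Optional[np.ndarray] = None
    ci_upper: Optional[np.ndarray] = None

    def survival_at(self, t: float) -> float:
        """S(t): step function, right-continuous, S = 1 before first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(surv: SurvivalData, ci: bool = True, alpha: float = 0.05) -> KMCurve:
    """Kaplan-Meier product-limit estimator with Greenwood CI bands."""
    if surv.n_events == 0:
        # fully censored cohort: S identically 1, no event times
        empty = np.array([])
        return KMCurve(empty, empty, empty.astype(int), empty.astype(int),
                       empty if ci else None, empty if ci else None)
    time, event = surv.time, surv.event
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    e_sorted = event[order]
    starts = np.flatnonzero(np.r_[True, t_sorted[1:] != t_sorted[:-1]])
    d = np.add.reduceat(e_sorted, starts)
    has_event = d > 0
    event_times = t_sorted[starts][has_event]
    d = d[has_event]
    n_at_risk = (surv.n - starts)[has_event]
    frac = 1.0 - d / n_at_risk
    survival = np.cumprod(frac)
    ci_lo = ci_hi = None
    if ci:
        with np.errstate(divide="ignore", invalid="ignore"):
            greenwood = np.cumsum(d / (n_at_risk * (n_at_risk - d)))
            se = survival * np.sqrt(greenwood)
        se[~np.isfinite(se)] = 0.0  # S = 0 endpoint: band collapses
        z = stats.norm.ppf(1 - alpha / 2)
        ci_lo = np.clip(survival - z * se, 0.0, 1.0)
        ci_hi = np.clip(survival + z * se, 0.0, 1.0)
    return KMCurve(event_times, survival, n_at_risk.astype(int), d.astype(int),
                   ci_lo, ci_hi)


@dataclass(frozen=True)
class LogrankResult:
    chi_square: float
    p: float
    observed: np.ndarray  # observed events per group (group0, group1)
    expected: np.ndarray


def logrank_test(groups: Sequence[int], surv: SurvivalData) -> LogrankResult:
    """Two-group log-rank test (1 df, chi-square upper tail)."""
    g = np.asarray(groups)
    if not np.isin(g, (0, 1)).all():
        raise ValueError("group labels must be binary 0/1")
    if g.shape != surv.time.shape:
        raise ValueError("groups must align with survival data")
    if g.sum() == 0 or g.sum() == g.size:
        raise DegenerateDataError("both groups must be non-empty")
    if surv.n_events == 0:
        raise DegenerateDataError("log-rank test requires at least one event")
    time, event = surv.time, surv.event
    t_sorted = np.sort(time)
    t1_sorted = np.sort(time[g == 1])
    ut = np.unique(time[event == 1])
    n_at = time.size - np.searchsorted(t_sorted, ut, side="left")
    n1_at = t1_sorted.size - np.searchsorted(t1_sorted, ut, side="left")
    # events per unique event time, total and in group 1
    d = np.array([np.sum((time == t) & (event == 1)) for t in ut], dtype=float)
    d1 = np.array(
        [np.sum((time == t) & (event == 1) & (g == 1)) for t in ut], dtype=float
    )
    frac1 = n1_at / n_at
    e1 = d * frac1
    with np.errstate(divide="ignore", invalid="ignore"):
        v = d * frac1 * (1 - frac1) * (n_at - d) / (n_at - 1)
    v[n_at <= 1] = 0.0
    vsum = v.sum()
    o1, e1sum = d1.sum(), e1.sum()
    if vsum <= 0:
        chi2 = 0.0
    else:
        chi2 = (o1 - e1sum) ** 2 / vsum
    p = float(stats.chi2.sf(chi2, df=1)) if vsum > 0 else 1.0
    observed = np.array([d.sum() - o1, o1])
    expected = np.array([d.sum() - e1sum, e1sum])
    return LogrankResult(float(chi2), p, observed, expected)


@dataclass(frozen=True)
class CoxResult:
    """One covariate's term from a (possibly multivariate) Cox PH fit."""

    term: str
    beta: float
    se: float
    hr: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    events: int
    converged: bool = True
    message: Optional[str] = None

    def format_p(self) -> str:
        """p to 2 significant digits in scientific style, e.g. '6.4e-16'."""
        return f"{self.p:.1e}" if self.p < 1e-3 else f"{self.p:.3f}"


class _RiskSetIndex:
    """Sorted-time bookkeeping shared by every Cox fit on the same outcome.

    Precomputing this once lets the cutoff scan fit hundreds of candidate
    dichotomizations against identical risk sets cheaply.
    """

    def __init__(self, surv: SurvivalData):
        if surv.n_events == 0:
            raise DegenerateDataError("Cox fit requires at least one event")
        self.surv = surv
        order = np.argsort(surv.time, kind="stable")
        self.order = order
        self.t_sorted = surv.time[order]
        self.e_sorted = surv.event[order].astype(float)
        self.starts = np.flatnonzero(
            np.r_[True, self.t_sorted[1:] != self.t_sorted[:-1]]
        )
        d_all = np.add.reduceat(self.e_sorted, self.starts)
        self.has_event = d_all > 0
        self.d = d_all[self.has_event]  # events per event time (float)
        self.estarts = self.starts[self.has_event]
        d_int = self.d.astype(int)
        total = int(d_int.sum())
        offsets = np.repeat(np.cumsum(d_int) - d_int, d_int)
        self.rep = np.repeat(np.arange(d_int.size), d_int)
        self.l_over_d = (np.arange(total) - offsets) / self.d[self.rep]
        self.n = surv.n
        self.n_events = total


def _revcumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def _efron_loglik_grad_info(idx: _RiskSetIndex, Xs: np.ndarray, beta: np.ndarray):
    """Efron partial log-likelihood, gradient and observed information.

    ``Xs`` is the covariate matrix already permuted into ``idx.order``.
    The linear predictor is shifted by its maximum for overflow safety;
    the shift cancels exactly in all three returned quantities.
    """
    e = idx.e_sorted
    eta = Xs @ beta
    eta_s = eta - eta.max()
    r = np.exp(eta_s)
    rx = r[:, None] * Xs
    rxx = rx[:, :, None] * Xs[:, None, :]
    S0 = _revcumsum(r)
    S1 = _revcumsum(rx)
    S2 = _revcumsum(rxx)
    er = r * e
    D0 = np.add.reduceat(er, idx.starts)[idx.has_event]
    D1 = np.add.reduceat(er[:, None] * Xs, idx.starts, axis=0)[idx.has_event]
    D2 = np.add.reduceat(e[:, None, None] * rxx, idx.starts, axis=0)[idx.has_event]
    rep, w = idx.rep, idx.l_over_d
    A0 = S0[idx.estarts][rep] - w * D0[rep]
    A1 = S1[idx.estarts][rep] - w[:, None] * D1[rep]
    A2 = S2[idx.estarts][rep] - w[:, None, None] * D2[rep]
    loglik = float((e * eta_s).sum() - np.log(A0).sum())
    sx = (e[:, None] * Xs).sum(axis=0)
    grad = sx - (A1 / A0[:, None]).sum(axis=0)
    info = (A2 / A0[:, None, None]).sum(axis=0) - np.einsum(
        "ti,tj,t->ij", A1, A1, 1.0 / A0**2
    )
    return loglik, grad, info


def _newton_cox(
    idx: _RiskSetIndex, Xs: np.ndarray, tol: float = 1e-8, max_iter: int = 100
):
    p = Xs.shape[1]
    beta = np.zeros(p)
    loglik, grad, info = _efron_loglik_grad_info(idx, Xs, beta)
    converged = False
    message = None
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        scale = 1.0
        for _h in range(30):
            candidate = beta + scale * step
            new = _efron_loglik_grad_info(idx, Xs, candidate)
            if np.isfinite(new[0]) and new[0] >= loglik - 1e-12:
                break
            scale /= 2.0
        else:
            message = "step-halving failed (monotone likelihood?)"
            break
        delta = new[0] - loglik
        beta, (loglik, grad, info) = candidate, new
        if abs(delta) <= tol * (abs(loglik) + 1.0):
            converged = True
            break
    if not converged and message is None:
        message = f"no convergence in {max_iter} iterations"
    if converged and np.abs(beta).max() > 15:
        # likelihood plateau at an extreme coefficient: monotone partial
        # likelihood (perfect separation), Wald inference is meaningless
        converged = False
        message = "monotone likelihood suspected (|beta| > 15)"
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        converged = False
        message = message or "singular information matrix at optimum"
    return beta, se, loglik, converged, message


def cox_fit(
    covariates: np.ndarray | Sequence[Sequence[float]],
    surv: SurvivalData,
    names: Optional[Sequence[str]] = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    _index: Optional[_RiskSetIndex] = None,
) -> list[CoxResult]:
    """Fit a Cox proportional-hazards model; one :class:`CoxResult` per
    covariate column, all from the joint fit.

    Non-convergence (e.g. monotone partial likelihood under perfect
    separation) yields flagged results (``converged=False``) rather than an
    exception; structurally degenerate inputs (constant covariate, zero
    events) raise :class:`DegenerateDataError`.
    """
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] == surv.n and X.shape[1] != surv.n:
        pass
    elif X.shape[1] == surv.n:
        X = X.T
    if X.shape[0] != surv.n:
        raise ValueError("covariates must align with survival data")
    if not np.isfinite(X).all():
        raise ValueError("covariates must be finite")
    names = list(names) if names is not None else [f"x{k}" for k in range(X.shape[1])]
    for k in range(X.shape[1]):
        if np.ptp(X[:, k]) == 0:
            raise DegenerateDataError(f"constant covariate {names[k]!r}")
    idx = _index if _index is not None else _RiskSetIndex(surv)
    Xs = X[idx.order]
    beta, se, loglik, converged, message = _newton_cox(idx, Xs, tol, max_iter)
    results = []
    for k in range(X.shape[1]):
        b, s = float(beta[k]), float(se[k])
        with np.errstate(over="ignore"):
            hr = float(np.exp(b))
            ci_low = float(np.exp(b - Z95 * s))
            ci_high = float(np.exp(b + Z95 * s))
        p = float(2.0 * stats.norm.sf(abs(b) / s)) if s > 0 else float("nan")
        p = min(max(p, np.nextafter(0, 1)), 1.0) if np.isfinite(p) else p
        results.append(
            CoxResult(names[k], b, s, hr, ci_low, ci_high, p,
                      n=surv.n, events=surv.n_events,
                      converged=converged, message=message)
        )
    return results


def cox_fit_single(
    covariate: Sequence[float],
    surv: SurvivalData,
    name: str = "x",
    **kwargs,
) -> CoxResult:
    """Univariate convenience wrapper around :func:`cox_fit`."""
    x = np.asarray(covariate, dtype=float).reshape(-1, 1)
    return cox_fit(x, surv, names=[name], **kwargs)[0]


def cox_results_frame(results: Sequence[CoxResult]):
    """Serialize Cox terms to the tabular shape used in reports."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "term": r.term,
                "hr": r.hr,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "n": r.n,
                "events": r.events,
            }
            for r in results
        ]
    )
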