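"""Survival primitives against hand calculations, brute-force oracles and
lifelines as an independent implementation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from senosig.survival import (
    DegenerateDataError,
    SurvivalData,
    cox_fit,
    cox_fit_single,
    km_estimate,
    logrank_test,
)


def surv(time, event):
    return SurvivalData(np.asarray(time, float), np.asarray(event))


# ---------------------------------------------------------------- Kaplan-Meier
def test_km_hand_product_limit():
    km = km_estimate(surv([1, 2, 3], [1, 0, 1]))
    # t=1: 3 at risk, 1 event -> 2/3; t=3: 1 at risk, 1 event -> 0
    assert np.allclose(km.event_times, [1, 3])
    assert np.allclose(km.survival, [2 / 3, 0.0])
    assert list(km.at_risk) == [3, 1]


def test_km_single_event_drops_to_zero():
    km = km_estimate(surv([5.0, 5.0], [1, 1]))
    assert km.survival_at(5.0) == 0.0


def test_km_all_censored_is_unity():
    km = km_estimate(surv([1, 2, 3], [0, 0, 0]))
    assert km.event_times.size == 0
    assert km.survival_at(99.0) == 1.0


def test_km_equals_one_minus_ecdf_without_censoring():
    rng = np.random.default_rng(5)
    t = rng.exponential(1.0, size=200) + 1e-9
    km = km_estimate(surv(t, np.ones_like(t)))
    for q in [np.quantile(t, x) for x in (0.1, 0.5, 0.9)]:
        assert km.survival_at(q) == pytest.approx(np.mean(t > q), abs=1e-12)


def test_km_matches_lifelines_with_ties_and_censoring():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(7)
    t = np.round(rng.exponential(10, size=300), 0) + 1.0
    e = rng.integers(0, 2, size=300)
    km = km_estimate(surv(t, e))
    kmf = lifelines.KaplanMeierFitter().fit(t, e)
    theirs = kmf.survival_function_["KM_estimate"]
    diffs = [abs(km.survival_at(u) - float(theirs.loc[u])) for u in km.event_times]
    assert max(diffs) < 1e-12


# -------------------------------------------------------------------- log-rank
def test_logrank_identical_groups_is_null():
    t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
    e = [1, 0, 1, 1, 0, 1]
    res = logrank_test([0, 0, 0, 1, 1, 1], surv(t, e))
    assert res.chi_square == pytest.approx(0.0, abs=1e-12)
    assert res.p == pytest.approx(1.0)


def brute_force_logrank(groups, time, event):
    """Literal O-E/V accumulation over every distinct event time."""
    o1 = e1 = v = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n, n1 = at_risk.sum(), (at_risk & (groups == 1)).sum()
        d = ((time == t) & (event == 1)).sum()
        d1 = ((time == t) & (event == 1) & (groups == 1)).sum()
        o1 += d1
        e1 += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = (o1 - e1) ** 2 / v
    return chi2, float(stats.chi2.sf(chi2, 1))


def test_logrank_matches_brute_force_four_subjects():
    time = np.array([1.0, 2.0, 3.0, 4.0])
    event = np.array([1, 1, 1, 1])
    groups = np.array([1, 1, 0, 0])
    res = logrank_test(groups, surv(time, event))
    chi2, p = brute_force_logrank(groups, time, event)
    assert res.chi_square == pytest.approx(chi2, abs=1e-12)
    assert res.p == pytest.approx(p, abs=1e-12)


def test_logrank_matches_lifelines():
    lifelines = pytest.importorskip("lifelines.statistics")
    rng = np.random.default_rng(11)
    t = np.round(rng.exponential(5, 120), 1) + 0.1
    e = rng.integers(0, 2, 120)
    g = rng.integers(0, 2, 120)
    res = logrank_test(g, surv(t, e))
    theirs = lifelines.logrank_test(t[g == 0], t[g == 1], e[g == 0], e[g == 1])
    assert res.chi_square == pytest.approx(theirs.test_statistic, rel=1e-9)
    assert res.p == pytest.approx(theirs.p_value, rel=1e-9)


def test_logrank_requires_events_and_two_groups():
    with pytest.raises(DegenerateDataError):
        logrank_test([0, 0, 1, 1], surv([1, 2, 3, 4], [0, 0, 0, 0]))
    with pytest.raises(DegenerateDataError):
        logrank_test([0, 0, 0, 0], surv([1, 2, 3, 4], [1, 1, 0, 0]))


def test_logrank_p_uniform_under_null():
    """Null p-values over 1000 two-group exponential simulations (n=60)
    should be uniform to Kolmogorov distance < 0.05."""
    rng = np.random.default_rng(17)
    ps = []
    for _ in range(1000):
        t = rng.exponential(1.0, 60) + 1e-9
        g = np.r_[np.zeros(30, int), np.ones(30, int)]
        ps.append(logrank_test(g, surv(t, np.ones(60, int))).p)
    ks = np.max(np.abs(np.sort(ps) - (np.arange(1, 1001) / 1000)))
    assert ks < 0.05


# ------------------------------------------------------------------------- Cox
def grid_search_beta(x, time, event, lo=-5.0, hi=5.0, step=1e-4):
    """Independent oracle: argmax of the explicitly enumerated Cox partial
    likelihood on a dense parameter grid (no ties)."""
    x, time, event = map(np.asarray, (x, time, event))
    betas = np.arange(lo, hi + step, step)
    ll = np.zeros_like(betas)
    for i in np.flatnonzero(event == 1):
        risk = time >= time[i]
        ll += betas * x[i] - np.log(np.exp(betas[:, None] * x[risk]).sum(axis=1))
    return betas[np.argmax(ll)]


def test_cox_beta_matches_grid_search_on_tiny_fixture():
    time = np.array([2.0, 5.0, 1.0, 7.0, 3.0, 9.0])
    event = np.array([1, 1, 1, 0, 1, 1])
    x = np.array([0.2, 1.0, 0.6, 0.1, 0.9, 0.4])
    res = cox_fit_single(x, surv(time, event))
    oracle = grid_search_beta(x, time, event)
    assert res.converged
    assert res.beta == pytest.approx(oracle, abs=1e-3)


def test_cox_matches_lifelines_with_ties():
    lifelines = pytest.importorskip("lifelines")
    rng = np.random.default_rng(3)
    n = 250
    x1 = rng.normal(size=n)
    x2 = rng.integers(0, 2, n).astype(float)
    t = np.round(rng.exponential(1 / np.exp(0.6 * x1 - 0.4 * x2)), 1) + 0.1
    c = rng.uniform(0, 3, n)
    e = (t <= c).astype(int)
    obs = np.minimum(t, c)
    ours = cox_fit(np.column_stack([x1, x2]), surv(obs, e), names=["x1", "x2"])
    cph = lifelines.CoxPHFitter().fit(
        pd.DataFrame({"T": obs, "E": e, "x1": x1, "x2": x2}), "T", "E"
    )
    for r in ours:
        assert r.beta == pytest.approx(cph.params_[r.term], abs=1e-5)
        assert r.se == pytest.approx(cph.standard_errors_[r.term], abs=1e-5)


def test_cox_result_invariants():
    rng = np.random.default_rng(9)
    x = rng.normal(size=100)
    t = rng.exponential(1 / np.exp(0.5 * x))
    res = cox_fit_single(x, surv(t, np.ones(100, int)))
    assert res.hr == pytest.approx(np.exp(res.beta))
    assert res.ci_low <= res.hr <= res.ci_high
    assert res.ci_low == pytest.approx(np.exp(res.beta - 1.959964 * res.se))
    assert 0 < res.p <= 1


def test_cox_affine_rescaling_of_covariate():
    """beta scales inversely with the covariate scale; the sign (and the
    dichotomized-group HR) is unchanged by positive affine maps."""
    rng = np.random.default_rng(21)
    x = rng.normal(size=150)
    t = rng.exponential(1 / np.exp(0.4 * x))
    s = surv(t, np.ones(150, int))
    base = cox_fit_single(x, s)
    scaled = cox_fit_single(3.0 + 2.0 * x, s)
    assert scaled.beta == pytest.approx(base.beta / 2.0, rel=1e-6)
    assert np.sign(scaled.beta) == np.sign(base.beta)


def test_cox_constant_covariate_rejected():
    with pytest.raises(DegenerateDataError):
        cox_fit_single(np.ones(5), surv([1, 2, 3, 4, 5], [1, 1, 0, 1, 0]))


def test_cox_perfect_separation_flagged_not_crashed():
    # covariate perfectly ordered with event times: monotone likelihood
    time = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
    x = -time  # larger x -> earlier death, beta -> +inf
    res = cox_fit_single(x, surv(time, np.ones(6, int)))
    assert not res.converged
    assert res.message


def test_cox_and_logrank_agree_on_two_groups():
    rng = np.random.default_rng(31)
    g = np.r_[np.zeros(100, int), np.ones(100, int)]
    t = rng.exponential(1 / np.exp(0.8 * g))
    s = surv(t, np.ones(200, int))
    cox = cox_fit_single(g.astype(float), s)
    lr = logrank_test(g, s)
    assert np.sign(cox.beta) > 0 and lr.observed[1] > lr.expected[1]
    assert abs(np.log10(cox.p) - np.log10(lr.p)) < 0.5
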