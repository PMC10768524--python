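"""Survival estimators against hand calculations and independent oracles.

Each estimator is checked two ways: against a frozen hand computation or
brute-force enumeration on a toy, and against an established library
(lifelines / scikit-survival / scikit-learn) on larger samples.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ildgapm import (
    ConvergenceError,
    bootstrap_normal_ci,
    cox_fit_univariate,
    harrell_c,
    km_estimate,
    logrank_test,
    td_auc_ipcw,
)

# --- Kaplan-Meier -----------------------------------------------------------


def test_km_all_events_hand_example():
    km = km_estimate([2.0, 4.0, 5.0], [True, True, True])
    np.testing.assert_allclose(km.times, [2, 4, 5])
    np.testing.assert_allclose(km.survival, [2 / 3, 1 / 3, 0.0])
    np.testing.assert_array_equal(km.at_risk, [3, 2, 1])


def test_km_no_events_is_flat():
    km = km_estimate([1.0, 2.0, 3.0], [False, False, False])
    assert len(km.times) == 0
    assert km.survival_at(10.0) == 1.0


def test_km_censor_at_event_time_stays_at_risk():
    # censoring at t=4 is counted in the risk set of the event at t=4
    km = km_estimate([2.0, 4.0, 4.0, 6.0], [True, True, False, True])
    np.testing.assert_allclose(km.survival, [3 / 4, 3 / 4 * 2 / 3, 3 / 4 * 2 / 3 * 0])


def test_km_input_order_invariant():
    times = [3.0, 1.0, 4.0, 2.0, 5.0]
    events = [True, True, False, True, True]
    ref = km_estimate(times, events)
    for perm in itertools.permutations(range(5)):
        km = km_estimate([times[i] for i in perm], [events[i] for i in perm])
        np.testing.assert_allclose(km.times, ref.times)
        np.testing.assert_allclose(km.survival, ref.survival)


@given(st.lists(st.floats(0.5, 100), min_size=2, max_size=30))
@settings(max_examples=100, deadline=None)
def test_km_without_censoring_is_empirical_survival(times):
    times = np.asarray(times)
    km = km_estimate(times, np.ones(len(times), bool))
    for t in km.times:
        assert km.survival_at(t) == pytest.approx((times > t).mean())


def test_km_matches_lifelines(censored_sample):
    from lifelines import KaplanMeierFitter

    times, events, _ = censored_sample
    km = km_estimate(times, events)
    kmf = KaplanMeierFitter().fit(times, events)
    ref = kmf.survival_function_at_times(km.times).to_numpy()
    np.testing.assert_allclose(km.survival, ref, atol=1e-12)


def test_km_curve_is_monotone_in_unit_interval(censored_sample):
    times, events, _ = censored_sample
    km = km_estimate(times, events)
    assert np.all(km.survival <= 1.0) and np.all(km.survival >= 0.0)
    assert np.all(np.diff(km.survival) <= 0)
    assert km.survival_at(0.0) == 1.0


def test_km_rejects_empty_and_nonpositive():
    with pytest.raises(ValueError):
        km_estimate([], [])
    with pytest.raises(ValueError):
        km_estimate([0.0, 1.0], [True, True])


# --- log-rank ----------------------------------------------------------------


def test_logrank_identical_groups_is_null():
    t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
    e = [True, True, False, True, True, False]
    g = ["a", "a", "a", "b", "b", "b"]
    res = logrank_test(t, e, g)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)


def test_logrank_hand_computed_two_group_toy():
    # O-E = 0.6 with total variance 0.74 -> chi-square 18/37
    t = [1.0, 3.0, 5.0, 2.0, 4.0, 6.0]
    e = [True, True, False, True, False, True]
    g = ["A", "A", "A", "B", "B", "B"]
    res = logrank_test(t, e, g)
    assert res.statistic == pytest.approx(18 / 37, rel=1e-12)
    assert res.df == 1


def test_logrank_label_swap_invariance():
    rng = np.random.default_rng(5)
    t = rng.exponential(10, 40) + 0.1
    e = rng.random(40) < 0.7
    g = rng.integers(0, 2, 40)
    a = logrank_test(t, e, g)
    b = logrank_test(t, e, 1 - g)
    assert a.statistic == pytest.approx(b.statistic, rel=1e-12)


def test_logrank_monotone_time_transform_invariance():
    rng = np.random.default_rng(6)
    t = rng.exponential(10, 50) + 0.1
    e = rng.random(50) < 0.6
    g = rng.integers(0, 3, 50)
    a = logrank_test(t, e, g)
    b = logrank_test(np.exp(t / 10), e, g)  # strictly increasing transform
    assert a.statistic == pytest.approx(b.statistic, rel=1e-10)
    assert a.df == b.df == 2


def test_logrank_matches_lifelines_k_groups(censored_sample):
    from lifelines.statistics import multivariate_logrank_test

    times, events, x = censored_sample
    groups = np.digitize(x, [-0.5, 0.5])
    mine = logrank_test(times, events, groups)
    ref = multivariate_logrank_test(times, groups, events)
    assert mine.statistic == pytest.approx(ref.test_statistic, rel=1e-10)
    assert mine.p_value == pytest.approx(ref.p_value, rel=1e-10)


def test_logrank_errors():
    with pytest.raises(ValueError, match="2 groups"):
        logrank_test([1.0, 2.0], [True, True], ["a", "a"])
    with pytest.raises(ValueError, match="no events"):
        logrank_test([1.0, 2.0], [False, False], ["a", "b"])


# --- Harrell's C -------------------------------------------------------------


def _harrell_c_bruteforce(times, events, pred):
    """Independent O(n^2) pure-Python pair enumeration."""
    n = len(times)
    conc = comp = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if times[i] < times[j] and events[i]:
                first = i
            elif times[i] == times[j] and events[i] and not events[j]:
                first = i
            else:
                continue
            later = j
            comp += 1
            if pred[first] > pred[later]:
                conc += 1
            elif pred[first] == pred[later]:
                conc += 0.5
    return conc / comp


def test_c_index_perfect_and_tied():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.ones(4, bool)
    assert harrell_c(t, e, np.array([4.0, 3.0, 2.0, 1.0])) == 1.0
    assert harrell_c(t, e, np.zeros(4)) == 0.5


def test_c_index_matches_bruteforce_with_ties():
    rng = np.random.default_rng(9)
    t = rng.integers(1, 15, 30).astype(float)  # many tied times
    e = rng.random(30) < 0.6
    p = rng.integers(0, 5, 30).astype(float)  # many tied predictions
    assert harrell_c(t, e, p) == pytest.approx(_harrell_c_bruteforce(t, e, p), abs=1e-12)


def test_c_index_matches_lifelines(censored_sample):
    from lifelines.utils import concordance_index

    times, events, x = censored_sample  # continuous times: no ties
    assert harrell_c(times, events, x) == pytest.approx(
        concordance_index(times, -x, events), abs=1e-12
    )


def test_c_index_no_comparable_pairs_errors():
    with pytest.raises(ValueError, match="comparable"):
        harrell_c([5.0, 5.0], [True, True], [1.0, 2.0])


# --- IPCW time-dependent AUC --------------------------------------------------


def test_td_auc_hand_worked_ipcw_toy():
    """8 subjects, one censored before the horizon.

    Censoring KM: G=5/6 after t=4.  Cases at t=5,7 get weight 6/5, the
    three controls weight 6/5 each; the weighted Mann-Whitney sum gives
    AUC = 16/33.
    """
    t = np.array([2.0, 4.0, 5.0, 12.0, 11.0, 7.0, 13.0, 3.0])
    e = np.array([1, 0, 1, 0, 0, 1, 0, 1], bool)
    p = np.array([5.0, 4.0, 3.0, 6.0, 1.0, 2.0, 7.0, 8.0])
    res = td_auc_ipcw(t, e, p, horizon=10.0, n_bootstrap=0)
    assert res.auc == pytest.approx(16 / 33, rel=1e-12)
    assert (res.n_cases, res.n_controls) == (4, 3)


def test_td_auc_no_censoring_reduces_to_binary_auc():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(21)
    n = 200
    p = rng.normal(size=n)
    t = rng.exponential(50 * np.exp(-p)) + 0.1
    e = np.ones(n, bool)
    tau = float(np.median(t))
    res = td_auc_ipcw(t, e, p, horizon=tau, n_bootstrap=0)
    assert res.auc == pytest.approx(roc_auc_score(t <= tau, p), abs=1e-12)


def test_td_auc_matches_scikit_survival_uno(censored_sample):
    from sksurv.metrics import cumulative_dynamic_auc

    times, events, x = censored_sample
    tau = 700.0
    mine = td_auc_ipcw(times, events, x, horizon=tau, n_bootstrap=0)
    y = np.empty(len(times), dtype=[("e", "?"), ("t", "<f8")])
    y["e"], y["t"] = events, times
    ref, _ = cumulative_dynamic_auc(y, y, x, [tau])
    assert mine.auc == pytest.approx(ref[0], abs=1e-10)


def test_td_auc_null_predictor_near_half():
    rng = np.random.default_rng(4)
    n = 5000
    t = rng.exponential(500, n) + 0.1
    e = rng.random(n) < 0.8
    p = rng.normal(size=n)  # independent of outcome
    res = td_auc_ipcw(t, e, p, horizon=400.0, n_bootstrap=200, seed=0)
    assert abs(res.auc - 0.5) < 3 * res.se


def test_td_auc_bootstrap_reproducible_and_b_scaling(censored_sample):
    times, events, x = censored_sample
    a = td_auc_ipcw(times, events, x, horizon=700.0, n_bootstrap=300, seed=42)
    b = td_auc_ipcw(times, events, x, horizon=700.0, n_bootstrap=300, seed=42)
    assert (a.auc, a.se, a.ci) == (b.auc, b.se, b.ci)
    c = td_auc_ipcw(times, events, x, horizon=700.0, n_bootstrap=301, seed=42)
    assert c.se != a.se  # different resamples actually used
    assert a.ci[0] < a.auc < a.ci[1]


def test_td_auc_degenerate_inputs_error():
    t = np.array([1.0, 2.0, 3.0])
    with pytest.raises(ValueError, match="no cases"):
        td_auc_ipcw(t, np.zeros(3, bool), t, horizon=10.0, n_bootstrap=0)
    with pytest.raises(ValueError, match="no controls"):
        td_auc_ipcw(t, np.ones(3, bool), t, horizon=10.0, n_bootstrap=0)


def test_td_auc_ipcw_weights_increase_auc_under_informative_censoring():
    # censoring concentrated among high-risk subjects before the horizon:
    # the IPCW estimate must differ from the naive binary AUC that treats
    # censored subjects as controls
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(33)
    n = 400
    p = rng.normal(size=n)
    t = rng.exponential(300 * np.exp(-0.8 * p)) + 0.1
    c = np.where(p > 0, rng.exponential(150, n), np.inf) + 0.1
    times = np.minimum(t, c)
    events = t <= c
    tau = 250.0
    res = td_auc_ipcw(times, events, p, horizon=tau, n_bootstrap=0)
    naive = roc_auc_score(
        (times <= tau) & events, p
    )  # censored-before-tau treated as controls
    assert res.auc != pytest.approx(naive, abs=1e-6)


# --- Cox ---------------------------------------------------------------------


def _cox_logpl_efron_reference(beta, times, events, x):
    """Slow, direct Efron log partial likelihood for the grid-search oracle."""
    logpl = 0.0
    for tv in np.unique(times[events]):
        tied = events & (times == tv)
        risk = times >= tv
        d = tied.sum()
        s0 = np.exp(beta * x[risk]).sum()
        t0 = np.exp(beta * x[tied]).sum()
        logpl += beta * x[tied].sum()
        for ell in range(d):
            logpl -= math.log(s0 - ell / d * t0)
    return logpl


def test_cox_beta_matches_grid_search_oracle():
    rng = np.random.default_rng(13)
    n = 20
    x = rng.integers(0, 4, n).astype(float)
    t = np.ceil(rng.exponential(20 * np.exp(-0.4 * x))) + 1  # tied integer times
    e = rng.random(n) < 0.8
    fit = cox_fit_univariate(t, e, x)
    grid = np.arange(-3, 3, 1e-4)
    lls = [_cox_logpl_efron_reference(b, t, e, x) for b in grid]
    beta_grid = grid[int(np.argmax(lls))]
    assert fit.coef == pytest.approx(beta_grid, abs=2e-4)
    assert fit.log_likelihood == pytest.approx(max(lls), abs=1e-6)


@pytest.mark.parametrize("ties", ["efron", "breslow"])
def test_cox_matches_lifelines(censored_sample, ties):
    import pandas as pd
    from lifelines import CoxPHFitter

    times, events, x = censored_sample
    df = pd.DataFrame({"t": times, "e": events.astype(int), "x": x})
    # introduce ties so the tie corrections are actually exercised
    df["t"] = np.ceil(df["t"] / 50.0)
    cph = CoxPHFitter().fit(df, "t", "e")  # lifelines uses Efron
    if ties == "efron":
        fit = cox_fit_univariate(df["t"], events, x, ties="efron")
        assert fit.coef == pytest.approx(cph.params_["x"], rel=1e-5)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], rel=1e-5)
        assert fit.log_likelihood == pytest.approx(cph.log_likelihood_, rel=1e-9)
        assert fit.aic == pytest.approx(cph.AIC_partial_, rel=1e-9)
    else:
        fit = cox_fit_univariate(df["t"], events, x, ties="breslow")
        # Breslow attenuates the estimate on tied data, but only mildly
        assert fit.coef != pytest.approx(cph.params_["x"], rel=1e-8)
        assert fit.coef == pytest.approx(cph.params_["x"], rel=0.10)


def test_cox_null_predictor_recovery():
    rng = np.random.default_rng(17)
    n = 3000
    x = rng.normal(size=n)
    t = rng.exponential(300, n) + 0.1  # no effect of x
    e = rng.random(n) < 0.5
    fit = cox_fit_univariate(t, e, x)
    assert fit.ci_lower < 1.0 < fit.ci_upper
    assert abs(fit.coef) < 3 * fit.se


def test_cox_null_loglik_and_aic_identity(censored_sample):
    times, events, x = censored_sample
    fit = cox_fit_univariate(times, events, x)
    # logPL(0) = -sum over events of log(risk-set size) when no ties
    order = np.argsort(times)
    ts, es = times[order], events[order]
    n = len(ts)
    expected = -sum(math.log(n - i) for i in range(n) if es[i])
    assert fit.log_likelihood_null == pytest.approx(expected, rel=1e-10)
    assert fit.aic == pytest.approx(-2 * fit.log_likelihood + 2, rel=1e-12)
    assert fit.ci_lower <= fit.hazard_ratio <= fit.ci_upper


def test_cox_degenerate_inputs():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    e = np.ones(4, bool)
    with pytest.raises(ValueError, match="constant"):
        cox_fit_univariate(t, e, np.ones(4))
    with pytest.raises(ValueError, match="event"):
        cox_fit_univariate(t, np.zeros(4, bool), np.arange(4.0))
    # predictor perfectly ordered with event times: monotone likelihood
    with pytest.raises(ConvergenceError):
        cox_fit_univariate(t, e, np.array([4.0, 3.0, 2.0, 1.0]))


# --- bootstrap helper ---------------------------------------------------------


def test_bootstrap_ci_reproducible_and_sane(censored_sample):
    times, events, x = censored_sample
    est1, se1, ci1, k1 = bootstrap_normal_ci(
        harrell_c, times, events, x, n_bootstrap=200, seed=7
    )
    est2, se2, ci2, k2 = bootstrap_normal_ci(
        harrell_c, times, events, x, n_bootstrap=200, seed=7
    )
    assert (est1, se1, ci1, k1) == (est2, se2, ci2, k2)
    assert ci1[0] < est1 < ci1[1]
    assert est1 == pytest.approx(harrell_c(times, events, x))
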