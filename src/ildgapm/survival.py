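"""Survival statistics for right-censored cohorts, implemented from scratch.

Provides the estimators used to evaluate prognostic scores against a
3-year composite endpoint:

* Kaplan-Meier product-limit curves (:func:`km_estimate`),
* the k-group log-rank test (:func:`logrank_test`),
* Harrell's concordance index (:func:`harrell_c`),
* cumulative/dynamic time-dependent ROC AUC at a fixed horizon with
  inverse-probability-of-censoring weights (:func:`td_auc_ipcw`),
* univariate Cox proportional-hazards fits by Newton-Raphson with Efron
  (default) or Breslow tie handling (:func:`cox_fit_univariate`),
* bootstrap normal-approximation confidence intervals
  (:func:`bootstrap_normal_ci`).

All functions accept plain arrays (times in days, boolean event flags,
real-valued risk predictors).  Established survival packages are used
only as cross-checking oracles in the test suite, never here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy import stats as _sps

__all__ = [
    "KmCurve",
    "LogrankResult",
    "CoxFit",
    "TdAucResult",
    "ConvergenceError",
    "km_estimate",
    "km_survival_at",
    "logrank_test",
    "harrell_c",
    "td_auc_ipcw",
    "cox_fit_univariate",
    "bootstrap_normal_ci",
]

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Raised when a partial-likelihood maximisation cannot converge."""


def _validate_sample(times, events, predictor=None):
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.ndim != 1 or events.shape != times.shape:
        raise ValueError("times and events must be 1-D arrays of equal length")
    if len(times) == 0:
        raise ValueError("empty sample")
    if np.any(times <= 0) or not np.all(np.isfinite(times)):
        raise ValueError("follow-up times must be positive and finite")
    if predictor is None:
        return times, events
    predictor = np.asarray(predictor, dtype=float)
    if predictor.shape != times.shape:
        raise ValueError("predictor must match times in length")
    if not np.all(np.isfinite(predictor)):
        raise ValueError("predictor contains non-finite values")
    return times, events, predictor


# ---------------------------------------------------------------------------
# Kaplan-Meier


@dataclass
class KmCurve:
    """Product-limit estimate: distinct event times with S(t), risk and event counts."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    n_total: int

    def survival_at(self, t: float) -> float:
        """Right-continuous S(t)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def survival_before(self, t: float) -> float:
        """Left limit S(t-): survival just before time t."""
        idx = np.searchsorted(self.times, t, side="left") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KmCurve:
    """Kaplan-Meier product-limit estimator.

    Tied events at one time decrement survival simultaneously; subjects
    censored at an event time remain at risk for that event (censoring is
    taken to occur just after the event).  The curve is tabulated at the
    distinct event times only.
    """
    times, events = _validate_sample(times, events)
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    uniq, first_idx = np.unique(t_sorted, return_index=True)
    n = len(t_sorted)
    at_risk_all = n - first_idx  # subjects with time >= uniq[i]
    d_all = np.add.reduceat(e_sorted.astype(int), first_idx)
    has_event = d_all > 0
    ts = uniq[has_event]
    d = d_all[has_event]
    r = at_risk_all[has_event]
    surv = np.cumprod(1.0 - d / r)
    return KmCurve(times=ts, survival=surv, at_risk=r, n_events=d, n_total=n)


def km_survival_at(curve: KmCurve, t) -> np.ndarray:
    """Vectorised right-continuous S(t) over an array of times."""
    t = np.asarray(t, dtype=float)
    idx = np.searchsorted(curve.times, t, side="right") - 1
    out = np.ones_like(t, dtype=float)
    mask = idx >= 0
    out[mask] = curve.survival[idx[mask]]
    return out


def _censoring_km(times, events) -> KmCurve:
    """KM estimate of the censoring distribution G(t).

    Censorings play the role of events.  At tied times a true event is
    taken to precede censoring, so subjects with events at t stay in the
    risk set for censorings at t but do not reduce G before t.
    """
    return km_estimate(times, ~np.asarray(events, dtype=bool))


# ---------------------------------------------------------------------------
# Log-rank test


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float
    groups: list = field(default_factory=list)
    observed: np.ndarray = None
    expected: np.ndarray = None


def logrank_test(times, events, groups) -> LogrankResult:
    """k-group log-rank test (observed minus expected, hypergeometric variance).

    Returns the chi-square statistic on k-1 degrees of freedom with its
    upper-tail P value.  Requires at least two non-empty groups and at
    least one event overall.
    """
    times, events = _validate_sample(times, events)
    groups = np.asarray(groups)
    if groups.shape != times.shape:
        raise ValueError("groups must match times in length")
    labels, gidx = np.unique(groups, return_inverse=True)
    k = len(labels)
    if k < 2:
        raise ValueError("log-rank test requires at least 2 groups")
    if not events.any():
        raise ValueError("log-rank test undefined: no events in the sample")

    event_times = np.unique(times[events])
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in event_times:
        at_risk = times >= t
        n = at_risk.sum()
        d = int((events & (times == t)).sum())
        n_g = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_g = np.bincount(gidx[events & (times == t)], minlength=k).astype(float)
        O += d_g
        E += d * n_g / n
        if n > 1:
            frac = n_g / n
            # hypergeometric covariance of the group event counts at t
            V += d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
    z = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    try:
        stat = float(z @ np.linalg.solve(Vsub, z))
    except np.linalg.LinAlgError:
        stat = float(z @ np.linalg.pinv(Vsub) @ z)
    stat = max(stat, 0.0)
    df = k - 1
    p = float(_sps.chi2.sf(stat, df))
    return LogrankResult(
        statistic=stat, df=df, p_value=p, groups=list(labels), observed=O, expected=E
    )


# ---------------------------------------------------------------------------
# Harrell's C


def harrell_c(times, events, predictor) -> float:
    """Harrell's concordance index for a risk predictor.

    A pair is comparable when the subject with the shorter follow-up had
    the event (or, at tied times, exactly one of the pair had the event,
    in which case the event is taken to occur first).  Concordant pairs
    have the higher predictor on the earlier failure; tied predictors
    count one half.
    """
    times, events, predictor = _validate_sample(times, events, predictor)
    t = times[:, None]
    e = events[:, None]
    # "i fails before j": strictly earlier event, or event tied with a censoring
    earlier = ((t < t.T) & e) | ((t == t.T) & e & ~e.T)
    p = predictor[:, None]
    conc = (earlier & (p > p.T)).sum()
    ties = (earlier & (p == p.T)).sum()
    comparable = earlier.sum()
    if comparable == 0:
        raise ValueError("concordance undefined: no comparable pairs")
    return float((conc + 0.5 * ties) / comparable)


# ---------------------------------------------------------------------------
# IPCW time-dependent AUC


@dataclass
class TdAucResult:
    horizon: float
    auc: float
    se: Optional[float] = None
    ci: Optional[tuple] = None
    n_bootstrap: int = 0
    n_cases: int = 0
    n_controls: int = 0


def _ipcw_auc_point(times, events, predictor, horizon, subject_ids=None) -> tuple:
    """Point estimate of the cumulative/dynamic IPCW AUC at the horizon.

    Cases are subjects with an observed event at or before the horizon,
    weighted 1/G(T-); controls are subjects still under observation past
    the horizon, weighted 1/G(horizon), where G is the Kaplan-Meier
    estimate of the censoring survival function.
    """
    case = (times <= horizon) & events
    # controls are known event-free through the horizon; a subject
    # administratively censored exactly at the horizon qualifies
    control = (times > horizon) | ((times == horizon) & ~events)
    if not case.any():
        raise ValueError("no cases (events at or before the horizon)")
    if not control.any():
        raise ValueError("no controls (subjects observed through the horizon)")
    G = _censoring_km(times, events)
    g_case = np.array([G.survival_before(t) for t in times[case]])
    if np.any(g_case <= 0):
        ids = (
            np.flatnonzero(case)[g_case <= 0]
            if subject_ids is None
            else np.asarray(subject_ids)[case][g_case <= 0]
        )
        raise ValueError(
            f"IPCW weight undefined (censoring survival 0) for subject(s) {ids.tolist()}"
        )
    # a control needs censoring time >= horizon: left limit G(horizon-)
    g_tau = G.survival_before(horizon)
    if g_tau <= 0:
        raise ValueError(
            "IPCW weight undefined: censoring survival is 0 at the horizon"
        )
    w_case = 1.0 / g_case
    w_ctrl = np.full(int(control.sum()), 1.0 / g_tau)

    p_case = predictor[case]
    p_ctrl = predictor[control]
    # weighted Mann-Whitney via sorted control predictors
    order = np.argsort(p_ctrl, kind="stable")
    pc_sorted = p_ctrl[order]
    wc_sorted = w_ctrl[order]
    cum = np.concatenate([[0.0], np.cumsum(wc_sorted)])
    lo = np.searchsorted(pc_sorted, p_case, side="left")
    hi = np.searchsorted(pc_sorted, p_case, side="right")
    w_less = cum[lo]
    w_equal = cum[hi] - cum[lo]
    num = float(np.sum(w_case * (w_less + 0.5 * w_equal)))
    den = float(w_case.sum() * w_ctrl.sum())
    return num / den, int(case.sum()), int(control.sum())


def td_auc_ipcw(
    times,
    events,
    predictor,
    horizon: float = 1095.0,
    n_bootstrap: int = 2000,
    seed: Optional[int] = None,
    subject_ids=None,
) -> TdAucResult:
    """Time-dependent (cumulative/dynamic) ROC AUC at a fixed horizon.

    Sensitivity at the horizon is taken over subjects with events by the
    horizon, specificity over subjects event-free and uncensored past it;
    censoring before the horizon is handled by inverse-probability-of-
    censoring weights from the Kaplan-Meier censoring-survival estimate.
    The confidence interval is a normal approximation, estimate +/- 1.96
    bootstrap SEs, from ``n_bootstrap`` subject resamples; resamples where
    the estimate is undefined (no cases or controls) are dropped.  With a
    given ``seed`` the resampling — hence the CI — is reproducible bit for
    bit.  Set ``n_bootstrap=0`` for the point estimate alone.
    """
    times, events, predictor = _validate_sample(times, events, predictor)
    auc, n_cases, n_controls = _ipcw_auc_point(
        times, events, predictor, horizon, subject_ids
    )
    result = TdAucResult(
        horizon=horizon, auc=auc, n_cases=n_cases, n_controls=n_controls
    )
    if n_bootstrap <= 0:
        return result
    n = len(times)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_bootstrap, n))
    boots = np.empty(n_bootstrap)
    valid = 0
    for b in range(n_bootstrap):
        i = idx[b]
        try:
            boots[valid], _, _ = _ipcw_auc_point(
                times[i], events[i], predictor[i], horizon
            )
            valid += 1
        except ValueError:
            continue
    if valid < 2:
        raise ValueError("bootstrap failed: fewer than 2 valid resamples")
    if valid < n_bootstrap:
        logger.warning(
            "td_auc_ipcw: %d of %d bootstrap resamples degenerate, dropped",
            n_bootstrap - valid,
            n_bootstrap,
        )
    se = float(np.std(boots[:valid], ddof=1))
    result.se = se
    result.ci = (auc - 1.96 * se, auc + 1.96 * se)
    result.n_bootstrap = valid
    return result


# ---------------------------------------------------------------------------
# Univariate Cox proportional hazards


@dataclass
class CoxFit:
    """Univariate Cox fit: coefficient, HR with 95% CI, likelihoods, AIC."""

    coef: float
    se: float
    hazard_ratio: float
    ci_lower: float
    ci_upper: float
    p_value: float
    log_likelihood: float
    log_likelihood_null: float
    aic: float
    n: int
    n_events: int
    ties: str = "efron"


def _cox_logpl_grad_hess(beta, x, event_groups, risk_starts, ties):
    """Log partial likelihood, score and information for one covariate.

    ``x`` is sorted by descending time.  ``risk_starts[j]`` marks the risk
    set of the j-th distinct event time as x[:risk_starts[j]] ... actually
    the risk set is x[0:risk_starts[j]] (all subjects with time >= t_j).
    ``event_groups[j]`` indexes the tied events at t_j.
    """
    exb = np.exp(beta * x)
    xexb = x * exb
    x2exb = x * xexb
    cs0 = np.cumsum(exb)
    cs1 = np.cumsum(xexb)
    cs2 = np.cumsum(x2exb)
    logpl = 0.0
    grad = 0.0
    info = 0.0
    for j, ev_idx in enumerate(event_groups):
        m = risk_starts[j]
        s0 = cs0[m - 1]
        s1 = cs1[m - 1]
        s2 = cs2[m - 1]
        d = len(ev_idx)
        xs = x[ev_idx]
        logpl += beta * xs.sum()
        grad += xs.sum()
        if ties == "breslow" or d == 1:
            if ties == "breslow":
                logpl -= d * np.log(s0)
                grad -= d * s1 / s0
                info += d * (s2 / s0 - (s1 / s0) ** 2)
            else:
                logpl -= np.log(s0)
                grad -= s1 / s0
                info += s2 / s0 - (s1 / s0) ** 2
        else:  # Efron correction for d tied events
            t0 = exb[ev_idx].sum()
            t1 = xexb[ev_idx].sum()
            t2 = x2exb[ev_idx].sum()
            ell = np.arange(d) / d
            a0 = s0 - ell * t0
            a1 = s1 - ell * t1
            a2 = s2 - ell * t2
            logpl -= np.sum(np.log(a0))
            grad -= np.sum(a1 / a0)
            info += np.sum(a2 / a0 - (a1 / a0) ** 2)
    return logpl, grad, info


def cox_fit_univariate(times, events, predictor, ties: str = "efron") -> CoxFit:
    """Fit a single-covariate Cox proportional-hazards model.

    Maximises the partial likelihood by Newton-Raphson with step halving,
    starting at beta = 0.  Ties are handled by the Efron approximation by
    default (``ties="breslow"`` for the simpler convention).  The standard
    error comes from the observed information; the 95% CI for the hazard
    ratio is exp(beta +/- 1.96 SE); AIC = -2 logPL(beta) + 2.

    Raises ``ValueError`` for a constant predictor or an event-free sample
    and ``ConvergenceError`` under monotone likelihood (perfect separation
    of event order by the predictor).
    """
    if ties not in ("efron", "breslow"):
        raise ValueError(f"ties must be 'efron' or 'breslow', got {ties!r}")
    times, events, predictor = _validate_sample(times, events, predictor)
    if not events.any():
        raise ValueError("Cox fit requires at least one event")
    sd = predictor.std()
    if sd == 0:
        raise ValueError("Cox fit undefined for a constant predictor")

    # standardise for numerical stability; coefficients mapped back at the end
    mu = predictor.mean()
    z = (predictor - mu) / sd

    order = np.argsort(-times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    z_sorted = z[order]

    event_time_values = np.unique(t_sorted[e_sorted])[::-1]
    event_groups = []
    risk_starts = []
    for tv in event_time_values:
        ev_idx = np.flatnonzero(e_sorted & (t_sorted == tv))
        event_groups.append(ev_idx)
        # risk set: all with time >= tv; times sorted descending
        risk_starts.append(int(np.searchsorted(-t_sorted, -tv, side="right")))

    beta = 0.0
    logpl0, _, _ = _cox_logpl_grad_hess(0.0, z_sorted, event_groups, risk_starts, ties)
    logpl = logpl0
    max_abs_beta = 50.0  # on the standardised scale; beyond this, separation
    for _ in range(100):
        lp, g, info = _cox_logpl_grad_hess(
            beta, z_sorted, event_groups, risk_starts, ties
        )
        if info <= 0 or not np.isfinite(info):
            raise ConvergenceError("singular information matrix in Cox fit")
        step = g / info
        if abs(g) < 1e-10 and abs(step) < 1e-12:
            logpl = lp
            break
        new_beta = beta + step
        new_lp, _, _ = _cox_logpl_grad_hess(
            new_beta, z_sorted, event_groups, risk_starts, ties
        )
        halvings = 0
        while new_lp < lp and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_lp, _, _ = _cox_logpl_grad_hess(
                new_beta, z_sorted, event_groups, risk_starts, ties
            )
            halvings += 1
        if abs(new_beta) > max_abs_beta:
            raise ConvergenceError(
                "monotone partial likelihood: predictor separates event order "
                "(no finite hazard-ratio estimate)"
            )
        converged = abs(new_beta - beta) < 1e-10
        beta, logpl = new_beta, new_lp
        if converged:
            break
    else:
        raise ConvergenceError("Cox Newton-Raphson failed to converge")

    _, _, info = _cox_logpl_grad_hess(beta, z_sorted, event_groups, risk_starts, ties)
    se_z = 1.0 / np.sqrt(info)
    coef = beta / sd
    se = se_z / sd
    zstat = coef / se
    p = float(2.0 * _sps.norm.sf(abs(zstat)))
    with np.errstate(over="ignore"):  # huge SE -> CI bound of inf is legitimate
        hr = float(np.exp(coef))
        ci_lo = float(np.exp(coef - 1.96 * se))
        ci_hi = float(np.exp(coef + 1.96 * se))
    return CoxFit(
        coef=float(coef),
        se=float(se),
        hazard_ratio=hr,
        ci_lower=ci_lo,
        ci_upper=ci_hi,
        p_value=p,
        log_likelihood=float(logpl),
        log_likelihood_null=float(logpl0),
        aic=float(-2.0 * logpl + 2.0),
        n=len(times),
        n_events=int(events.sum()),
        ties=ties,
    )


# ---------------------------------------------------------------------------
# Bootstrap normal-approximation CI


def bootstrap_normal_ci(
    stat_fn: Callable[..., float],
    times,
    events,
    predictor,
    n_bootstrap: int = 2000,
    seed: Optional[int] = None,
) -> tuple:
    """Normal-approximation bootstrap CI for any (times, events, predictor) statistic.

    Resamples subjects with replacement ``n_bootstrap`` times and returns
    ``(estimate, se, (lo, hi), n_valid)`` with the CI as estimate +/- 1.96
    bootstrap SEs.  Resamples where the statistic is undefined are
    dropped.  A fixed seed makes the resampling bit-reproducible; with the
    same seed, sample size and resample count the resample indices are
    identical across calls, so comparisons of two predictors on one
    cohort are paired.
    """
    times, events, predictor = _validate_sample(times, events, predictor)
    est = float(stat_fn(times, events, predictor))
    n = len(times)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_bootstrap, n))
    vals = np.empty(n_bootstrap)
    valid = 0
    for b in range(n_bootstrap):
        i = idx[b]
        try:
            vals[valid] = stat_fn(times[i], events[i], predictor[i])
            valid += 1
        except (ValueError, ConvergenceError):
            continue
    if valid < 2:
        raise ValueError("bootstrap failed: fewer than 2 valid resamples")
    se = float(np.std(vals[:valid], ddof=1))
    return est, se, (est - 1.96 * se, est + 1.96 * se), valid
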