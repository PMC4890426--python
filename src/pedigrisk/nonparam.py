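"""One-sample non-parametric estimators.

Kaplan-Meier survival (all-cause, or the deliberately biased per-cause
variant that treats competing events as censoring), the Aalen-Johansen
cumulative incidence function for competing risks, and the reverse-role
Kaplan-Meier estimate of the censoring distribution used for inverse
probability of censoring weighting (IPCW).

All curves are right-continuous step functions evaluable at arbitrary
times.  Ties between an event and a censoring at the same time are
resolved event-first.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .sample import CRSample

__all__ = [
    "SurvivalCurve",
    "CIFCurve",
    "kaplan_meier",
    "aalen_johansen_cif",
    "censoring_survival",
]


class _StepCurve:
    """Right-continuous step function with pointwise variance and CI."""

    _start_value: float = 1.0

    def __init__(self, times, values, variance=None, ci_lower=None, ci_upper=None,
                 n_risk=None, n_event=None):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.variance = None if variance is None else np.asarray(variance, dtype=float)
        self.ci_lower = None if ci_lower is None else np.asarray(ci_lower, dtype=float)
        self.ci_upper = None if ci_upper is None else np.asarray(ci_upper, dtype=float)
        self.n_risk = None if n_risk is None else np.asarray(n_risk)
        self.n_event = None if n_event is None else np.asarray(n_event)

    def at(self, t):
        """Evaluate the step function at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], self._start_value)
        return float(out) if out.ndim == 0 else out

    @property
    def se(self):
        return None if self.variance is None else np.sqrt(np.clip(self.variance, 0, None))

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.times, "estimate": self.values}
        if self.variance is not None:
            cols["se"] = self.se
        if self.ci_lower is not None:
            cols["ci_lower"] = self.ci_lower
            cols["ci_upper"] = self.ci_upper
        if self.n_risk is not None:
            cols["n_risk"] = self.n_risk
        if self.n_event is not None:
            cols["n_event"] = self.n_event
        return pd.DataFrame(cols)


class SurvivalCurve(_StepCurve):
    """Kaplan-Meier survival estimate with Greenwood variance.

    ``S(0) = 1``; values are non-increasing in [0, 1]; the pointwise
    confidence interval uses the log(-log) transform so bounds stay in
    [0, 1].
    """

    _start_value = 1.0


class CIFCurve(_StepCurve):
    """Aalen-Johansen cumulative incidence for one cause.

    ``F_k(0) = 0``; values are non-decreasing in [0, 1]; confidence
    intervals use the complementary log-log transform.
    """

    _start_value = 0.0

    def __init__(self, *args, cause=None, zero_events=False, **kwargs):
        super().__init__(*args, **kwargs)
        self.cause = cause
        #: set when the requested cause has no events (curve identically 0)
        self.zero_events = zero_events


def _risk_table(time, event_indicator):
    """Unique times, numbers at risk, event counts and censor counts.

    The grid contains every distinct observed time (event or censoring);
    at a tied time events are processed before censorings, so the risk
    set at ``t`` counts every observation with ``T >= t``.
    """
    order = np.argsort(time, kind="mergesort")
    t = time[order]
    e = event_indicator[order]
    grid, start = np.unique(t, return_index=True)
    bounds = np.append(start, t.size)
    n_at_risk = t.size - start
    d = np.add.reduceat(e.astype(int), start)
    c = (bounds[1:] - bounds[:-1]) - d
    return grid, n_at_risk, d, c, order


def _greenwood_ci(s, var, alpha):
    """log(-log)-transformed pointwise CI, clamped to [0, 1]."""
    z = norm.ppf(1 - alpha / 2.0)
    lo = np.empty_like(s)
    hi = np.empty_like(s)
    interior = (s > 0) & (s < 1)
    lo[~interior] = s[~interior]
    hi[~interior] = s[~interior]
    si = s[interior]
    se_theta = np.sqrt(np.clip(var[interior], 0, None)) / (si * np.abs(np.log(si)))
    lo[interior] = si ** np.exp(z * se_theta)
    hi[interior] = si ** np.exp(-z * se_theta)
    return np.clip(lo, 0, 1), np.clip(hi, 0, 1)


def kaplan_meier(
    sample: CRSample,
    cause: int | None = None,
    treat_competitors_as_censoring: bool = False,
    alpha: float = 0.05,
) -> SurvivalCurve:
    """Product-limit survival estimate.

    With ``cause=None`` any non-zero status is an event (all-cause
    survival).  Passing a specific ``cause`` together with
    ``treat_competitors_as_censoring=True`` computes the deliberately
    *biased* per-cause Kaplan-Meier that treats competing events as
    censoring times; ``1 - S(t)`` from this curve overestimates the
    cause's cumulative incidence whenever competitors occur.

    Parameters
    ----------
    sample
        Competing-risks observations; must contain at least one event.
    cause
        Target cause code, or ``None`` for all-cause.
    treat_competitors_as_censoring
        Required (and only meaningful) when ``cause`` is given.
    """
    if sample.n_events == 0:
        raise ValueError("sample contains no events")
    if cause is None:
        ev = sample.status > 0
    else:
        if not treat_competitors_as_censoring:
            raise ValueError(
                "per-cause Kaplan-Meier requires treat_competitors_as_censoring=True; "
                "use aalen_johansen_cif for an unbiased cause-specific estimate"
            )
        ev = sample.status == cause

    grid, n, d, _, _ = _risk_table(sample.time, ev)
    frac = np.ones_like(grid)
    np.divide(d, n, out=frac, where=n > 0)
    s = np.cumprod(1.0 - frac)
    # Greenwood: var(S) = S^2 * cumsum(d / (n (n - d)))
    gw_term = np.zeros_like(grid)
    ok = (n - d) > 0
    gw_term[ok] = d[ok] / (n[ok] * (n[ok] - d[ok]))
    var = s**2 * np.cumsum(gw_term)
    lo, hi = _greenwood_ci(s, var, alpha)
    return SurvivalCurve(grid, s, var, lo, hi, n_risk=n, n_event=d)


def aalen_johansen_cif(
    sample: CRSample, cause: int, alpha: float = 0.05
) -> CIFCurve:
    """Aalen-Johansen cumulative incidence for ``cause``.

    ``F_k(t) = sum_{t_i <= t} S(t_i-) d_ki / n_i`` with ``S`` the
    all-cause Kaplan-Meier.  The variance uses the Dinse-Larson
    counting-process estimator; with zero censoring the estimate equals
    the empirical sub-distribution exactly.
    """
    ev_all = sample.status > 0
    grid, n, d_all, _, order = _risk_table(sample.time, ev_all)

    st = sample.status[order]
    t_sorted = sample.time[order]
    _, start = np.unique(t_sorted, return_index=True)
    d_k = np.add.reduceat((st == cause).astype(int), start)

    if d_k.sum() == 0:
        zero = np.zeros_like(grid)
        return CIFCurve(grid, zero, zero, zero, zero, n_risk=n, n_event=d_k,
                        cause=cause, zero_events=True)

    frac_all = np.zeros_like(grid)
    np.divide(d_all, n, out=frac_all, where=n > 0)
    s = np.cumprod(1.0 - frac_all)
    s_minus = np.concatenate([[1.0], s[:-1]])
    jumps = s_minus * d_k / n
    f = np.cumsum(jumps)

    # Dinse-Larson variance of F_k(t): sums over event times t_j <= t of
    #   (F(t)-F(t_j))^2 d_j/(n_j(n_j-d_j))
    # + S(t_j-)^2 d_kj (n_j - d_kj)/n_j^3
    # - 2 (F(t)-F(t_j)) S(t_j-) d_kj/n_j^2
    a = np.zeros_like(grid)
    ok = (n - d_all) > 0
    a[ok] = d_all[ok] / (n[ok] * (n[ok] - d_all[ok]))
    b = s_minus**2 * d_k * (n - d_k) / n**3
    c = s_minus * d_k / n**2
    # expand (F(t)-F(t_j))^2 = F(t)^2 - 2 F(t) F(t_j) + F(t_j)^2 to keep O(T)
    A0, A1, A2 = np.cumsum(a), np.cumsum(a * f), np.cumsum(a * f**2)
    C0, C1 = np.cumsum(c), np.cumsum(c * f)
    var = (f**2 * A0 - 2 * f * A1 + A2) + np.cumsum(b) - 2 * (f * C0 - C1)
    var = np.clip(var, 0.0, None)

    # complementary log-log CI on 1 - F
    z = norm.ppf(1 - alpha / 2.0)
    lo = np.zeros_like(f)
    hi = np.zeros_like(f)
    interior = (f > 0) & (f < 1)
    lo[~interior] = f[~interior]
    hi[~interior] = f[~interior]
    fi = f[interior]
    se_theta = np.sqrt(var[interior]) / ((1 - fi) * np.abs(np.log1p(-fi)))
    lo[interior] = 1 - (1 - fi) ** np.exp(z * se_theta)
    hi[interior] = 1 - (1 - fi) ** np.exp(-z * se_theta)
    return CIFCurve(grid, f, var, np.clip(lo, 0, 1), np.clip(hi, 0, 1),
                    n_risk=n, n_event=d_k, cause=cause)


def censoring_survival(
    sample: CRSample, stratify_by: np.ndarray | str | None = None
) -> SurvivalCurve | dict:
    """Reverse-role Kaplan-Meier of the censoring distribution G(t).

    Censorings play the role of events and events the role of censoring.
    Because ties are resolved event-first, observations with an event at
    ``t`` are removed from the risk set before the censoring jump at
    ``t`` is applied; with this convention the IPCW identity
    ``(1/n) sum_i 1{T_i<=t, eps_i=k} / G(T_i-) = F_k^AJ(t)`` holds
    exactly.

    Parameters
    ----------
    stratify_by
        Optional covariate name (or array of labels) producing one curve
        per experimental group; returns a dict keyed by group label.
    """
    if stratify_by is not None:
        labels = (
            sample.covariates[stratify_by].to_numpy()
            if isinstance(stratify_by, str)
            else np.asarray(stratify_by)
        )
        return {
            lvl: censoring_survival(sample.subset(labels == lvl))
            for lvl in pd.unique(labels)
        }

    grid, n, d_all, c_cnt, _ = _risk_table(sample.time, sample.status > 0)
    # risk set for the censoring jump at t excludes events tied at t
    denom = (n - d_all).astype(float)
    frac = np.zeros_like(grid)
    np.divide(c_cnt, denom, out=frac, where=denom > 0)
    frac[(denom <= 0) & (c_cnt > 0)] = 1.0
    g = np.cumprod(1.0 - frac)
    gw = np.zeros_like(grid)
    ok = (denom - c_cnt) > 0
    gw[ok] = c_cnt[ok] / (denom[ok] * (denom[ok] - c_cnt[ok]))
    var = g**2 * np.cumsum(gw)
    return SurvivalCurve(grid, g, var, n_risk=n, n_event=c_cnt)


def ipcw_weights(sample: CRSample, ghat: SurvivalCurve | dict,
                 strata: np.ndarray | None = None) -> np.ndarray:
    """Per-observation IPCW factor ``1/G(T_i-)`` for observed events.

    Censored observations get weight 0.  ``G(T_i-)`` is the left limit
    of the censoring survival at the observation's own time, taken from
    the (possibly stratified) reverse Kaplan-Meier.
    """
    w = np.zeros(sample.n)
    ev = sample.status > 0

    def _left_limit(curve, t):
        idx = np.searchsorted(curve.times, t, side="left") - 1
        vals = np.where(idx >= 0, curve.values[np.clip(idx, 0, None)], 1.0)
        return vals

    if isinstance(ghat, dict):
        if strata is None:
            raise ValueError("stratified G requires the strata labels")
        for lvl, curve in ghat.items():
            m = ev & (strata == lvl)
            g = _left_limit(curve, sample.time[m])
            if np.any(g <= 0):
                raise ValueError("censoring survival reached 0 before an event time")
            w[m] = 1.0 / g
    else:
        g = _left_limit(ghat, sample.time[ev])
        if np.any(g <= 0):
            raise ValueError("censoring survival reached 0 before an event time")
        w[ev] = 1.0 / g
    return w
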