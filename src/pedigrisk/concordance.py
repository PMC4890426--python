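"""Clustered concordance analysis for kin pairs.

Given kin pairs (siblings, mother-daughter, first or second cousins)
with competing-risks outcomes, this module estimates

* the pairwise concordance probability
  ``H(t) = P(T1 <= t, eps1 = k, T2 <= t, eps2 = k)`` by IPCW,
* the conditional (probandwise) probability ``pi(t) = H(t) / F(t)``, and
* a cross-odds ratio (COR): the odds that one member experiences the
  event by ``t`` given its co-member has, divided by the unconditional
  odds.  ``COR = 1`` under independence; ``COR > 1`` means concordant
  fates, ``COR < 1`` discordant fates.

The COR is estimated in two stages: the marginal CIF first
(non-parametric, or covariate-adjusted through a fitted
competing-risks regression), then a Clayton/gamma-frailty dependence
parameter ``theta`` by a pairwise estimating equation matching the
observed concordance curve; the reported COR is the time-average of the
model-implied cross-odds-ratio profile.  Uncertainty is propagated
through both stages by a seeded cluster bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm

from .nonparam import censoring_survival
from .pedigree import KinPairSet
from .sample import CRSample

__all__ = [
    "PairedCRSample",
    "pair_sample",
    "ConcordanceFit",
    "concordance_curve",
    "CrossOddsRatio",
    "CrossOddsRatioResults",
    "cross_odds_ratio",
]


# ----------------------------------------------------------------------
@dataclass
class PairedCRSample:
    """Per-pair competing-risks observations ``(T1, eps1, T2, eps2)``.

    ``cluster`` identifies the common ancestor defining each pair's
    cluster, so cousin clusters whose cross pairs share cells can be
    grouped for cluster-robust resampling.
    """

    time1: np.ndarray
    status1: np.ndarray
    time2: np.ndarray
    status2: np.ndarray
    cluster: np.ndarray
    relation: str = ""
    ids1: np.ndarray | None = None
    ids2: np.ndarray | None = None
    #: optional censoring-weight strata per member (e.g. generation);
    #: censoring intensity in pedigree data depends on birth time, and
    #: both members of a kin pair share it, so the censoring survival
    #: used for IPCW is estimated within strata when these are set
    strata1: np.ndarray | None = None
    strata2: np.ndarray | None = None
    #: censoring-fate labels per member ("lost" / "end_of_observation" /
    #: "" for events); distinguishes the individual loss component from
    #: the shared end-of-observation component in the IPCW weights
    kinds1: np.ndarray | None = None
    kinds2: np.ndarray | None = None
    #: censoring dependence within a pair: "independent" (each member
    #: censored on its own) or "common" (members share their censoring
    #: time, as kin in a pedigree share the observation horizon from
    #: their birth).  Determines the pair-level IPCW weight: a product
    #: of member weights, or 1/G(max(T1, T2)-).
    censoring: str = "independent"
    n_dropped: int = 0

    def __post_init__(self):
        self.time1 = np.asarray(self.time1, dtype=float)
        self.time2 = np.asarray(self.time2, dtype=float)
        self.status1 = np.asarray(self.status1, dtype=int)
        self.status2 = np.asarray(self.status2, dtype=int)
        self.cluster = np.asarray(self.cluster)
        if not (self.time1.size == self.time2.size == self.status1.size
                == self.status2.size == self.cluster.size):
            raise ValueError("paired arrays must have equal length")

    @property
    def n_pairs(self) -> int:
        return self.time1.size

    def members(self) -> CRSample:
        """Pooled member records (unique cells when ids are available)."""
        t = np.concatenate([self.time1, self.time2])
        s = np.concatenate([self.status1, self.status2])
        cl = np.concatenate([self.cluster, self.cluster])
        strata = (np.concatenate([self.strata1, self.strata2])
                  if self.strata1 is not None else None)
        kinds = (np.concatenate([self.kinds1, self.kinds2])
                 if self.kinds1 is not None else None)
        if self.ids1 is not None and self.ids2 is not None:
            ids = np.concatenate([self.ids1, self.ids2])
            _, keep = np.unique(ids, return_index=True)
            return CRSample(t[keep], s[keep], cluster=cl[keep], ids=ids[keep],
                            generation=None if strata is None else strata[keep],
                            censor_kind=None if kinds is None else kinds[keep])
        return CRSample(t, s, cluster=cl, generation=strata,
                        censor_kind=kinds)

    def __len__(self) -> int:
        return self.n_pairs


def pair_sample(sample: CRSample, kin_pairs: KinPairSet) -> PairedCRSample:
    """Join kin pairs onto a flattened sample.

    Pairs with a member filtered out upstream are dropped and counted in
    ``n_dropped``; an entirely empty result is an error.
    """
    if sample.ids is None:
        raise ValueError("sample must carry cell ids to join kin pairs")
    idx = {cid: i for i, cid in enumerate(sample.ids)}
    rows1, rows2, clusters, a_ids, b_ids = [], [], [], [], []
    dropped = 0
    for a, b, cl in kin_pairs:
        if a not in idx or b not in idx:
            dropped += 1
            continue
        rows1.append(idx[a])
        rows2.append(idx[b])
        clusters.append(cl)
        a_ids.append(a)
        b_ids.append(b)
    if not rows1:
        raise ValueError("no kin pairs remain after joining onto the sample")
    i1 = np.asarray(rows1)
    i2 = np.asarray(rows2)
    gen = sample.generation
    return PairedCRSample(
        sample.time[i1], sample.status[i1],
        sample.time[i2], sample.status[i2],
        cluster=np.asarray(clusters), relation=kin_pairs.relation,
        ids1=np.asarray(a_ids), ids2=np.asarray(b_ids),
        strata1=None if gen is None else gen[i1],
        strata2=None if gen is None else gen[i2],
        kinds1=None if sample.censor_kind is None else sample.censor_kind[i1],
        kinds2=None if sample.censor_kind is None else sample.censor_kind[i2],
        censoring="common",  # kin share the observation horizon
        n_dropped=dropped,
    )


# ----------------------------------------------------------------------
def _left_limit(curve, t):
    idx = np.searchsorted(curve.times, t, side="left") - 1
    return np.where(idx >= 0, curve.values[np.clip(idx, 0, None)], 1.0)


def _g_left(ghat, time, strata):
    """Left limit G(t-), dispatching on stratified vs pooled curves."""
    if isinstance(ghat, dict):
        out = np.ones(time.size)
        for lvl, curve in ghat.items():
            m = strata == lvl
            if np.any(m):
                out[m] = _left_limit(curve, time[m])
        return out
    return _left_limit(ghat, time)


def _g_grid(ghat, grid):
    """Pointwise minimum of G over strata (for truncation checks)."""
    if isinstance(ghat, dict):
        return np.min([c.at(grid) for c in ghat.values()], axis=0)
    return ghat.at(grid)


class _CensoringModel:
    """Two-component censoring distribution for IPCW.

    Kin in a pedigree share their end-of-observation time (both were
    born when their parent divided, and tracking stops at the same
    horizon) but are lost individually.  When the censoring-fate labels
    are available the two mechanisms get separate reverse-Kaplan-Meier
    estimates — `shared` (end_of_observation) and `indep` (lost) — so a
    pair can be weighted by ``1/[G_sh(max) G_in(T1) G_in(T2)]`` under
    shared censoring.  Both components are stratified by the member
    strata (generation) when present, because the remaining observation
    time depends on when a cell was born.
    """

    def __init__(self, members: CRSample):
        t, s = members.time, members.status
        kinds = members.censor_kind
        self._strata = members.generation
        cens = s == 0
        have_both = (kinds is not None
                     and np.any(cens & (kinds == "lost"))
                     and np.any(cens & (kinds == "end_of_observation")))
        if have_both:
            shared_status = np.where(cens & (kinds == "end_of_observation"),
                                     0, 1)
            indep_status = np.where(cens & (kinds == "lost"), 0, 1)
            self.shared = self._fit(t, shared_status)
            self.indep = self._fit(t, indep_status)
        else:
            self.shared = self._fit(t, s)
            self.indep = None

    def _fit(self, t, s):
        samp = CRSample(t, np.where(np.asarray(s) == 0, 0, 1))
        if (self._strata is not None
                and np.unique(self._strata).size > 1):
            return censoring_survival(samp, stratify_by=self._strata)
        return censoring_survival(samp)

    def member_left(self, time, strata):
        g = _g_left(self.shared, time, strata)
        if self.indep is not None:
            g = g * _g_left(self.indep, time, strata)
        return g

    def pair_left_common(self, t1, s1, t2, s2):
        """Weight denominator for a pair under shared censoring."""
        t_max = np.maximum(t1, t2)
        later = None
        if s1 is not None:
            later = np.where(t1 >= t2, s1, s2)
        g = _g_left(self.shared, t_max, later)
        if self.indep is not None:
            g = g * _g_left(self.indep, t1, s1) * _g_left(self.indep, t2, s2)
        return g

    def at(self, grid):
        g = _g_grid(self.shared, grid)
        if self.indep is not None:
            g = g * _g_grid(self.indep, grid)
        return g


def _pair_matrices(paired: PairedCRSample, cause: int, grid: np.ndarray,
                   members=None, ghat=None):
    """IPCW matrices for the concordance estimators.

    Returns ``(h_terms, rm, members, ghat)`` where ``h_terms[p, t]`` is
    the pair's weighted both-events indicator and ``rm[i, t]`` the
    member-level weighted event indicator used for the marginal CIF.

    Under ``censoring="independent"`` the pair weight is the product of
    the member weights ``1/G(T_j-)``; under ``"common"`` (members share
    their censoring time) it is ``1/G(max(T1, T2)-)`` — the probability
    that the shared censoring outlasts both events.
    """
    if members is None:
        members = paired.members()
    if ghat is None:
        ghat = _CensoringModel(members)

    def member_weights(time, status, strata):
        w = np.zeros(time.size)
        ev = status == cause
        g = ghat.member_left(time[ev],
                             None if strata is None else strata[ev])
        if np.any(g <= 0):
            raise ValueError("censoring survival reached 0 before an event")
        w[ev] = 1.0 / g
        return w

    both = (paired.status1 == cause) & (paired.status2 == cause)
    ind = ((paired.time1[:, None] <= grid[None, :])
           & (paired.time2[:, None] <= grid[None, :])
           & both[:, None])
    if paired.censoring == "common":
        g = ghat.pair_left_common(paired.time1, paired.strata1,
                                  paired.time2, paired.strata2)
        if np.any(g[both] <= 0):
            raise ValueError("censoring survival reached 0 before an event")
        w_pair = np.where(both & (g > 0), 1.0 / np.where(g > 0, g, 1.0), 0.0)
    else:
        w1 = member_weights(paired.time1, paired.status1, paired.strata1)
        w2 = member_weights(paired.time2, paired.status2, paired.strata2)
        w_pair = w1 * w2
    h_terms = w_pair[:, None] * ind
    wm = member_weights(members.time, members.status, members.generation)
    rm = wm[:, None] * (members.time[:, None] <= grid[None, :])
    return h_terms, rm, members, ghat


def _default_grid(paired, cause, max_points=40):
    t = np.concatenate([paired.time1[paired.status1 == cause],
                        paired.time2[paired.status2 == cause]])
    if t.size == 0:
        raise ValueError(f"no events of cause {cause} among pair members")
    grid = np.unique(t)
    if grid.size > max_points:
        idx = np.unique(np.linspace(0, grid.size - 1, max_points).round().astype(int))
        grid = grid[idx]
    return grid


@dataclass
class ConcordanceFit:
    """Concordance and conditional probability curves (with optional COR)."""

    cause: int
    relation: str
    grid: np.ndarray
    concordance: np.ndarray  # H(t)
    marginal: np.ndarray  # F(t)
    conditional: np.ndarray  # pi(t) = H/F
    concordance_ci: tuple[np.ndarray, np.ndarray] | None = None
    conditional_ci: tuple[np.ndarray, np.ndarray] | None = None
    truncated: bool = False
    n_pairs: int = 0

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "time": self.grid, "H": self.concordance,
            "F": self.marginal, "pi": self.conditional,
        })
        if self.concordance_ci is not None:
            out["H_lo"], out["H_hi"] = self.concordance_ci
        if self.conditional_ci is not None:
            out["pi_lo"], out["pi_hi"] = self.conditional_ci
        return out


def concordance_curve(
    paired: PairedCRSample,
    cause: int,
    grid=None,
    alpha: float = 0.05,
    n_resample: int = 500,
    seed=None,
) -> ConcordanceFit:
    """IPCW concordance and conditional probability curves.

    Each pair contributes the product of its members' IPCW event
    indicators, i.e. it is weighted by the inverse probability that both
    members remain uncensored to their event times.  The marginal
    ``F(t)`` is the IPCW estimate over all (unique) member records —
    identical to Aalen-Johansen.  Pointwise CIs come from a seeded
    cluster multiplier bootstrap.  If the censoring survival reaches 0
    before the last requested time the curves are truncated there and
    flagged.
    """
    if grid is None:
        grid = _default_grid(paired, cause)
    grid = np.asarray(grid, dtype=float)
    h_terms, rm, members, ghat = _pair_matrices(paired, cause, grid)
    truncated = False
    g_at = ghat.at(grid)
    if np.any(g_at <= 0):
        keep = g_at > 0
        grid = grid[keep]
        h_terms, rm = h_terms[:, keep], rm[:, keep]
        truncated = True
    h = h_terms.mean(axis=0)
    f = rm.mean(axis=0)
    h = np.minimum(h, np.maximum(f, 0))  # enforce H <= F after truncation
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = np.where(f > 0, np.clip(h / f, 0, 1), 0.0)

    # cluster multiplier bootstrap for pointwise CIs
    rng = np.random.default_rng(seed)
    clusters, pair_cl = np.unique(paired.cluster, return_inverse=True)
    mem_cl = np.searchsorted(clusters, members.cluster)
    xi = rng.standard_normal((n_resample, clusters.size))
    ch = np.zeros((clusters.size, grid.size))
    np.add.at(ch, pair_cl, h_terms - h)
    cf = np.zeros((clusters.size, grid.size))
    np.add.at(cf, mem_cl, rm - f)
    dh = xi @ ch / h_terms.shape[0]
    df_ = xi @ cf / rm.shape[0]
    z = norm.ppf(1 - alpha / 2)
    se_h = dh.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        dpi = np.where(f > 0, (dh - pi * df_) / f, 0.0)
    se_pi = dpi.std(axis=0, ddof=1)
    fit = ConcordanceFit(
        cause=cause, relation=paired.relation, grid=grid,
        concordance=h, marginal=f, conditional=pi,
        concordance_ci=(np.clip(h - z * se_h, 0, 1), np.clip(h + z * se_h, 0, 1)),
        conditional_ci=(np.clip(pi - z * se_pi, 0, 1), np.clip(pi + z * se_pi, 0, 1)),
        truncated=truncated, n_pairs=paired.n_pairs,
    )
    return fit


# ----------------------------------------------------------------------
def clayton_cdf(u, v, theta):
    """Clayton copula ``C_theta(u, v)``, evaluated in log space so large
    positive ``theta`` (strong concordance) does not overflow.

    ``theta = 0`` is independence; ``theta`` in (-1, 0) gives discordant
    dependence (with the usual zero region where the generator argument
    is negative)."""
    u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
    v = np.clip(np.asarray(v, dtype=float), 0.0, 1.0)
    if abs(theta) < 1e-9:
        return u * v
    with np.errstate(divide="ignore", invalid="ignore"):
        if theta > 0:
            a = -theta * np.log(u)
            b = -theta * np.log(v)
            hi = np.maximum(a, b)
            lo = np.minimum(a, b)
            log_base = hi + np.log1p(np.exp(lo - hi) - np.exp(-hi))
            out = np.exp(-log_base / theta)
        else:
            base = u ** (-theta) + v ** (-theta) - 1.0
            out = np.where(base > 0, np.maximum(base, 1e-300) ** (-1.0 / theta),
                           0.0)
    out = np.where((u <= 0) | (v <= 0), 0.0, out)
    return np.minimum(out, np.minimum(u, v))


_clayton = clayton_cdf


class CrossOddsRatio:
    """Model object for the constant cross-odds ratio of kin pairs.

    Parameters
    ----------
    paired
        Kin pairs with competing-risks outcomes.
    cause
        Target cause code.
    marginal_model
        ``None`` for the non-parametric pooled marginal CIF, or a fitted
        :class:`~pedigrisk.crr.CRRResults` whose ``predict_cif`` supplies
        member-specific (covariate-adjusted) marginals; in that case
        ``marginal_profiles`` must give the per-member covariate profiles
        as two DataFrames (member 1, member 2).
    grid
        Time grid for the estimating equation; default: quantiles of the
        member cause-event times (up to ``max_points``).
    theta_bounds
        Search interval for the Clayton dependence parameter; the lower
        bound may be negative to allow discordance.
    """

    def __init__(self, paired: PairedCRSample, cause: int,
                 marginal_model=None, marginal_profiles=None,
                 grid=None, grid_fractions=None,
                 theta_bounds=(-0.6, 60.0)):
        self.paired = paired
        self.cause = cause
        self.marginal_model = marginal_model
        self.marginal_profiles = marginal_profiles
        self.theta_bounds = theta_bounds
        #: fractions of the terminal marginal mass defining the grid times
        self.grid_fractions = (np.linspace(0.05, 0.95, 19)
                               if grid_fractions is None
                               else np.asarray(grid_fractions, dtype=float))
        self.grid = None if grid is None else np.asarray(grid, dtype=float)

    def _select_grid(self, members, ghat):
        """Times where the marginal CIF first reaches each fraction of
        its value at the last reliable time.

        Tying the grid to marginal quantiles makes the time-averaged COR
        a well-defined estimand, comparable across datasets and matching
        the convention of the theoretical oracle."""
        fine = _default_grid(self.paired, self.cause, max_points=10**9)
        g_at = ghat.at(fine)
        fine = fine[g_at > 0]
        if fine.size == 0:
            raise ValueError("censoring survival reached 0 before any event")
        w = np.zeros(members.n)
        ev = members.status == self.cause
        g = ghat.member_left(members.time[ev],
                              None if members.generation is None
                              else members.generation[ev])
        w[ev] = 1.0 / g
        f_fine = ((w[:, None] * (members.time[:, None] <= fine[None, :]))
                  .mean(axis=0))
        f_fine = np.maximum.accumulate(f_fine)
        f_end = f_fine[-1]
        idx = np.searchsorted(f_fine, self.grid_fractions * f_end, side="left")
        idx = np.clip(idx, 0, fine.size - 1)
        return np.unique(fine[idx])

    # -- internals ------------------------------------------------------
    def _marginal_matrices(self):
        """Per-member model CIF matrices F1, F2 (pairs x grid)."""
        m = self.paired.n_pairs
        if self.marginal_model is None:
            return None
        if self.marginal_profiles is None:
            raise ValueError("marginal_model requires marginal_profiles")
        prof1, prof2 = self.marginal_profiles

        def matrix(profiles):
            rows = np.empty((m, self.grid.size))
            uniq = profiles.drop_duplicates()
            for _, row in uniq.iterrows():
                curve = self.marginal_model.predict_cif(row.to_dict(),
                                                        n_resample=50, seed=0)
                mask = (profiles == row).all(axis=1).to_numpy()
                rows[mask] = curve.at(self.grid)
            return np.clip(rows, 1e-10, 1 - 1e-10)

        return matrix(pd.DataFrame(prof1)), matrix(pd.DataFrame(prof2))

    def fit(self, n_resample: int = 500, seed=None,
            min_pairs: int = 5) -> "CrossOddsRatioResults":
        """Two-stage estimation with cluster-bootstrap uncertainty.

        Raises when fewer than ``min_pairs`` pairs have both members
        observed with the target cause, or when the estimating equation
        has no root inside ``theta_bounds``.
        """
        paired, cause = self.paired, self.cause
        both = np.sum((paired.status1 == cause) & (paired.status2 == cause))
        if both < min_pairs:
            raise ValueError(
                f"only {both} doubly-observed pairs (< {min_pairs}); "
                "COR is not estimable"
            )
        members = paired.members()
        ghat = _CensoringModel(members)
        grid = (self._select_grid(members, ghat) if self.grid is None
                else self.grid)
        h_terms, rm, members, ghat = _pair_matrices(paired, cause, grid,
                                                    members, ghat)
        g_at = ghat.at(grid)
        if np.any(g_at <= 0):
            keep = g_at > 0
            grid = grid[keep]
            h_terms, rm = h_terms[:, keep], rm[:, keep]
        fmats = self._marginal_matrices()

        clusters, pair_cl = np.unique(paired.cluster, return_inverse=True)
        mem_cl = np.searchsorted(clusters, members.cluster)
        n_cl = clusters.size

        def estimate(pair_w, mem_w):
            h_obs = (pair_w[:, None] * h_terms).sum(0) / pair_w.sum()
            if fmats is None:
                f_obs = (mem_w[:, None] * rm).sum(0) / mem_w.sum()
                f_obs = np.clip(np.maximum.accumulate(f_obs), 1e-10, 1 - 1e-10)
                f1m = f2m = np.broadcast_to(f_obs, h_terms.shape)
            else:
                f1m, f2m = fmats
                f_obs = np.clip((mem_w[:, None] * rm).sum(0) / mem_w.sum(),
                                1e-10, 1 - 1e-10)

            def ee(theta):
                model = _clayton(f1m, f2m, theta)
                return float(((pair_w[:, None] * (h_terms - model)).sum(0)
                              / pair_w.sum()).sum())

            lo, hi = self.theta_bounds
            flo, fhi = ee(lo), ee(hi)
            if flo * fhi > 0:  # boundary solution
                theta = lo if abs(flo) < abs(fhi) else hi
            else:
                theta = optimize.brentq(ee, lo, hi, xtol=1e-10)
            pi_model = _clayton(f_obs, f_obs, theta) / f_obs
            pi_model = np.clip(pi_model, 1e-10, 1 - 1e-10)
            cor_prof = (pi_model / (1 - pi_model)) / (f_obs / (1 - f_obs))
            return theta, cor_prof, f_obs, h_obs

        pw = np.ones(paired.n_pairs)
        mw = np.ones(members.n)
        theta_hat, cor_profile, f_obs, h_obs = estimate(pw, mw)
        cor_hat = float(np.mean(cor_profile))
        log_cor = float(np.log(max(cor_hat, 1e-12)))

        rng = np.random.default_rng(seed)
        log_draws = np.empty(n_resample)  # n_resample = 0 skips the bootstrap
        for b in range(n_resample):
            counts = rng.multinomial(n_cl, np.full(n_cl, 1.0 / n_cl))
            pwb = counts[pair_cl].astype(float)
            mwb = counts[mem_cl].astype(float)
            if pwb.sum() == 0 or mwb.sum() == 0:
                log_draws[b] = log_cor
                continue
            try:
                _, prof_b, _, _ = estimate(pwb, mwb)
                log_draws[b] = np.log(max(float(np.mean(prof_b)), 1e-12))
            except (ValueError, RuntimeError):
                log_draws[b] = np.nan
        log_draws = log_draws[np.isfinite(log_draws)]
        se = float(log_draws.std(ddof=1)) if log_draws.size > 1 else np.nan
        zval = log_cor / se if se and se > 0 else np.nan
        pval = float(2 * norm.sf(abs(zval))) if np.isfinite(zval) else np.nan

        curves = ConcordanceFit(
            cause=cause, relation=paired.relation, grid=grid,
            concordance=h_obs, marginal=f_obs,
            conditional=np.where(f_obs > 0, np.clip(h_obs / f_obs, 0, 1), 0.0),
            n_pairs=paired.n_pairs,
        )
        return CrossOddsRatioResults(
            model=self, theta=float(theta_hat), cor=cor_hat,
            log_cor=log_cor, se_log_cor=se, pvalue=pval,
            cor_profile=pd.DataFrame({"time": grid, "cor": cor_profile}),
            curves=curves, n_pairs=paired.n_pairs,
            n_boot=int(log_draws.size),
        )


@dataclass
class CrossOddsRatioResults:
    """Fitted cross-odds ratio.

    Both reporting scales are carried: ``log_cor`` with ``se_log_cor``
    (the estimation scale) and the exponentiated ``cor``.  ``pvalue`` is
    the Wald test of independence (log COR = 0, i.e. COR = 1).
    """

    model: CrossOddsRatio
    theta: float
    cor: float
    log_cor: float
    se_log_cor: float
    pvalue: float
    cor_profile: pd.DataFrame
    curves: ConcordanceFit
    n_pairs: int
    n_boot: int

    def conf_int(self, alpha: float = 0.05) -> tuple[float, float]:
        """CI for the COR (normal on the log scale, exponentiated)."""
        z = norm.ppf(1 - alpha / 2)
        return (float(np.exp(self.log_cor - z * self.se_log_cor)),
                float(np.exp(self.log_cor + z * self.se_log_cor)))

    def summary(self) -> str:
        lo, hi = self.conf_int()
        return "\n".join([
            "Cross-odds ratio (Clayton/gamma-frailty dependence)",
            f"  relation: {self.model.paired.relation or '<unset>'}"
            f"    cause: {self.model.cause}    pairs: {self.n_pairs}",
            f"  COR      = {self.cor:.3f}   95% CI [{lo:.3f}, {hi:.3f}]",
            f"  log(COR) = {self.log_cor:.3f} +/- {self.se_log_cor:.3f} (SE)",
            f"  theta    = {self.theta:.3f}",
            f"  H0 COR = 1: p = {self.pvalue:.4g}   "
            f"({self.n_boot} bootstrap replicates)",
        ])

    def to_dict(self) -> dict:
        return {
            "relation": self.model.paired.relation,
            "cause": self.model.cause,
            "n_pairs": self.n_pairs,
            "theta": self.theta,
            "cor": self.cor,
            "log_cor": self.log_cor,
            "se_log_cor": self.se_log_cor,
            "pvalue": self.pvalue,
        }


def cross_odds_ratio(paired: PairedCRSample, cause: int,
                     marginal_model=None, marginal_profiles=None,
                     n_resample: int = 500, seed=None,
                     **kwargs) -> CrossOddsRatioResults:
    """Convenience wrapper: build and fit a :class:`CrossOddsRatio`."""
    return CrossOddsRatio(
        paired, cause, marginal_model, marginal_profiles, **kwargs
    ).fit(n_resample=n_resample, seed=seed)
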