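"""Synthetic lifetime data with known ground truth.

Three generators and one oracle:

* :func:`simulate_precompetition_pairs` — bivariate latent
  (division, death) lifetimes with a Gaussian copula of tunable
  correlation ``rho``.  The first latent fate to occur is observed, the
  alternative is censored by competition, demonstrating that the
  pre-competition dependence is not identifiable from the observed
  cumulative incidence functions.
* :func:`simulate_clayton_pairs` — kin pairs whose cause-k
  sub-distributions are linked by a Clayton (gamma-frailty) copula with
  parameter ``theta``; used for cross-odds-ratio recovery.
* :func:`simulate_pedigrees` — binary-division pedigree forests with
  frailty-induced kin dependence, treatment and fluorescence-intensity
  covariates, an observation horizon and random loss.
* :func:`theoretical_cor` — numerical oracle for the cross-odds ratio
  implied by a Clayton dependence, with :func:`cor_to_theta` as its
  inverse.

All generators are reproducible bit-for-bit given ``(seed, config)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .pedigree import CellRecord, PedigreeForest
from .sample import CRSample
from .concordance import PairedCRSample, clayton_cdf

__all__ = [
    "SimConfig",
    "simulate_precompetition_pairs",
    "simulate_clayton_pairs",
    "simulate_pedigrees",
    "simulate_crr_sample",
    "theoretical_cor",
    "cor_to_theta",
    "clayton_cdf",
]


# ----------------------------------------------------------------------
@dataclass
class SimConfig:
    """Parameters of the pedigree simulator (times in hours).

    The defaults emulate a multi-day time-lapse experiment: founders
    plated at time 0, binary divisions up to ~6 generations, competing
    division/death fates with a separate differentiation-onset event, an
    observation horizon, random loss, and gamma frailty shared within
    kinship clusters.
    """

    seed: int | None = None
    n_founders: int = 150
    max_generations: int = 6
    division_hazard: float = 1.0 / 20.0  # scale parameter; mean cycle ~18 h
    division_shape: float = 3.0  # Weibull shape: concentrated cycle times
    death_hazard: float = 1.0 / 90.0
    death_shape: float = 1.0  # exponential death by default
    differentiation_hazard: float = 0.0
    horizon: float = 96.0  # end of observation, hours
    loss_rate: float = 1.0 / 400.0  # random loss, per hour
    frailty_theta: float = 0.0  # variance of the mean-1 frailty
    frailty_mode: str = "shared"  # "shared" | "heritable"
    frailty_level: str = "parent"  # ancestor depth for "shared"
    frailty_decay: float = 0.5  # lineage AR coefficient for "heritable"
    #: which cause-specific hazards the frailty multiplies
    frailty_applies: tuple = ("division", "death")
    treatment_prob: float = 0.0  # per-pedigree treatment flag
    treatment_log_hr: float = 0.0  # effect of treatment on division hazard
    intensity_mean: float = 100.0  # founder fluorescence intensity
    intensity_heritability: float = 0.9
    intensity_cv: float = 0.3
    cell_cap: int = 200_000

    def to_manifest(self) -> dict:
        return asdict(self)


_FRAILTY_DEPTH = {"parent": 1, "grandparent": 2, "great_grandparent": 3}


# ----------------------------------------------------------------------
def simulate_precompetition_pairs(
    n: int = 5000,
    rho: float = 0.39,
    marginal_division=None,
    marginal_death=None,
    horizon: float = 72.0,
    seed=None,
    rng: np.random.Generator | None = None,
) -> tuple[CRSample, pd.DataFrame]:
    """Bivariate pre-competition lifetimes under a Gaussian copula.

    Each unit draws latent division and death times whose dependence is
    set by the copula correlation ``rho``; the earlier latent event is
    the observed fate, the other is censored by competition, and times
    beyond ``horizon`` are administratively censored.  With the default
    marginals (division typically early, death late) the observed
    cumulative incidence functions are nearly invariant to ``rho``,
    while the per-cause Kaplan-Meier curves — which presume competing
    events censor independently — shift visibly with it: the
    pre-competition dependence cannot be read off the incidence
    functions, but it contaminates the naive per-cause analysis.

    Returns the observable sample (status 1 = division, 2 = death) and
    the latent table retained for oracle checks.
    """
    if not -1.0 < rho < 1.0:
        raise ValueError("copula correlation rho must lie in (-1, 1)")
    if marginal_division is None:
        marginal_division = stats.lognorm(s=0.45, scale=18.0)
    if marginal_death is None:
        marginal_death = stats.lognorm(s=0.55, scale=55.0)
    rng = rng or np.random.default_rng(seed)
    # shared innovations across rho configs act as common random numbers
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(1.0 - rho**2) * rng.standard_normal(n)
    t_div = marginal_division.ppf(stats.norm.cdf(z1))
    t_death = marginal_death.ppf(stats.norm.cdf(z2))
    t_min = np.minimum(t_div, t_death)
    status = np.where(t_min >= horizon, 0, np.where(t_div <= t_death, 1, 2))
    time = np.minimum(t_min, horizon)
    latent = pd.DataFrame({
        "latent_division": t_div,
        "latent_death": t_death,
        "time": time,
        "status": status,
    })
    sample = CRSample(time, status, cause_map={"division": 1, "death": 2})
    return sample, latent


# ----------------------------------------------------------------------
def _clayton_pair_uniforms(n, theta, rng):
    u = rng.uniform(size=n)
    v = rng.uniform(size=n)
    if theta < 1e-12:
        return u, v
    w = (u ** (-theta) * (v ** (-theta / (1.0 + theta)) - 1.0) + 1.0) ** (-1.0 / theta)
    return u, w


def simulate_clayton_pairs(
    n_pairs: int = 1000,
    theta: float = 0.0,
    cause_prob: float = 0.7,
    marginal=None,
    other_marginal=None,
    horizon: float = 72.0,
    censor_rate: float = 0.0,
    seed=None,
    rng: np.random.Generator | None = None,
) -> PairedCRSample:
    """Kin pairs with Clayton-linked cause-1 sub-distributions.

    Each member's outcome is generated from a single uniform ``U``: if
    ``U < cause_prob`` the member experiences cause 1 at the time where
    the cause-1 sub-distribution reaches ``U``, otherwise cause 2.  The
    two members' uniforms follow a Clayton copula with parameter
    ``theta`` (``theta = 0`` is independence), so the joint cause-1
    sub-distribution is exactly ``C_theta(F1(t), F1(s))``.
    """
    if theta < 0:
        raise ValueError("theta must be >= 0 for pair simulation")
    if marginal is None:
        marginal = stats.lognorm(s=0.45, scale=18.0)
    if other_marginal is None:
        other_marginal = stats.lognorm(s=0.5, scale=26.0)
    rng = rng or np.random.default_rng(seed)
    u1, u2 = _clayton_pair_uniforms(n_pairs, theta, rng)

    def realize(u):
        is1 = u < cause_prob
        t = np.where(
            is1,
            marginal.ppf(np.clip(u / cause_prob, 1e-12, 1 - 1e-12)),
            other_marginal.ppf(
                np.clip((u - cause_prob) / (1 - cause_prob), 1e-12, 1 - 1e-12)
            ),
        )
        status = np.where(is1, 1, 2)
        if censor_rate > 0:
            c = np.minimum(rng.exponential(1.0 / censor_rate, size=u.size), horizon)
        else:
            c = np.full(u.size, horizon)
        status = np.where(t >= c, 0, status)
        t = np.minimum(t, c)
        return np.maximum(t, 1e-9), status

    t1, s1 = realize(u1)
    t2, s2 = realize(u2)
    cluster = np.arange(n_pairs)
    return PairedCRSample(t1, s1, t2, s2, cluster=cluster, relation="sibling")


# ----------------------------------------------------------------------
def simulate_pedigrees(
    config: SimConfig | None = None, rng: np.random.Generator | None = None,
    **overrides,
) -> tuple[PedigreeForest, pd.DataFrame, dict]:
    """Grow binary-division pedigree forests with frailty dependence.

    Founders start at time 0 with unknown birth (present at experiment
    start).  Each cell draws latent exponential times for division,
    death and (optionally) differentiation onset; its cause-specific
    division/death hazards are scaled by a mean-1 gamma frailty shared
    within kinship clusters.  With ``frailty_mode="shared"`` the frailty
    is the draw made by the cell's ancestor ``frailty_level`` generations
    up (so siblings share the parental draw, first cousins share only at
    grandparent level, and so on); with ``frailty_mode="heritable"`` the
    log-frailty follows a stationary lineage AR(1) with coefficient
    ``frailty_decay``, so kin dependence decays smoothly with the
    distance to the common ancestor.  Observation stops at the horizon;
    random loss is an independent exponential censoring time per cell.

    Returns ``(forest, latent_table, manifest)``; the forest always
    passes :func:`~pedigrisk.pedigree.validate_pedigree`.
    """
    config = config or SimConfig()
    if overrides:
        config = SimConfig(**{**config.to_manifest(), **overrides})
    if config.frailty_theta < 0:
        raise ValueError("frailty variance theta must be >= 0")
    projected = config.n_founders * (2 ** (config.max_generations + 1))
    if projected > config.cell_cap:
        raise ValueError(
            f"projected cell count {projected} exceeds cap {config.cell_cap}"
        )
    rng = rng or np.random.default_rng(config.seed)
    theta = config.frailty_theta

    if config.frailty_mode not in ("shared", "heritable"):
        raise ValueError("frailty_mode must be 'shared' or 'heritable'")
    depth = _FRAILTY_DEPTH.get(config.frailty_level)
    if config.frailty_mode == "shared" and depth is None:
        raise ValueError(
            f"frailty_level must be one of {sorted(_FRAILTY_DEPTH)}"
        )
    alpha = (1.0 / theta) if theta > 0 else None  # gamma shape, scale theta

    def draw_gamma():
        if theta <= 0:
            return 1.0
        return rng.gamma(alpha, theta)

    def heritable_child(parent_z):
        # beta-thinning gamma autoregression: keeps the Gamma(1/theta,
        # theta) marginal exactly, with per-generation autocorrelation
        # `frailty_decay`, so kin frailty correlation decays as
        # decay ** (branch distance to the common ancestor)
        if theta <= 0:
            return 1.0
        w = config.frailty_decay
        b = rng.beta(w * alpha, (1 - w) * alpha)
        return b * parent_z + rng.gamma((1 - w) * alpha, theta)

    records: list[CellRecord] = []
    latent_rows: list[dict] = []
    counter = 0

    for f in range(config.n_founders):
        treated = int(rng.uniform() < config.treatment_prob)
        ped_id = f"P{f}"
        founder_id = f"P{f}:0"
        if config.frailty_mode == "shared":
            founder_state = [draw_gamma()]  # own draws along lineage, newest last
        else:
            founder_state = draw_gamma()
        intensity = config.intensity_mean * math.exp(
            rng.normal(0, config.intensity_cv))
        # queue: (cell_id, parent_id, birth or None, gen, frailty_state, intensity)
        queue = [(founder_id, None, None, 0, founder_state, intensity)]
        while queue:
            cid, pid, birth, gen, fstate, inten = queue.pop()
            counter += 1
            if counter > config.cell_cap:  # pragma: no cover - guarded above
                raise RuntimeError("cell cap exceeded during growth")
            if config.frailty_mode == "shared":
                # entry j of fstate is the draw made for the ancestor at
                # generation j (shared with that ancestor's sibling); the
                # cluster at ancestor-depth d uses the entry d-1 levels up
                z = fstate[-depth] if len(fstate) >= depth else fstate[0]
            else:
                z = fstate
            z_div = z if "division" in config.frailty_applies else 1.0
            z_death = z if "death" in config.frailty_applies else 1.0
            # multipliers act on the cumulative hazard (proportional
            # hazards given frailty, for any Weibull shape)
            m_div = z_div * math.exp(config.treatment_log_hr * treated)
            m_death = z_death
            h_div = config.division_hazard
            h_death = config.death_hazard
            h_diff = config.differentiation_hazard
            t0 = 0.0 if birth is None else birth
            lat = {}
            best_fate, best_t = None, math.inf
            for fate, h, shape, mult in (
                ("division", h_div, config.division_shape, m_div),
                ("death", h_death, config.death_shape, m_death),
                ("differentiation", h_diff, 1.0, 1.0),
            ):
                if h <= 0 or mult <= 0:
                    lat[fate] = math.inf
                    continue
                # Weibull survival exp(-mult (h t)^shape)
                t = (rng.exponential(1.0) / mult) ** (1.0 / shape) / h
                lat[fate] = t
                if t < best_t:
                    best_fate, best_t = fate, t
            loss_t = (rng.exponential(1.0 / config.loss_rate)
                      if config.loss_rate > 0 else math.inf)
            end_abs = t0 + best_t if best_fate else math.inf
            fate = best_fate or "end_of_observation"
            if t0 + loss_t < min(end_abs, config.horizon):
                fate, end_abs = "lost", t0 + loss_t
            elif end_abs > config.horizon:
                fate, end_abs = "end_of_observation", config.horizon
            records.append(CellRecord(
                cell_id=cid, parent_id=pid, pedigree_id=ped_id,
                birth_time=birth, end_time=end_abs, fate=fate,
                generation=gen,
                covariates={"treatment": treated,
                            "intensity": round(inten, 3)},
            ))
            latent_rows.append({
                "cell_id": cid, "frailty": z,
                "latent_division": lat.get("division", math.inf),
                "latent_death": lat.get("death", math.inf),
                "latent_differentiation": lat.get("differentiation", math.inf),
                "fate": fate, "end_time": end_abs,
            })
            if (fate == "division" and gen < config.max_generations
                    and end_abs < config.horizon):
                if config.frailty_mode == "shared":
                    child_state = fstate + [draw_gamma()] if theta > 0 else fstate + [1.0]
                    child_states = (child_state, child_state)  # siblings share
                else:
                    child_states = (heritable_child(fstate),
                                    heritable_child(fstate))
                h2 = config.intensity_heritability
                for k in (0, 1):
                    child_int = inten ** h2 * config.intensity_mean ** (1 - h2) \
                        * math.exp(rng.normal(0, config.intensity_cv
                                              * math.sqrt(1 - h2**2)))
                    queue.append((f"{cid}.{k}", cid, end_abs, gen + 1,
                                  child_states[k], child_int))
    forest = PedigreeForest(records)
    latent = pd.DataFrame(latent_rows)
    manifest = {"config": config.to_manifest(), "n_cells": len(forest)}
    return forest, latent, manifest


# ----------------------------------------------------------------------
def theoretical_cor(
    theta: float,
    marginal=None,
    cause_prob: float = 0.7,
    t_grid=None,
    method: str = "copula",
) -> dict:
    """Cross-odds ratio implied by a Clayton/gamma-frailty dependence.

    ``COR(t) = odds(H(t)/F(t)) / odds(F(t))`` with
    ``H(t) = C_theta(F(t), F(t))`` and ``F(t) = cause_prob *
    marginal.cdf(t)``.  ``method="copula"`` evaluates the closed-form
    Clayton expression; ``method="quadrature"`` integrates the gamma
    frailty representation ``C(u,u) = E_Z exp(-2 Z psi(u))`` with
    ``psi(u) = (u^-theta - 1)/theta`` numerically, as an independent
    route.  Returns the grid profile and its time-average.
    """
    if marginal is None:
        marginal = stats.lognorm(s=0.45, scale=18.0)
    if t_grid is None:
        t_grid = marginal.ppf(np.linspace(0.05, 0.95, 19))
    t_grid = np.asarray(t_grid, dtype=float)
    f_vals = cause_prob * marginal.cdf(t_grid)
    f_vals = np.clip(f_vals, 1e-12, 1 - 1e-12)
    if method == "copula" or abs(theta) < 1e-9:
        h = clayton_cdf(f_vals, f_vals, theta)
    elif method == "quadrature":
        if theta <= 0:
            raise ValueError("quadrature route requires theta > 0")
        shape = 1.0 / theta
        h = np.empty_like(f_vals)
        for i, u in enumerate(f_vals):
            psi = (u ** (-theta) - 1.0) / theta
            val, err = integrate.quad(
                lambda zz: math.exp(-2.0 * zz * psi)
                * stats.gamma.pdf(zz, shape, scale=theta),
                0, np.inf, limit=200,
            )
            if not np.isfinite(val) or err > 1e-6 * max(val, 1e-12):
                raise RuntimeError(
                    f"frailty quadrature failed at u={u:.4g}: value={val}, err={err}"
                )
            h[i] = val
    else:
        raise ValueError("method must be 'copula' or 'quadrature'")
    pi = h / f_vals
    cor = (pi / (1 - pi)) / (f_vals / (1 - f_vals))
    return {
        "t_grid": t_grid,
        "F": f_vals,
        "cor_profile": cor,
        "cor": float(np.mean(cor)),
    }


def cor_to_theta(
    target_cor: float,
    marginal=None,
    cause_prob: float = 0.7,
    t_grid=None,
    bounds=(1e-8, 80.0),
) -> float:
    """Clayton parameter whose time-averaged cross-odds ratio equals
    ``target_cor`` (inverse of :func:`theoretical_cor`)."""
    if target_cor <= 1.0:
        raise ValueError("target COR must exceed 1 for a positive theta")

    def objective(th):
        return theoretical_cor(th, marginal, cause_prob, t_grid)["cor"] - target_cor

    return float(optimize.brentq(objective, *bounds, xtol=1e-10))


# ----------------------------------------------------------------------
def simulate_crr_sample(
    n: int = 2000,
    gamma: float = 0.7,
    link: str = "proportional",
    baseline_mass: float = 0.55,
    baseline_tau: float = 12.0,
    horizon: float = 72.0,
    censor_scale: float = 50.0,
    additive_slope: float = 0.004,
    seed=None,
    rng: np.random.Generator | None = None,
) -> CRSample:
    """Two-group competing-risks data generated from the regression model.

    ``link="proportional"``: ``cloglog F1(t|z) = b0(t) + gamma z`` with
    exponential-shape baseline ``F0(t) = baseline_mass (1 - e^{-t/tau})``.
    ``link="additive"``: ``F1(t|z) = F0(t) + additive_slope * t * z``
    (``gamma`` is ignored; the recovery target is ``additive_slope``).
    Cause-2 times fill the remaining mass; censoring is the minimum of an
    exponential and the administrative horizon.
    """
    rng = rng or np.random.default_rng(seed)
    z = (rng.uniform(size=n) < 0.5).astype(float)
    u = rng.uniform(size=n)
    p0 = baseline_mass

    def f0_inv(v):
        return -baseline_tau * np.log1p(-np.clip(v / p0, 0, 1 - 1e-12))

    if link == "proportional":
        p1 = 1.0 - (1.0 - p0) ** np.exp(gamma * z)
        is1 = u < p1
        v = 1.0 - (1.0 - u) ** np.exp(-gamma * z)
        t = np.where(is1, f0_inv(v), np.nan)
    elif link == "additive":
        tg = np.linspace(0, horizon * 2, 4001)
        f_base = p0 * (1 - np.exp(-tg / baseline_tau))
        t = np.empty(n)
        is1 = np.zeros(n, dtype=bool)
        for zi in (0.0, 1.0):
            curve = np.clip(f_base + additive_slope * tg * zi, 0, 1 - 1e-9)
            curve = np.maximum.accumulate(curve)
            m = z == zi
            p1m = curve[-1]
            sel = m & (u < p1m)
            is1 |= sel
            t[sel] = np.interp(u[sel], curve, tg)
    else:
        raise ValueError("link must be 'proportional' or 'additive'")
    t_other = stats.lognorm(s=0.5, scale=15.0).rvs(size=n, random_state=rng)
    t = np.where(is1, t, t_other)
    status = np.where(is1, 1, 2)
    c = np.minimum(rng.exponential(censor_scale, size=n), horizon)
    status = np.where(t >= c, 0, status)
    t = np.minimum(t, c)
    return CRSample(np.maximum(t, 1e-9), status, pd.DataFrame({"z": z}))
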