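"""Competing-risks regression on the cumulative incidence scale.

The model regresses the cause-k cumulative incidence function on
covariates through inverse-probability-of-censoring-weighted (IPCW)
binomial estimating equations solved on a grid of event times
(Scheike-Zhang-style direct binomial regression).  Two link functions are
supported:

``additive``
    ``F(t | x, z) = x' B(t) + (z' gamma) t`` — time-varying effects add
    directly to the baseline CIF; constant effects grow linearly in time.

``proportional``
    ``cloglog F(t | x, z) = x' B(t) + z' gamma`` — a Fine-Gray-type
    proportional effect on the subdistribution scale; constant
    coefficients are log-scale factors on the cumulative subdistribution
    hazard.

``x`` collects the baseline and time-varying terms, ``z`` the ``const()``
terms.  With a baseline-only formula either link reproduces the
Aalen-Johansen estimate exactly.  Constant coefficients get
cluster-robust (sandwich) standard errors; time-varying coefficient paths
get pointwise confidence bands by a multiplier (wild) bootstrap, which
also drives the supremum-type test of time invariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .formula import ModelFormula, Term, parse_formula
from .nonparam import CIFCurve, censoring_survival, ipcw_weights
from .sample import CRSample

__all__ = [
    "CompetingRisksRegression",
    "CRRResults",
    "TimeInvarianceResult",
    "ConvergenceError",
    "threshold_scan",
]

_ETA_MIN, _ETA_MAX = -30.0, 3.2
_F_EPS = 1e-10


class ConvergenceError(RuntimeError):
    """Estimating equations failed to converge; carries the last iterate."""

    def __init__(self, message, gamma=None, paths=None, history=None):
        super().__init__(message)
        self.gamma = gamma
        self.paths = paths
        self.history = history


def _cloglog(f):
    return np.log(-np.log1p(-np.clip(f, _F_EPS, 1 - _F_EPS)))


def _inv_cloglog(eta):
    return -np.expm1(-np.exp(np.clip(eta, _ETA_MIN, _ETA_MAX)))


def _check_design(X, Z, names):
    full = np.hstack([X, Z]) if Z.shape[1] else X
    rank = np.linalg.matrix_rank(full)
    if rank < full.shape[1]:
        # name columns whose removal restores full rank
        bad = []
        for j in range(full.shape[1]):
            keep = [c for c in range(full.shape[1]) if c != j]
            if np.linalg.matrix_rank(full[:, keep]) == rank:
                bad.append(names[j])
        raise np.linalg.LinAlgError(
            f"singular design matrix; collinear terms: {bad}"
        )


class CompetingRisksRegression:
    """Model object for CIF regression of one competing cause.

    Parameters
    ----------
    sample
        :class:`~pedigrisk.sample.CRSample` with the covariates named in
        the formula.
    formula
        A formula string (``"CIF ~ 1 + A + const(B) + cluster(g)"``) or a
        parsed :class:`~pedigrisk.formula.ModelFormula`.
    cause
        Target cause code (1..K).
    link
        ``"proportional"`` or ``"additive"``.  Default: proportional when
        the formula has ``const()`` terms, additive for purely
        non-parametric formulas.
    weight_strata
        Optional covariate name; the censoring survival used for IPCW is
        then estimated separately per level (recommended when censoring
        intensity differs across experimental groups).
    max_grid
        Optional cap on the number of grid times; the grid is the set of
        observed event times of the target cause, thinned to evenly
        spaced order statistics when it exceeds the cap.
    """

    def __init__(
        self,
        sample: CRSample,
        formula: str | ModelFormula,
        cause: int = 1,
        link: str | None = None,
        weight_strata: str | None = None,
        max_grid: int | None = None,
    ) -> None:
        if isinstance(formula, str):
            formula = parse_formula(formula)
        if link is None:
            link = "proportional" if formula.constant_terms else formula.link
        if link not in ("proportional", "additive"):
            raise ValueError("link must be 'proportional' or 'additive'")
        self.sample = sample
        self.formula = ModelFormula(formula.response, formula.terms,
                                    formula.cluster, link)
        self.cause = int(cause)
        self.link = link
        self.weight_strata = weight_strata
        self.max_grid = max_grid

        ev = sample.status == self.cause
        if not np.any(ev):
            raise ValueError(f"no events of cause {cause} in the sample")
        grid = np.unique(sample.time[ev])
        if max_grid is not None and grid.size > max_grid:
            idx = np.unique(np.linspace(0, grid.size - 1, max_grid).round().astype(int))
            grid = grid[idx]
        self.grid = grid

        cov = sample.covariates
        self.varying_names = ["baseline"] + [t.name for t in formula.varying_terms]
        self.const_names = [t.name for t in formula.constant_terms]
        X = np.column_stack(
            [np.ones(sample.n)] + [t.values(cov) for t in formula.varying_terms]
        )
        Z = (np.column_stack([t.values(cov) for t in formula.constant_terms])
             if formula.constant_terms else np.empty((sample.n, 0)))
        _check_design(X, Z, self.varying_names + self.const_names)
        self.X, self.Z = X, Z

        if formula.cluster is not None:
            if formula.cluster in cov.columns:
                self.cluster_labels = cov[formula.cluster].to_numpy()
            elif sample.cluster is not None:
                self.cluster_labels = sample.cluster
            else:
                raise KeyError(
                    f"cluster variable {formula.cluster!r} not found in sample"
                )
        else:
            self.cluster_labels = None

        strata = (cov[weight_strata].to_numpy() if weight_strata else None)
        ghat = censoring_survival(sample, strata)
        w = ipcw_weights(sample, ghat, strata)
        self._weights_provenance = {
            "stratified_by": weight_strata,
            "estimator": "reverse Kaplan-Meier",
        }
        # IPCW response matrix: R[i, j] = 1{T_i <= t_j, eps_i = cause}/G(T_i-)
        is_k = (sample.status == self.cause).astype(float)
        self.R = (w * is_k)[:, None] * (sample.time[:, None] <= grid[None, :])

    # ------------------------------------------------------------------
    def fit(self, max_iter: int = 100, tol: float = 1e-8) -> "CRRResults":
        """Solve the estimating equations; returns :class:`CRRResults`."""
        X, Z, R = self.X, self.Z, self.R
        n, p = X.shape
        q = Z.shape[1]
        T = self.grid.size

        if self.link == "additive":
            B, gamma = self._fit_additive()
            D = np.ones((n, T))
            n_iter, converged = 1, True
        else:
            B, gamma, n_iter, converged, D = self._fit_proportional(max_iter, tol)
            if not converged:
                raise ConvergenceError(
                    f"estimating equations did not converge in {max_iter} iterations",
                    gamma=gamma, paths=B,
                )

        F = self._fitted_F(B, gamma)
        resid = D * (R - F)  # n x T working residuals

        # gamma-direction time weight: dF/dgamma = z * gt(t) * D
        # (constant effects enter additively as gamma * t, so gt = t there)
        gt = self.grid if self.link == "additive" else np.ones(T)

        # per-time information and its inverse for the varying paths
        J_t = np.einsum("ip,it,iq->tpq", X, D * D, X)
        A_t = np.linalg.inv(J_t)  # T x p x p

        if q:
            XDZ = np.einsum("ip,it,iq->tpq", X, D * D, Z) * gt[:, None, None]
            H_t = A_t @ XDZ  # T x p x q
            resid_g = resid * gt[None, :]
            Ztil_scores = np.einsum("iq,it->iq", Z, resid_g) - np.einsum(
                "tpq,ip,it->iq", H_t, X, resid
            )  # per-subject profile score for gamma, summed over grid
            J_gamma = (np.einsum("iq,it,ir->qr", Z, (D * D) * (gt**2)[None, :], Z)
                       - np.einsum("tpq,tpr->qr", XDZ, H_t))
            bread = np.linalg.inv(J_gamma)
            psi = Ztil_scores
            if self.cluster_labels is not None:
                psi_g = pd.DataFrame(psi).groupby(self.cluster_labels).sum().to_numpy()
            else:
                psi_g = psi
            meat = psi_g.T @ psi_g
            vcov = bread @ meat @ bread
            meat_naive = psi.T @ psi
            vcov_naive = bread @ meat_naive @ bread
        else:
            H_t = np.zeros((T, p, 0))
            J_gamma = np.zeros((0, 0))
            bread = np.zeros((0, 0))
            vcov = np.zeros((0, 0))
            vcov_naive = np.zeros((0, 0))
            psi = np.zeros((n, 0))

        return CRRResults(
            model=self,
            paths=B,
            gamma=gamma,
            vcov_gamma=vcov,
            vcov_gamma_naive=vcov_naive,
            converged=converged,
            n_iter=n_iter,
            _A_t=A_t,
            _H_t=H_t,
            _bread=bread,
            _resid=resid,
            _psi=psi,
        )

    # ------------------------------------------------------------------
    def _fitted_F(self, B, gamma):
        if self.link == "additive":
            F = self.X @ B.T
            if gamma.size:
                F = F + np.outer(self.Z @ gamma, self.grid)
            return F
        eta = self.X @ B.T
        if gamma.size:
            eta = eta + (self.Z @ gamma)[:, None]
        return _inv_cloglog(eta)

    def _fit_additive(self):
        X, Z, R, t = self.X, self.Z, self.R, self.grid
        XtX_inv = np.linalg.inv(X.T @ X)
        if Z.shape[1]:
            P = X @ XtX_inv @ X.T
            MZ = Z - P @ Z
            lhs = (MZ.T @ Z) * np.sum(t**2)
            rhs = MZ.T @ (R @ t)
            gamma = np.linalg.solve(lhs, rhs)
            B = (XtX_inv @ X.T @ (R - np.outer(Z @ gamma, t))).T
        else:
            gamma = np.zeros(0)
            B = (XtX_inv @ X.T @ R).T
        return B, gamma

    def _fit_proportional(self, max_iter, tol):
        X, Z, R, grid = self.X, self.Z, self.R, self.grid
        n, p = X.shape
        q = Z.shape[1]
        T = grid.size
        fbar = np.clip(R.mean(axis=0), 1e-6, 1 - 1e-6)
        B = np.zeros((T, p))
        B[:, 0] = _cloglog(np.maximum.accumulate(fbar))
        gamma = np.zeros(q)

        def eta_of(B, gamma):
            eta = X @ B.T
            if q:
                eta = eta + (Z @ gamma)[:, None]
            return np.clip(eta, _ETA_MIN, _ETA_MAX)

        converged = False
        for it in range(1, max_iter + 1):
            # paths update given gamma (batched damped Gauss-Newton)
            for _ in range(50):
                eta = eta_of(B, gamma)
                ex = np.exp(eta)
                F = -np.expm1(-ex)
                D = ex * np.exp(-ex)
                score = np.einsum("ip,it->tp", X, D * (R - F))
                J = np.einsum("ip,it,iq->tpq", X, D * D, X)
                J[:, np.arange(p), np.arange(p)] += 1e-10
                step = np.linalg.solve(J, score[..., None])[..., 0]
                step = np.clip(step, -2.0, 2.0)  # damping
                B = B + step
                if np.max(np.abs(step)) < tol:
                    break
            if not q:
                converged = True
                n_iter = it
                break
            eta = eta_of(B, gamma)
            ex = np.exp(eta)
            F = -np.expm1(-ex)
            D = ex * np.exp(-ex)
            resid = D * (R - F)
            J_t = np.einsum("ip,it,iq->tpq", X, D * D, X)
            J_t[:, np.arange(p), np.arange(p)] += 1e-10
            A_t = np.linalg.inv(J_t)
            XDZ = np.einsum("ip,it,iq->tpq", X, D * D, Z)
            H_t = A_t @ XDZ
            score_g = (np.einsum("iq,it->q", Z, resid)
                       - np.einsum("tpq,ip,it->q", H_t, X, resid))
            J_g = (np.einsum("iq,it,ir->qr", Z, D * D, Z)
                   - np.einsum("tpq,tpr->qr", XDZ, H_t))
            step_g = np.linalg.solve(J_g, score_g)
            step_g = np.clip(step_g, -1.0, 1.0)
            gamma = gamma + step_g
            if np.max(np.abs(step_g)) < tol:
                converged = True
                n_iter = it
                break
        else:
            n_iter = max_iter
        eta = eta_of(B, gamma)
        ex = np.exp(eta)
        D = ex * np.exp(-ex)
        return B, gamma, n_iter, converged, D


# ----------------------------------------------------------------------
@dataclass
class TimeInvarianceResult:
    """Supremum-test of a constant effect over time."""

    term: str
    statistic: float
    pvalue: float
    n_resample: int
    null_draws: np.ndarray

    def __repr__(self):  # pragma: no cover - cosmetic
        return (f"<TimeInvarianceResult term={self.term!r} "
                f"sup-stat={self.statistic:.4f} p={self.pvalue:.4f}>")


class CRRResults:
    """Fitted competing-risks regression.

    Attributes
    ----------
    paths
        ``(T, p)`` array of time-varying coefficient functions ``B(t)``
        on the model grid (column 0 is the baseline).
    gamma
        Constant (``const()``) coefficient estimates.
    bse, pvalues
        Cluster-robust standard errors and Wald p-values for ``gamma``.
    """

    def __init__(self, model, paths, gamma, vcov_gamma, vcov_gamma_naive,
                 converged, n_iter, _A_t, _H_t, _bread, _resid, _psi):
        self.model = model
        self.grid = model.grid
        self.link = model.link
        self.paths = paths
        self.gamma = gamma
        self.vcov_gamma = vcov_gamma
        self.vcov_gamma_naive = vcov_gamma_naive
        self.converged = converged
        self.n_iter = n_iter
        self.weights_provenance = model._weights_provenance
        self._A_t = _A_t
        self._H_t = _H_t
        self._bread = _bread
        self._resid = _resid
        self._psi = _psi

    # -- constant coefficients -----------------------------------------
    @property
    def params_const(self) -> pd.Series:
        return pd.Series(self.gamma, index=self.model.const_names)

    @property
    def bse(self) -> pd.Series:
        se = np.sqrt(np.diag(self.vcov_gamma)) if self.gamma.size else np.array([])
        return pd.Series(se, index=self.model.const_names)

    @property
    def bse_naive(self) -> pd.Series:
        se = (np.sqrt(np.diag(self.vcov_gamma_naive))
              if self.gamma.size else np.array([]))
        return pd.Series(se, index=self.model.const_names)

    @property
    def pvalues(self) -> pd.Series:
        if not self.gamma.size:
            return pd.Series(dtype=float)
        z = self.gamma / self.bse.to_numpy()
        return pd.Series(2 * norm.sf(np.abs(z)), index=self.model.const_names)

    def paths_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.paths, index=pd.Index(self.grid, name="time"),
                            columns=self.model.varying_names)

    # -- multiplier (wild) bootstrap -----------------------------------
    def _multiplier_draws(self, n_resample: int, seed=None):
        """One-step multiplier-bootstrap perturbations of (paths, gamma).

        Returns ``(d_gamma (B, q), d_paths (B, T, p))`` from i.i.d.
        standard normal subject-level multipliers applied to the profiled
        estimating-equation influence functions.
        """
        rng = np.random.default_rng(seed)
        n = self.model.X.shape[0]
        xi = rng.standard_normal((n_resample, n))
        q = self.gamma.size
        if q:
            d_gamma = (xi @ self._psi) @ self._bread.T  # B x q
        else:
            d_gamma = np.zeros((n_resample, 0))
        # path scores: S_b[t] = X' (xi o resid[:, t])  -> B x T x p
        Xr = self.model.X
        S = np.einsum("bi,it,ip->btp", xi, self._resid, Xr, optimize=True)
        d_paths = np.einsum("tpq,btq->btp", self._A_t, S, optimize=True)
        if q:
            d_paths = d_paths - np.einsum("tpq,bq->btp", self._H_t, d_gamma,
                                          optimize=True)
        return d_gamma, d_paths

    def varying_ci(self, n_resample: int = 1000, seed=None, alpha: float = 0.05):
        """Pointwise resampling CIs for the time-varying paths.

        Returns a dict ``term -> DataFrame(time, estimate, lo, hi)``.
        """
        _, d_paths = self._multiplier_draws(n_resample, seed)
        z = norm.ppf(1 - alpha / 2)
        se = d_paths.std(axis=0, ddof=1)  # T x p
        out = {}
        for j, name in enumerate(self.model.varying_names):
            out[name] = pd.DataFrame({
                "time": self.grid,
                "estimate": self.paths[:, j],
                "se": se[:, j],
                "ci_lower": self.paths[:, j] - z * se[:, j],
                "ci_upper": self.paths[:, j] + z * se[:, j],
            })
        return out

    # -- prediction ----------------------------------------------------
    def predict_cif(self, profile: dict, n_resample: int = 200,
                    seed=None, alpha: float = 0.05) -> CIFCurve:
        """Model-implied CIF for a covariate profile.

        The profile must assign a value to every covariate appearing in
        the formula.  Additive-link predictions are clamped to [0, 1];
        ``curve.clamped`` records whether clamping was active.  Pointwise
        standard errors come from the multiplier bootstrap.
        """
        needed = {c for t in self.model.formula.terms for c in t.components}
        missing = needed - set(profile)
        if missing:
            raise KeyError(f"profile is missing covariates: {sorted(missing)}")

        def term_val(term: Term) -> float:
            v = 1.0
            for c in term.components:
                v *= float(profile[c])
            return v

        x0 = np.array([1.0] + [term_val(t)
                               for t in self.model.formula.varying_terms])
        z0 = np.array([term_val(t) for t in self.model.formula.constant_terms])

        if self.link == "additive":
            raw = self.paths @ x0
            if z0.size:
                raw = raw + (z0 @ self.gamma) * self.grid
            f = np.clip(raw, 0.0, 1.0)
            clamped = bool(np.any(raw != f))
        else:
            eta = self.paths @ x0
            if z0.size:
                eta = eta + float(z0 @ self.gamma)
            f = _inv_cloglog(eta)
            clamped = False

        d_gamma, d_paths = self._multiplier_draws(n_resample, seed)
        d_lin = d_paths @ x0  # B x T
        if z0.size:
            if self.link == "additive":
                d_lin = d_lin + np.outer(d_gamma @ z0, self.grid)
            else:
                d_lin = d_lin + (d_gamma @ z0)[:, None]
        if self.link == "proportional":
            # delta method through the cloglog inverse
            ex = np.exp(np.clip(self.paths @ x0 + (z0 @ self.gamma if z0.size else 0),
                                _ETA_MIN, _ETA_MAX))
            d_lin = d_lin * (ex * np.exp(-ex))[None, :]
        var = d_lin.var(axis=0, ddof=1)
        z = norm.ppf(1 - alpha / 2)
        se = np.sqrt(var)
        curve = CIFCurve(self.grid, f, var,
                         np.clip(f - z * se, 0, 1), np.clip(f + z * se, 0, 1),
                         cause=self.model.cause)
        curve.clamped = clamped
        return curve

    # -- tests ---------------------------------------------------------
    def test_time_invariance(self, term: str, n_resample: int = 1000,
                             seed=None, min_events: int = 10) -> TimeInvarianceResult:
        """Supremum test of H0: the effect of ``term`` is constant in time.

        Compares the fitted path ``B_j(t)`` to its inverse-variance
        weighted constant approximation through the standardised process
        ``|B_j(t) - c| / se_j(t)``; the null distribution of its
        supremum comes from the multiplier bootstrap.  The supremum runs
        over grid times after at least ``min_events`` target-cause
        events have accrued (the path is too unstable before that for
        the Gaussian approximation).  Deterministic for a fixed seed.
        """
        if n_resample < 50:
            raise ValueError("n_resample must be >= 50 for a stable null")
        if term not in self.model.varying_names:
            raise KeyError(
                f"term {term!r} is not a time-varying term of this fit "
                f"(have {self.model.varying_names})"
            )
        j = self.model.varying_names.index(term)
        path = self.paths[:, j]
        _, d_paths = self._multiplier_draws(n_resample, seed)
        draws = d_paths[:, :, j]
        se = draws.std(axis=0, ddof=1)
        sample = self.model.sample
        ev_times = np.sort(sample.time[sample.status == self.model.cause])
        n_acc = np.searchsorted(ev_times, self.grid, side="right")
        keep = (n_acc >= min_events) & (se > 0)
        if keep.sum() < 3:
            keep = se > 0
        w = 1.0 / se[keep] ** 2
        c = float(np.sum(w * path[keep]) / np.sum(w))
        stat = float(np.max(np.abs(path[keep] - c) / se[keep]))
        dk = draws[:, keep]
        c_star = (dk * w).sum(axis=1) / np.sum(w)
        null = np.max(np.abs(dk - c_star[:, None]) / se[keep], axis=1)
        p = (1.0 + np.sum(null >= stat)) / (n_resample + 1.0)
        return TimeInvarianceResult(term, stat, float(p), n_resample, null)

    # -- reporting -----------------------------------------------------
    def summary(self) -> str:
        lines = [
            "Competing-risks regression",
            f"  formula: {self.model.formula.unparse()}",
            f"  cause:   {self.model.cause}    link: {self.link}",
            f"  n obs:   {self.model.sample.n}    grid points: {self.grid.size}",
            f"  converged: {self.converged} ({self.n_iter} iterations)",
            f"  IPCW weights: {self.weights_provenance['estimator']}"
            + (f", stratified by {self.weights_provenance['stratified_by']}"
               if self.weights_provenance["stratified_by"] else ""),
        ]
        if self.gamma.size:
            lines.append("")
            lines.append("  Constant coefficients (cluster-robust SE):"
                         if self.model.cluster_labels is not None
                         else "  Constant coefficients (robust SE):")
            lines.append(f"  {'term':<22}{'coef':>10}{'se':>10}{'z':>8}{'P>|z|':>10}")
            for name, g, s, pv in zip(self.model.const_names, self.gamma,
                                      self.bse, self.pvalues):
                zval = g / s if s > 0 else np.nan
                lines.append(f"  {name:<22}{g:>10.4f}{s:>10.4f}{zval:>8.2f}{pv:>10.4g}")
        if len(self.model.varying_names):
            lines.append("")
            lines.append("  Time-varying terms (value at last grid time):")
            for j, name in enumerate(self.model.varying_names):
                lines.append(f"  {name:<22}{self.paths[-1, j]:>10.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-ready serialization of the fit."""
        return {
            "formula": self.model.formula.unparse(),
            "cause": self.model.cause,
            "link": self.link,
            "converged": self.converged,
            "n_iter": self.n_iter,
            "grid": self.grid.tolist(),
            "varying_names": self.model.varying_names,
            "paths": self.paths.tolist(),
            "const_names": self.model.const_names,
            "gamma": self.gamma.tolist(),
            "gamma_se": self.bse.tolist(),
            "gamma_p": self.pvalues.tolist(),
            "weights": self.weights_provenance,
        }


# ----------------------------------------------------------------------
def threshold_scan(
    sample: CRSample,
    intensity_covariate: str,
    partner_covariate: str,
    grid,
    alpha: float = 0.05,
    cause: int = 1,
    link: str = "proportional",
    max_grid: int | None = 40,
) -> dict:
    """Scan candidate intensity thresholds for loss of a partner effect.

    For each candidate ``g`` the model ``CIF ~ 1 + const(partner)`` is
    fitted on the sub-threshold subset (intensity below ``g``); the
    selected threshold is the largest ``g`` whose sub-threshold partner
    effect is non-significant at ``alpha``.  When even the full data show
    no partner effect there is no threshold to find and the selection is
    flagged unstable.

    Returns a dict with the scan table, the selected threshold and the
    selection rule.
    """
    intensity = pd.to_numeric(sample.covariates[intensity_covariate]).to_numpy()
    grid = np.asarray(grid, dtype=float)
    if grid.min() < intensity.min() or grid.max() > intensity.max():
        raise ValueError("threshold grid extends outside the observed "
                         "intensity range")
    rows = []
    for g in np.sort(grid):
        sub = sample.subset(intensity < g)
        try:
            fit = CompetingRisksRegression(
                sub, f"CIF ~ 1 + const({partner_covariate})",
                cause=cause, link=link, max_grid=max_grid,
            ).fit()
            coef = float(fit.params_const.iloc[0])
            pval = float(fit.pvalues.iloc[0])
        except (ValueError, np.linalg.LinAlgError, ConvergenceError):
            coef, pval = np.nan, np.nan
        rows.append({"threshold": g, "partner_coef": coef, "partner_p": pval})
    scan = pd.DataFrame(rows)
    ok = scan["partner_p"].notna()
    nonsig = scan.loc[ok & (scan["partner_p"] >= alpha), "threshold"]
    selected = float(nonsig.max()) if len(nonsig) else None
    top_p = scan.loc[ok, "partner_p"].iloc[-1] if ok.any() else np.nan
    unstable = bool(np.isnan(top_p) or top_p >= alpha)
    return {
        "scan": scan,
        "threshold": selected,
        "unstable": unstable,
        "rule": (f"largest candidate with sub-threshold partner p >= {alpha}"),
        "alpha": alpha,
    }
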