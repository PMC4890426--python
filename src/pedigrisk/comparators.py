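"""Classical (complete-case) statistics for side-by-side comparison.

These are the contemporary methods commonly applied to cell lifetime
data: mean-time comparisons by Student's t-test, Pearson and intraclass
correlation of kin pairs, Yule's Q and the binomial test on fate
concordance, and the random-re-pairing permutation test.  All of them
exclude right-censored (and, for the correlation measures, discordant)
outcomes, which is exactly the selection bias the competing-risks
machinery in the rest of the package avoids; they are provided so the
bias can be demonstrated on the same data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .concordance import PairedCRSample

__all__ = [
    "ComparatorResult",
    "PermutationResult",
    "mean_time_comparison",
    "pearson_kin",
    "icc_kin",
    "yules_q",
    "permutation_test",
    "binomial_concordance_test",
]


@dataclass
class ComparatorResult:
    """Estimate, CI, test and records-used accounting for one method."""

    method: str
    estimate: float
    ci: tuple[float, float] | None
    statistic: float | None
    pvalue: float | None
    n_used: int
    n_total: int

    @property
    def fraction_used(self) -> float:
        return self.n_used / self.n_total if self.n_total else 0.0


@dataclass
class PermutationResult:
    """Observed vs. randomly re-paired mean absolute time difference."""

    observed: float  # mean |t1 - t2| over true pairs, hours
    null_mean: float
    null_sd: float
    statistic: float  # (null_mean - observed) / null_sd
    pvalue: float  # empirical, (1 + #{null <= observed}) / (n_perm + 1)
    n_perm: int
    seed: int | None
    n_used: int
    n_total: int


def _complete_pairs(pairs: PairedCRSample, event: int):
    both = (pairs.status1 == event) & (pairs.status2 == event)
    return pairs.time1[both], pairs.time2[both], int(both.sum())


def mean_time_comparison(sample_a, sample_b, cause: int = 1) -> ComparatorResult:
    """Complete-case mean time-to-fate comparison (two-tailed Student t).

    Only records with the realised fate of interest enter; censored and
    competing outcomes are excluded, which biases the means toward
    shorter lifetimes when long lifetimes are censored.
    """
    ta = sample_a.time[sample_a.status == cause]
    tb = sample_b.time[sample_b.status == cause]
    if ta.size < 2 or tb.size < 2:
        raise ValueError("each group needs >= 2 complete cases")
    t, p = stats.ttest_ind(ta, tb, equal_var=True)
    diff = float(ta.mean() - tb.mean())
    se = np.sqrt(ta.var(ddof=1) / ta.size + tb.var(ddof=1) / tb.size)
    ci = (diff - 1.96 * se, diff + 1.96 * se)
    n_tot = sample_a.n + sample_b.n
    return ComparatorResult("mean_time_ttest", diff, ci, float(t), float(p),
                            int(ta.size + tb.size), n_tot)


def pearson_kin(pairs: PairedCRSample, event: int = 1,
                seed=None) -> ComparatorResult:
    """Pearson correlation of times for pairs where both members realised
    the event (complete-case; single entry per unordered pair, member
    order randomised by ``seed``)."""
    x, y, n = _complete_pairs(pairs, event)
    if n < 3:
        raise ValueError(f"only {n} usable pairs (< 3)")
    rng = np.random.default_rng(seed)
    flip = rng.uniform(size=n) < 0.5
    x, y = np.where(flip, y, x), np.where(flip, x, y)
    r, p = stats.pearsonr(x, y)
    if n > 3:
        zr = np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12))
        half = 1.96 / np.sqrt(n - 3)
        ci = (float(np.tanh(zr - half)), float(np.tanh(zr + half)))
    else:
        ci = (-1.0, 1.0)  # Fisher-z interval undefined at n = 3
    return ComparatorResult("pearson", float(r), ci, None, float(p),
                            n, pairs.n_pairs)


def icc_kin(pairs: PairedCRSample, event: int = 1,
            alpha: float = 0.05) -> ComparatorResult:
    """One-way random-effects intraclass correlation, ICC(1,1).

    Computed on order-symmetrised complete-case pairs via the one-way
    ANOVA decomposition with two members per pair:
    ``ICC = (MSB - MSW) / (MSB + MSW)``; the CI uses the F distribution.
    """
    x, y, n = _complete_pairs(pairs, event)
    if n < 3:
        raise ValueError(f"only {n} usable pairs (< 3)")
    vals = np.stack([x, y], axis=1)
    grand = vals.mean()
    pair_means = vals.mean(axis=1)
    msb = 2.0 * np.sum((pair_means - grand) ** 2) / (n - 1)
    msw = np.sum((vals - pair_means[:, None]) ** 2) / n
    if msw == 0:  # identical members in every pair
        return ComparatorResult("icc", 1.0, (1.0, 1.0), np.inf, 0.0,
                                n, pairs.n_pairs)
    icc = (msb - msw) / (msb + msw)
    f_obs = msb / msw
    df1, df2 = n - 1, n
    f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
    f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
    ci = ((f_l - 1) / (f_l + 1), (f_u - 1) / (f_u + 1))
    p = float(stats.f.sf(f_obs, df1, df2))
    return ComparatorResult("icc", float(icc), ci, float(f_obs), p,
                            n, pairs.n_pairs)


def yules_q(pair_fate_table) -> ComparatorResult:
    """Yule's Q from a 2x2 table of pair fates.

    The table rows/cols are the two fates; concordant pairs sit on the
    diagonal (``a`` = both fate A, ``d`` = both fate B), discordant off
    it.  ``Q = (ad - bc) / (ad + bc)``; SE by the standard formula.
    Censored-containing pairs must be excluded upstream.
    """
    tab = np.asarray(pair_fate_table, dtype=float)
    if tab.shape != (2, 2):
        raise ValueError("pair_fate_table must be 2x2")
    a, b = tab[0]
    c, d = tab[1]
    denom = a * d + b * c
    if denom == 0:
        raise ValueError("Yule's Q undefined: ad + bc = 0")
    q = (a * d - b * c) / denom
    if np.all(tab > 0):
        se = 0.5 * (1 - q**2) * np.sqrt(np.sum(1.0 / tab))
    else:
        se = np.nan  # |Q| = 1: the large-sample SE formula degenerates
    z = q / se if np.isfinite(se) and se > 0 else np.inf
    p = float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    n = int(tab.sum())
    ci = (max(-1.0, q - 1.96 * se), min(1.0, q + 1.96 * se)) \
        if np.isfinite(se) else None
    return ComparatorResult("yules_q", float(q), ci, float(z) if np.isfinite(z)
                            else np.nan, p, n, n)


def permutation_test(pairs: PairedCRSample, n_perm: int = 10000,
                     seed=None, event: int = 1) -> PermutationResult:
    """Random re-pairing test of within-pair synchrony.

    The observed statistic is the mean absolute difference in time to
    the event across true (complete-case) pairs; the null distribution
    re-pairs the pooled member times uniformly at random ``n_perm``
    times.  Reports the null mean and SD, the standardised statistic
    ``t = (mu_null - observed)/sd_null``, and the empirical one-sided
    p-value ``(1 + #{null <= observed}) / (n_perm + 1)``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    x, y, n = _complete_pairs(pairs, event)
    if n < 3:
        raise ValueError(f"only {n} usable pairs (< 3)")
    observed = float(np.mean(np.abs(x - y)))
    pool = np.concatenate([x, y])
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(pool)
        null[b] = np.mean(np.abs(perm[:n] - perm[n:]))
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    stat = (mu - observed) / sd if sd > 0 else np.inf
    p = float((1 + np.sum(null <= observed)) / (n_perm + 1))
    return PermutationResult(observed, mu, sd, float(stat), p, n_perm,
                             seed, n, pairs.n_pairs)


def binomial_concordance_test(n_concordant: int, n_total: int,
                              p0: float = 0.5) -> ComparatorResult:
    """Exact two-sided binomial test of fate concordance among
    fate-known pairs against null probability ``p0``."""
    if n_total == 0:
        raise ValueError("n_total must be positive")
    res = stats.binomtest(n_concordant, n_total, p0, alternative="two-sided")
    ci_obj = res.proportion_ci(0.95)
    return ComparatorResult(
        "binomial", n_concordant / n_total, (ci_obj.low, ci_obj.high),
        float(n_concordant), float(res.pvalue), n_total, n_total,
    )
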