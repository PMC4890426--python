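# pedigrisk

Competing-risks and concordance analysis for single-cell pedigree
lifetime data.

Time-lapse imaging with single-cell tracking produces *lifetime
tables*: one row per cell with its birth and end time, its fate
(division, death, loss, end of observation, or a user-defined event
such as differentiation onset) and its position in a lineage tree.
Such data have two features that break the statistics most commonly
applied to them.  Fates **compete** — a cell that divides can never be
observed to die, so per-fate Kaplan-Meier analysis (which treats the
competing fate as independent censoring) overestimates every fate's
probability.  And fates are heavily **right-censored** — complete-case
summaries (mean cycle times, Pearson/ICC correlations of kin, Yule's Q)
silently discard censored and discordant outcomes and are biased toward
short lifetimes and symmetric fates.

`pedigrisk` is a toolkit for biologists and biostatisticians analysing
such data without those biases:

* **Pedigree data model** — reading/writing delimited lifetime tables,
  structural validation, kinship-pair extraction (siblings,
  mother-daughter, first/second cousins with their cluster ids), and
  flattening to competing-risks observations under configurable fate
  codings and time origins.
* **Non-parametric estimation** — the Aalen-Johansen cumulative
  incidence function (CIF) `F_k(t)` for each competing fate,
  Kaplan-Meier survival `S(t)` with Greenwood variance, and the
  reverse-role censoring estimate `G(t)` used for inverse probability
  of censoring weighting (IPCW).
* **Competing-risks regression** — Wilkinson-Rogers formulas
  (`CIF ~ 1 + WT + Dox + WT:Dox + const(GF) + cluster(siblings)`) fitted
  by IPCW binomial estimating equations with time-varying coefficient
  paths `B_j(t)` and constant coefficients `gamma` (additive or
  proportional/Fine-Gray-type link), cluster-robust standard errors,
  multiplier-bootstrap confidence bands, a supremum test of
  time-invariance, CIF prediction for covariate profiles, full
  factorial design helpers and a reporter-intensity threshold scan.
* **Clustered concordance** — IPCW concordance curves
  `H(t) = P(both kin experience the fate by t)`, probandwise
  conditional curves `pi(t) = H(t)/F(t)`, and the cross-odds ratio
  (COR) under a Clayton/gamma-frailty dependence:
  `COR = odds(pi)/odds(F)`, with COR = 1 under independence and
  COR > 1 for concordant fates.
* **The classical comparators** — complete-case t-tests, Pearson, ICC,
  Yule's Q, binomial and permutation tests, each with records-used
  accounting so their selection bias can be quantified side by side.
* **Simulators with ground truth** — bivariate pre-competition
  lifetimes with tunable dependence (demonstrating that pre-competition
  dependence is not identifiable from observed incidence but biases
  per-cause Kaplan-Meier), Clayton-linked kin pairs, frailty-driven
  pedigree forests, and numerical COR oracles for recovery testing.

## Worked example

Simulate a pedigree experiment (150 founders, heritable division
frailty, a treatment that accelerates division), fit a regression for
the division CIF and quantify sibling concordance:

```python
from pedigrisk import (SimConfig, simulate_pedigrees, to_cr_sample,
                       CompetingRisksRegression, extract_kin_pairs,
                       pair_sample, cross_odds_ratio)

cfg = SimConfig(seed=7, n_founders=150, max_generations=5,
                frailty_theta=2.0, frailty_mode="heritable",
                frailty_decay=0.85, treatment_prob=0.5,
                treatment_log_hr=0.5)
forest, latent, manifest = simulate_pedigrees(cfg)

sample, report = to_cr_sample(
    forest, {"division": 1, "death": 2, "lost": 0, "end_of_observation": 0},
    covariates=["treatment"])

fit = CompetingRisksRegression(sample, "CIF ~ 1 + const(treatment)",
                               cause=1, max_grid=50).fit()
print(fit.summary())

paired = pair_sample(sample, extract_kin_pairs(forest, "sibling"))
print(cross_odds_ratio(paired, 1, n_resample=300, seed=1).summary())
```

Output:

```
Competing-risks regression
  formula: CIF ~ 1 + const(treatment)
  cause:   1    link: proportional
  n obs:   1758    grid points: 50
  converged: True (4 iterations)
  IPCW weights: reverse Kaplan-Meier

  Constant coefficients (robust SE):
  term                        coef        se       z     P>|z|
  const(treatment)          0.2349    0.0815    2.88  0.003946

  Time-varying terms (value at last grid time):
  baseline                  0.4183

Cross-odds ratio (Clayton/gamma-frailty dependence)
  relation: sibling    cause: 1    pairs: 879
  COR      = 2.277   95% CI [1.606, 3.228]
  log(COR) = 0.823 +/- 0.178 (SE)
  theta    = 0.365
  H0 COR = 1: p = 3.825e-06   (300 bootstrap replicates)
```

The constant coefficient 0.23 (robust SE 0.08) is the treatment's
log-scale effect on the cumulative subdistribution hazard of division —
treated cells divide sooner, p = 0.004.  The sibling COR of 2.28 (95%
CI 1.61-3.23) says a cell's odds of having divided by time *t* are
about 2.3-fold higher if its sibling has divided by then — strong
heritable concordance, detected while *keeping* every censored cell in
the analysis.  The conversion report shows what the complete-case
alternatives would have discarded.

The same analyses are scriptable from a shell:

```
pedigrisk simulate --seed 7 --out table.csv
pedigrisk validate table.csv
pedigrisk crr table.csv --formula "CIF ~ 1 + const(treatment)" --cause division
pedigrisk concordance table.csv --relation sibling --cause division --seed 1
pedigrisk compare table.csv --relation sibling --n-perm 10000 --seed 1
```

Every run writes a manifest (options, seed, version) next to its
outputs; identical seeds give byte-identical outputs.

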