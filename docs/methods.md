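# Methods

`pedigrisk` analyses single-cell lifetime data: one record per tracked
cell with its birth and end times (hours from experiment start), a fate
label and its position in a lineage tree.  Fates compete — a cell that
divides cannot later be seen to die — and many fates are right-censored
(cell lost, or observation ended).  This note records the statistical
models implemented, the estimators' conventions, what the simulators do
and do not emulate, and the design choices made where several
reasonable options existed.

## Data model

A pedigree forest is a set of binary lineage trees.  `lost` and
`end_of_observation` are the two fixed right-censoring fates; every
other label (division, death, user-defined events such as
differentiation onset) is an event.  Kinship relations are defined by
the nearest common ancestor: siblings share a parent, first cousins a
grandparent (but not a parent), second cousins a great-grandparent (but
not a grandparent).  The cluster id of a kin pair is that common
ancestor, so the cross pairs of a four-cell cousin cluster share one
cluster and can be grouped for cluster-robust inference.

Times in files are absolute; analyses choose an origin when a forest is
flattened to competing-risks observations: `cell_birth` (lifetime
scale; founders with unknown birth are excluded and counted) or
`ancestor_stimulus` (time from experiment start, used for events such
as differentiation onset that are timed from when the ancestors
received the stimulus).  Founders observed from experiment start are
analysed separately through generation filters rather than by left
truncation, mirroring how generation-0 and generation>0 fits are kept
apart.

## Non-parametric estimators

All-cause survival is Kaplan-Meier with Greenwood variance and
log(-log) confidence limits; the cause-k cumulative incidence is
Aalen-Johansen, `F_k(t) = sum S(t_i-) d_ki / n_i`, with the
Dinse-Larson variance and complementary-log-log limits.  Ties between
an event and a censoring at the same time are resolved event-first.
Two algebraic identities hold exactly under these conventions and are
enforced by tests: the cause CIFs and all-cause survival sum to one at
every event time, and the IPCW representation
`(1/n) sum 1{T_i<=t, eps_i=k} / G(T_i-)` — with `G` the reverse-role
Kaplan-Meier of censoring — reproduces Aalen-Johansen to machine
precision.  The latter identity is what makes the baseline-only
regression fit collapse to the non-parametric estimate.

The per-cause Kaplan-Meier that treats competing events as censoring is
implemented deliberately (behind an explicit flag) for bias
demonstrations: `1 - KM_k(t)` dominates `F_k(t)` everywhere.

## Competing-risks regression

The regression models the cause-k CIF directly through IPCW binomial
estimating equations on a grid of event times (direct binomial
regression in the Scheike-Zhang tradition).  The response is
`R_i(t) = 1{T_i <= t, eps_i = k} / G(T_i-)`; the estimating equation at
each grid time is `sum_i x_i D_i (R_i(t) - F(t | x_i, z_i)) = 0`.

Two link functions:

* **additive** — `F(t|x,z) = x'B(t) + (z'gamma) t`.  Time-varying
  effects add to the baseline CIF on the probability scale and the fit
  is closed-form weighted least squares; constant effects grow linearly
  in time (units: probability per hour).  Predictions are clamped to
  [0, 1] with a clamp flag.
* **proportional** — `cloglog F(t|x,z) = x'B(t) + z'gamma`, a
  Fine-Gray-type proportional effect on the subdistribution scale;
  constant coefficients are log-scale factors.  Solved by damped
  Gauss-Newton, batched across grid times, profiling constant terms in
  an outer loop (tolerance 1e-8, at most 100 iterations; non-convergence
  raises an error carrying the last iterate).

The default link is proportional when the formula has `const()` terms
and otherwise whatever the caller sets (additive for purely
non-parametric fits); both are always available.  The grid is the set
of observed event times of the target cause; fits used in large
simulation studies thin it to at most 50-60 evenly spaced order
statistics, which changes third-decimal details only.  Censoring
weights may be stratified by an experimental-group covariate
(`weight_strata`), recommended whenever censoring intensity differs
across treatments.

Constant coefficients get profile-corrected sandwich standard errors
(cluster-aggregated when a `cluster()` term is present; the
uncertainty of the estimated censoring weights is ignored, which is
mildly conservative).  Time-varying paths get pointwise confidence
bands from a multiplier (wild) bootstrap of the estimating-equation
influence functions — the same machinery drives prediction standard
errors and the time-invariance test.

**Time-invariance test.**  `sup_t |B_j(t) - c| / se_j(t)` where `c` is
the inverse-variance-weighted grid average and the null distribution
comes from the multiplier bootstrap (default 1000 replicates, seeded).
The supremum runs over grid times after at least 10 target-cause events
have accrued; before that the cloglog-scale path is so unstable that
the Gaussian approximation fails badly.  Simulations at n = 300 show
type-I error within binomial error of the nominal 5% and power near 1
against a sign-reversing effect at n = 1500.

**Threshold scan.**  For classifying reporter-positive cells, the scan
fits `CIF ~ 1 + const(partner)` on each sub-threshold subset and
selects the largest candidate whose partner effect is non-significant;
if even the full data show no partner effect the selection is flagged
unstable.  Multiple testing across the scan is deliberately not
adjusted; the scan is exploratory and the selection rule is recorded in
the output.

No multiple-testing correction is applied anywhere: the package reports
unadjusted p-values, documented here.

## Concordance and the cross-odds ratio

For kin pairs the concordance probability
`H(t) = P(T1<=t, eps1=k, T2<=t, eps2=k)` is estimated by IPCW, the
conditional (probandwise) probability is `pi(t) = H(t)/F(t)`, and the
cross-odds ratio `COR(t) = odds(pi(t)) / odds(F(t))` summarises
dependence (1 = independence).

**Censoring within pairs.**  Kin share their end-of-observation time
(tracking stops at one horizon, and siblings are born at the same
parental division) but are lost individually.  When censoring-fate
labels are available the two mechanisms get separate reverse
Kaplan-Meier estimates, each stratified by generation because the
remaining observation time depends on when a cell was born.  A pair is
then weighted by `1 / [G_sh(max(T1,T2)-) G_in(T1-) G_in(T2-)]`; the
marginal CIF uses member-level weights.  For pairs built outside a
pedigree (`censoring="independent"`, e.g. the Clayton pair simulator)
the weight is the product of member weights.  Simulations at zero
frailty confirm the sibling estimator is unbiased (mean log-COR 0.02
against sd 0.07 across replicates).  Limitation: cousins are born at
different times, so the shared-horizon weight is an approximation for
them; at the simulator's censoring levels it biases cousin CORs
downward by roughly 4-6%, an order of magnitude below the frailty
signals the ordering analyses target, but it means small cousin-vs-
cousin differences should not be over-interpreted.

**Dependence model.**  The two members' cause-k sub-distributions are
linked by a Clayton (gamma-frailty) copula,
`H(t) = (F1^-theta + F2^-theta - 1)^(-1/theta)` (evaluated in log space
so strong dependence does not overflow; `theta` may be negative down to
-0.6 to allow discordance).  Estimation is two-stage: the marginal CIF
first (non-parametric pooled, or covariate-adjusted through a fitted
regression with per-member profiles), then `theta` by a pairwise moment
estimating equation matching the observed concordance curve on a grid.
Because the Clayton COR profile varies over time (diverging as F -> 0),
the reported scalar is its time-average over a grid tied to marginal
quantiles — the times where the marginal CIF first reaches 5%, 10%, ...,
95% of its terminal value.  Tying the grid to quantiles makes the
estimand well-defined and identical to the convention used by the
theoretical oracle, so simulation recovery is a like-for-like
comparison.  Standard errors propagate both stages through a seeded
cluster bootstrap (default 500 replicates) holding the censoring
estimate fixed (slightly conservative); the independence test is Wald
on log COR.  Both reporting scales (log COR with SE, and the
exponentiated COR) are carried, since either may be the one quoted in a
given table.

**Oracle.**  `theoretical_cor` evaluates the COR profile implied by a
Clayton dependence either in closed form or by numerical integration of
the gamma-frailty mixture (two independent routes, agreeing to 1e-9);
`cor_to_theta` inverts the time-averaged profile so simulation studies
can be pinned at, say, COR = 5.

## Classical comparators

Student's t on complete-case mean times, Pearson correlation
(single-entry unordered pairs, member order randomised by seed — the
statistic is not order-symmetric and published analyses rarely state
which order was used), one-way random-effects ICC(1,1) via the two-member
ANOVA decomposition (order-symmetric by construction), Yule's Q with
its standard error (undefined CI at |Q| = 1), an exact binomial
concordance test, and a permutation test whose null re-pairs the pooled
member times uniformly at random.  The permutation statistic is
standardised as `(mu_null - observed) / sd_null` and the empirical
p-value is `(1 + #{null <= observed}) / (n_perm + 1)`.  Each comparator
reports its records-used accounting, consistent with the `data_usage`
rules: correlation-type methods use only pairs where both members
realised the concordant fate, the categorical methods use pairs with
both fates known, and competing-risks analysis uses every record.

## Simulators

All generators are bitwise-reproducible given (seed, config), always
emit structurally valid forests, and keep their latent tables
(pre-competition times, frailties) for oracle checks.

* **Pre-competition pairs** (identifiability demonstration): latent
  division and death times under a Gaussian copula with correlation
  `rho`; the earlier latent event is observed, times beyond the 72 h
  horizon are censored.  The printed generating distributions for this
  kind of demonstration are rarely recoverable, so the defaults were
  chosen once for the demonstration to be clean: lognormal division
  times (median 18 h, sigma 0.45) and a later, wider death marginal
  (median 55 h, sigma 0.55).  With division dominating, the observed
  incidence functions are nearly invariant to `rho` (sup-norm ~0.02
  between rho 0.39 and 0.96 at n = 5000, using common random numbers),
  while the per-cause Kaplan-Meier of the heavily competitor-censored
  death fate shifts by >0.2.  Strongly overlapping marginals would make
  the observed incidences themselves rho-dependent and the
  demonstration would not hold — the near-invariance is a property of
  the chosen regime, not of competing-risks data in general.
* **Clayton pairs**: both members' outcomes derive from one uniform
  each, the pair of uniforms following a Clayton copula, so the joint
  cause-k sub-distribution is exactly `C_theta(F(t), F(s))` — the same
  family the estimator assumes, making these pairs the recovery oracle.
  Censoring is independent per member (exponential plus horizon).
* **Pedigree forests**: founders plated at time 0 with unknown birth;
  per-cell latent Weibull division times (shape 3 — concentrated cycle
  times with CV ~0.36, as observed cycle-time distributions are far
  from exponential), exponential death and optional differentiation
  onset; binary division up to a generation cap; administrative
  censoring at the horizon and independent exponential loss.  A mean-1
  gamma frailty with variance `theta` multiplies the cumulative hazards
  of the configured causes.  Two sharing modes:
  `shared` — the frailty is the draw made by the ancestor at the
  configured depth (parent/grandparent/great-grandparent), so all kin
  below that ancestor are equally concordant and more distant kin are
  independent; `heritable` — the frailty follows a beta-thinning gamma
  autoregression along the lineage (exact Gamma(1/theta, theta)
  marginal, per-generation autocorrelation `frailty_decay`), so kin
  correlation decays as `decay^(branch distance)`.  A single
  shared-level draw cannot produce a strictly decreasing
  sibling > cousin1 > cousin2 pattern (kin under the sharing ancestor
  are exchangeable), which is why the heritable mode exists: it is the
  generative mechanism behind the ordering analyses, consistent with
  inheritance being diluted at each division.  Covariates: a
  per-pedigree treatment flag acting log-linearly on the division
  hazard, and a heritable fluorescence intensity.

What the generators do **not** emulate: measurement error in times
(frames are continuous here), track re-identification errors,
within-lifetime covariate dynamics, mother-daughter asymmetries in
inherited state, or crowding/contact effects.  Passing recovery tests
therefore demonstrates estimator correctness under the stated
mechanisms, not robustness to those artefacts.

## Study conditions used by the acceptance checks

Simulation sizes were fixed once: 100 random samples for the estimator
identities; n = 5000 per copula configuration; 200 replicates of
n = 2000 for regression recovery (|mean gamma-hat - 0.7| and the ratio
of mean reported SE to empirical SE); 100 replicates of 1000 pairs for
COR recovery at oracle COR = 5 and for independence coverage; 100
forests of 400 founders, 6 generations, theta = 2, decay 0.85 for the
kinship ordering fraction.

## Known limitations

* No left truncation and no within-lifetime time-dependent covariates.
* IPCW variance ignores the estimation of G (conservative direction).
* The cousin shared-censoring approximation above.
* The additive link can clamp predictions at [0, 1]; clamping is
  flagged rather than re-solved under constraints.
* The COR is reported under a constant-dependence (single-theta)
  Clayton model; genuinely time-varying dependence is visible in the
  concordance curves but not parameterised.
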