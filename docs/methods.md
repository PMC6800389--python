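# Methods

`mortmap` estimates age-specific child mortality over a gridded study region
from household-survey birth histories, and derives the reported measures —
neonatal/infant/under-5 mortality, death counts, calibrated subnational
estimates with uncertainty, SDG exceedance probabilities, inequality metrics
and counterfactual deaths averted — with uncertainty propagated through every
step by posterior draws.

## The discrete-hazards model

Age under five is split into seven bins (0, 1–5, 6–11, 12–23, 24–35, 36–47,
48–59 months).  Each bin has a conditional probability of death
`P[a,s,t]` given survival to its start, in grid cell `s` and year `t`.
Observed deaths are binomial,

    Y[a,s,t] ~ Binomial(n[a,s,t], P[a,s,t])

with a logit link to a linear predictor

    logit P = beta0 + I(a>1) * beta_age[a] + beta_cov . X[s,t]
              + beta_time * t~ + nu_c[country(s)] + nu_k[survey] + Z[a,t,s]

where `X` are standardized gridded covariates, `t~` is the year index centred
on the middle study year (a pure conditioning choice; centring changes only
the interpretation of `beta0`), `nu_c ~ N(0, sigma_c^2)` are country effects,
`nu_k ~ N(0, sigma_k^2)` are data-source effects that absorb survey-specific
bias (used in fitting, never in prediction), and `Z` is a mean-zero Gaussian
process over (age bin, year, cell) with separable covariance

    K = sigma_z^2 * R_a(rho_a) (x) R_t(rho_t) (x) R_s(range).

`R_a` and `R_t` are AR1 correlation matrices; `R_s` is a Matérn correlation
over inter-cell distances.  Smoothness is fixed at 3/2 by default (closed
form, once-differentiable paths; 1/2 and 5/2 are available).  The
user-facing `spatial_range` is the distance at which spatial correlation
falls to ~0.1; internally it is converted to the Matérn length-scale.  The
Kronecker structure is exploited throughout (per-factor Cholesky solves and
eigendecompositions); the dense `K` is never formed outside tiny test
instances.

Likelihood weights: entrants and deaths may be fractional (polygon
resampling, SBH down-weighting), so the binomial log-likelihood omits its
normalizing coefficient and accepts real-valued `n, Y`.  Rows that share a
(survey, cell, year, bin) have identical linear predictors, and the weighted
likelihood aggregates over them exactly; the model collapses such rows before
fitting.

## Data preparation

**Tabulation (synthetic cohort method).**  Each child contributes one
entrant to every age bin it enters before the interview; the period of a
contribution is the calendar year containing the midpoint of the bin's
interval on the child's own calendar axis (unbiased for bins spanning a year
boundary).  A death contributes `Y = 1` to the bin containing the age at
death and censors later bins.  A bin whose full width is not observed before
the interview contributes nothing unless the child died in it — a
conservative censoring rule that keeps `n` interpretable as binomial trials,
at the cost of discarding partial exposure.  Retrospective periods more than
17 years before the interview are dropped by default (mothers' age
composition makes older recall unreliable); the cut-off applies per survey
and is configurable.

**Summary birth histories.**  Indirect estimation from mothers' aggregate
counts is out of scope; synthetic SBH sources are generated directly as
bin-level counts and then down-weighted by multiplying both `n` and `Y` by
0.5 (halving the effective sample size while preserving every ratio `Y/n`).

**Polygon resampling.**  Observations located only to an administrative
polygon are replaced by up to `k = 10` cell-centre pseudo-points sampled
without replacement proportional to the polygon's under-5 population in the
observation's year, with `n, Y` split proportional to the selected cells'
population (normalized to sum to one).  Totals are conserved exactly and each
pseudo-point keeps the parent's ratio.  `k` and with/without replacement are
configurable.

## Inference

Estimation is maximum a posteriori with uncertainty from the curvature at the
mode.  Priors are weakly informative and configurable: Normal(0, 5²) on all
fixed effects, half-Normal(0, 1) on `sigma_c`, `sigma_k`, `sigma_z`,
log-Normal(log median inter-cell distance, 1²) on the spatial range, and
Uniform(−1, 1) on the AR1 correlations via a tanh transform.

The parameters split into two groups:

* the *effect* parameters (fixed effects, `nu_c`, `nu_k`, the full `Z`
  field), for which the negative log posterior is strictly convex given
  hyperparameters.  They are profiled by a damped inexact-Newton method:
  exact Hessian-vector products (the likelihood is a weighted GLM), conjugate
  gradients with a block preconditioner — a dense solve on the small head
  block and a spectral `(K^-1 + d̄ I)^-1` solve on the field block built from
  the Kronecker eigendecompositions — and a backtracking line search.
  Convergence is declared when the gradient infinity-norm falls below
  `max(1e-3, 5e-7 |f|)`; the floor scales with the objective because
  CG-truncated steps cannot resolve finer.
* the six transformed hyperparameters (`log sigma_c/k/z`, log length-scale,
  `atanh rho_t/a`), estimated by a Laplace-type marginal criterion:
  the profiled objective plus half the log-determinant of the inner Hessian.
  A fully joint mode over hyperparameters does not exist for this model — the
  prior log-determinant diverges to −∞ along `|rho| -> 1` or
  `range -> ∞` faster than any reasonable prior grows — and the Occam
  log-determinant term is exactly what offsets those ridges.  The field block
  `log|K^-1 + D|` is evaluated for a rank-1 Kronecker-separable surrogate of
  the likelihood curvature diagonal `D` (curvature is close to separable over
  age × year × cell because it factorizes as entrants × p(1−p)), which
  reduces to three small eigenproblems; on dense-checkable instances this
  surrogate tracks the exact log-determinant to within a few units over the
  relevant hyperparameter range and shares its minimizer, whereas a scalar
  mean-curvature approximation visibly over-shrinks `sigma_z` and the range.
  The 6-dimensional criterion is searched by Nelder–Mead with a wide initial
  simplex (±0.8 on the transformed scales; the default tiny simplex
  under-explores log-scale parameters) and warm-started inner refits.

One consequence: with zero observations the hyperparameter criterion reduces
exactly to the hyperparameter priors, so the no-data mode is the prior mode
for *all* parameters (sd's at 1, correlations at 0, range at its prior
median) — a property a fully joint MAP cannot have.

**Uncertainty.**  The joint precision is the analytic negative Hessian over
the effect parameters at the mode with hyperparameters at their marginal
estimates; it is positive definite by convexity.  Posterior draws (default
1,000) come from `N(mode, H^-1)` via a Cholesky solve of the precision, and
hyperparameter uncertainty is propagated on top for the two hyperparameters
that dominate predictive interval width at data-free cells — `log sigma_z`
and the log spatial length-scale.  Their 2×2 curvature under the marginal
criterion (finite differences with warm inner refits) gives a Gaussian
approximation; each draw perturbs them and carries the perturbation into the
effects by a first-order mean shift through the profiled-mode Jacobian (a
by-product of the same finite-difference stencil) and by rescaling the field
deviation with the drawn `sigma_z` (the conditional field dispersion scales
with the prior sd where data are thin).  This is a delta-method approximation
of drawing all parameters from a joint precision; uncertainty in the AR1
correlations and the random-effect sds is not propagated, and conditional
covariance changes beyond the `sigma_z` scale are ignored, so intervals
remain slightly approximate.  For large fields, where the dense precision is not
tractable, `precision_mode="fixed_marginal"` computes the exact marginal
covariance of the non-field block by a Schur complement with
Kronecker-preconditioned CG solves (no draws available in that mode).

**Prediction.**  Per draw, `P[a,t,s]` is rebuilt from the linear predictor
with the cell's country effect included and the survey effects excluded:
data-source biases describe sources, not places.

## Post-estimation

* Composition: `q = 1 − prod_{a<=A}(1 − P_a)` with `A` = 1 (neonatal), 3
  (infant), 7 (under-5), per draw.  The neonatal measure uses the month-0
  bin, standing in for the 0–28-day definition; the 2–3-day discrepancy is
  accepted, not corrected.
* Death counts: cohort mode `deaths = live_births × q` (the default
  everywhere downstream); period-rate mode converts bin probabilities to
  rates `m_a = −ln(1−P_a)/width_a` applied to the width-apportioned under-5
  population.
* Raking: per draw and per (country, year, measure), gridded probabilities
  are multiplied by `reference / birth-weighted national aggregate` and
  clipped at 0.999 (clip events logged; without clipping the recomputed
  aggregate equals the reference exactly).  Raking operates on the
  probability scale against a reference *mean* series, per draw; a count-scale
  option is available through the same function by passing death-count cubes.
  The three composed measures are raked independently, so a mutually
  inconsistent reference could break their ordering — the synthetic reference
  envelope is internally consistent by construction.
* Aggregation: probability measures are live-birth-weighted means over member
  cells per draw (probabilities are per-birth quantities; the under-5
  population class is used only for period-rate death counts); counts are
  sums.  Summaries (mean, 2.5th/97.5th percentiles) are computed across
  draws after aggregation.  Zero-population units yield flagged NaNs.
* Exceedance: the share of draws with `q × 1000` at or below the threshold
  (25 under-5, 12 neonatal); a unit "meets the target with 90% certainty"
  at probability ≥ 0.9.
* Inequality: absolute range of unit means (×1000) per country-year, unit
  ratios to the birth-weighted country mean, and a significant-change flag
  between two years when the 95% intervals do not overlap.
* Counterfactuals (per draw): `best_unit` lowers every unit to its country's
  per-draw best under-5 rate (selection uncertainty propagates); `threshold`
  clamps rates at the target; both never raise a unit's rate, so averted
  deaths are non-negative by construction.  `rates_of_year` substitutes the
  reference year's rates exactly and is signed.

## The synthetic world

The generator produces everything the pipeline consumes, with the structure
the model assumes: a planar km grid (the model needs only inter-point
distances), nested axis-aligned rectangular admin units (exactly testable
aggregation without shapefile machinery), covariates as kernel-smoothed white
noise plus linear year trends, standardized per world over the full support,
log-normal strictly positive population texture, a separable GP truth field,
and surveys whose children walk through the seven bins under logit-biased
hazards (`nu_k ~ N(0, sigma_k^2)`), with deaths placed uniformly within their
bin.  Cluster positions are sampled proportional to births; a configurable
fraction is referenced only to its admin-2 polygon.

What it does not emulate: real covariate products, country-border geometry,
fertility or migration dynamics, survey nonresponse, or age heaping.  Passing
tests therefore demonstrate the statistical machinery under the model's own
assumptions — they say nothing about robustness to the misspecifications real
survey data carry.

### Standing study designs

Two fixed designs (in `mortmap.experiments`) define the package's evaluation
conditions:

* **Recovery world**: 20×20 grid of 10 km cells, six years, four countries,
  eight region-wide surveys with 25 clusters each (200 clusters per year),
  180 births per cluster, survey bias sd 0.1, covariate effects (0.8, −0.5).
  GP hyperparameters (range 15 km, `sigma_z` 0.45, `rho` 0.85) are supplied
  to the fit; the study measures fixed-effect interval coverage over 20
  replicates.
* **Evaluation world**: 12×16 grid, six years, four countries, 48 small
  admin-1 blocks of 2×2 cells, each carrying exactly one survey (50 clusters,
  230 births per cluster; `sigma_z` 0.40).  The segregated-source design is
  deliberate: holding out a survey removes all data from its admin-1 block,
  which is the missingness pattern survey-holdout cross-validation is meant
  to stress, and it is what makes the CV coverage check meaningful (held-out
  areas are predicted by spatial interpolation, not by refitting the same
  cells).  Two power considerations size the design: survey density makes
  direct estimates from a held-out survey precise relative to the model's
  predictive intervals at data-free units, and the number of blocks controls
  the Monte-Carlo error of the pooled out-of-sample mean error (block errors
  are spatially correlated, so the mean error averages over blocks, not over
  unit-years; ~48 blocks bring its sd to ~0.002, small enough to measure
  bias at the 0.005 scale).

Problem sizes throughout (grid sizes, cluster counts, 500-draw inference in
the studies) are desk-scale choices: large enough for the statistical checks
to bind, small enough to iterate on a laptop.

## Numerical choices and degenerate inputs

* Matérn factors get escalating diagonal jitter only if a Cholesky fails
  (logged); AR1 factors are exact.
* `expit` outputs are clipped to `(1e-15, 1-1e-15)`; predicted cubes to
  `(1e-12, 1-1e-12)`.
* Observation-to-cell mapping is nearest cell centre with ties broken toward
  the lower cell index; points outside the grid bounding box raise.
* Zero-entrant rows, deaths exceeding entrants, out-of-window years and
  location-free rows are dropped by QC with a per-survey reason report,
  never raised.
* Zero under-5 deaths in a draw make the neonatal fraction undefined for that
  draw (NaN, excluded from summaries, logged); zero-population admin units
  likewise.
* All randomness flows through explicitly passed `numpy` generators; the
  pipeline derives per-stage seeds by hashing the master seed with the stage
  name, so every artifact is a pure function of (config, seed).

## Known limitations

* Hyperparameter uncertainty enters the draws through a first-order
  approximation (mean shift plus `sigma_z` scaling); higher-order effects on
  the conditional covariance are ignored, so intervals remain very slightly
  narrow.
* The Occam log-determinant surrogate assumes near-separable likelihood
  curvature; strongly clustered designs with large data holes weaken it.
* Joint point-and-polygon likelihoods are not attempted (polygon rows are
  resampled to pseudo-points); no SPDE/knot approximation of the field, so
  supports are limited to a few thousand cells; no MCMC.
* Counterfactual and inequality summaries inherit whatever bias raking
  introduces when the reference disagrees with the data.
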