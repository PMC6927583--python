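# Methods

This note documents the statistical models, the data-generating process used
for validation, the numerical choices, and the limits of what the test suite
demonstrates.

## Panels and cleaning

A panel is a set of (unit, school year) records with outcome percentages in
[0, 100] (missing cells are NaN, never zero), a population, and optional
covariates keyed by unit-year.  Years are encoded by school-year start
(2016 means the 2016–17 school year), and `policy_year = 2016` marks the
first post-policy year, matching a law effective July 1, 2016.

Cleaning applies three rules, each fully logged in a `CleaningReport`:

* **Population filter.**  Counties whose *mean recorded population* is below
  the threshold (default 65,000) are excluded.  Population rarely crosses the
  threshold within a study window; the mean makes the rule deterministic
  when it does.
* **Proxy substitution.**  A county that never reports overall coverage but
  reports MMR coverage has overall coverage set to MMR, year by year.  The
  substitution is per-unit (a county is either fully proxied or not at all)
  so the overall-coverage-only subanalysis can drop exactly those units.
* **Impute-or-exclude.**  For a given outcome, units missing more than
  `max_missing_fraction` (default 0.2) of the panel's year span are excluded;
  remaining gaps are filled by within-unit linear interpolation over year
  with nearest-value extension at the edges.  This is order-preserving,
  deterministic, and leaks nothing across units.  Observed cells are never
  altered, and both operations are idempotent.

## Synthetic control

Donor weights solve the simplex-constrained QP
`min_W (X1 − X0·W)' diag(V) (X1 − X0·W)` (SLSQP from the uniform start,
`ftol 1e-14`; weights are clipped at zero and renormalised, and the reported
objective is recomputed at the returned point).  Predictor weights V are
found by multi-start Nelder–Mead on the softmax parameterisation of the
simplex, minimising prepolicy outcome MSPE.  The start set — uniform V, one
near-vertex start per predictor, and four draws from a fixed-seed RNG
(seed 20160701) — is deterministic, so repeated fits are bit-identical; the
returned V is additionally guaranteed no worse than uniform V.  Convergence
tolerances: inner QP 1e-8 on the objective scale, outer search `fatol 1e-9`.

Predictors are z-scored across the treated-plus-donor pool so V is
comparable across scales; zero-variance rows are dropped.  The outcome
enters as its prepolicy *mean* by default (matching on average prepolicy
outcomes); per-year lags are available via `outcome_lags=True`, which
matches the full pretreatment path and is the stronger choice when donors'
paths are informative.  With mean-matching and many donors the inner QP can
be under-determined (several weight vectors reproduce the same predictor
values); the fitted path then depends on the solver's deterministic choice.
This is a property of the estimator, not the implementation — exact-recovery
tests therefore use either per-year lags or enough predictors relative to
donors for uniqueness.

The effect size is the mean post-policy gap minus the mean prepolicy gap,
over all available years in each window (two post years in the motivating
setting).  Because weights sum to one, gaps are invariant to adding a common
constant to every unit's outcome.

Forward stepwise covariate selection starts from the prepolicy-mean-only
predictor set and greedily adds the candidate that most reduces validation
MSPE, computed by refitting on prepolicy years excluding the last
`holdout_years` (default 1) and scoring squared gaps on the held-out years.
It stops when no candidate improves by more than 1e-6; ties break by
candidate list order.  The holdout scheme is this package's concrete choice
for "cross-validated stepwise selection"; other splits are defensible.

## Placebo inference

Each control unit is recast as treated and the full procedure refit with a
donor pool excluding both that unit and the true treated unit (the latter is
exposed post-policy and would contaminate counterfactuals).  Effects are
oriented so the hypothesized direction (coverage up, nonmedical exemptions
down, medical exemptions up) is positive; the treated rank is
`1 + #{placebo effects ≥ treated effect}` — ties count against the treated
unit, which is conservative — and the effect is flagged meaningful when
`100·rank/n_evaluated ≤ 5`.  Infeasible placebo fits (missing data) are
recorded as exclusions, not errors, so reported counts reflect data
availability.  No prepolicy-fit (MSPE-ratio) filtering is applied by
default; ranking is by signed effect in the prespecified direction, not by
absolute value.

## Difference-in-differences

The default specification is the 2×2 interaction design (intercept, treated,
post, treated×post) plus untransformed covariates; year fixed effects are
available behind `year_fixed_effects=True`.  The covariance is the CR1
sandwich — `(X'X)⁻¹ [Σ_g X_g'e_g e_g'X_g] (X'X)⁻¹ · G/(G−1) · (n−1)/(n−p)` —
which reduces exactly to HC1 when every observation is its own cluster; CR0
is available via `correction="CR0"`.  Degrees of freedom for CIs and
p-values are `G − 1` (clusters minus one), a standard conservative choice.
No enrollment weighting is applied.  The parallel-trends diagnostic reports
per-(group, year) mean outcomes and the difference of OLS slopes fitted to
the prepolicy group means.

## The data-generating process

Outcomes follow
`Y_it = μ + α_i + δ_t + λ_i'f_t + τ·1{treated, post} + e_it`
with unit effects α, a linear common trend δ (one slope, default 0.1 pp/yr,
shared by all outcomes), a 2-factor latent component (county/state loadings,
scale 0.5 pp), AR(1) noise (ρ = 0.5, marginal sd 0.5 pp), and clamping to
[0, 100] — the single nonlinearity.  Three outcomes are generated with the
policy sign structure coverage ↑, nonmedical ↓, medical ↑.  Covariates are
constant within unit; income and education load positively on the
coverage-family unit effect and poverty/uninsurance negatively, so predictor
selection has genuine signal, while household size is pure noise.  County
panels nest counties in states with a state random effect giving intraclass
correlation `county_icc` (default 0.5), heavy-tailed lognormal populations
so the 65,000 filter binds, and optional effect heterogeneity (larger
effects where prepolicy coverage is lower).  `treated_counties` lets the
treated state be larger than the controls, as treated states often are.

Default baselines (94.2 / 2.2 / 0.3 pp with spreads 2.5 / 1.3 / 0.2) mirror
real 2015 kindergarten-entry levels, and default effects (+4.3 / −3.9 /
+2.4 pp) mirror plausible county-level policy impacts.  **Near the upper
bound the clamp truncates noise asymmetrically and attenuates injected
effects** — real coverage near 99% cannot rise by 4 pp either, so this is a
feature of bounded outcomes, not a bug.  Recovery and calibration
simulations therefore use a clamp-safe baseline (coverage 88.0, nonmedical
8.0, medical 3.0, all ≥3 sd from the bounds), where the linear model is
correctly specified and unbiased recovery is the right expectation.

What the generator does **not** emulate: reporting-system changes across
years, state-specific secular policy trends, enrollment-size heteroskedasticity,
non-random missingness, and correlated treatment timing.  Passing tests
show the estimators are correct under the assumed factor-model world; they
do not validate the identifying assumptions in any real dataset.

## Problem sizes and calibration facts

Monte-Carlo checks run at: 200 replicates for synthetic-control recovery
under noise (mean error ~0.01 pp, band 0.15 pp); 200 replicates × 20 states
for placebo calibration (null flag rate ≈ 0.05–0.06 against a nominal 1/20);
200 (coverage) and 500 (size) replicates of a county study with 57 treated
and ~250 control counties over 8 years, where the 95% CI covers the true
effect ~92–95% of the time and the type-I error is ~0.05.  With markedly
fewer treated clusters (e.g. ~15 of 170) cluster-robust t inference
over-rejects (~0.08 observed) — the well-known few-treated-clusters
problem; results with few treated clusters should be read cautiously or
paired with randomization inference.

## Known limitations

* No augmented/bias-corrected or penalised synthetic-control variants, no
  multiple-treated-unit pooling, no conformal or asymptotic SC inference.
* No event-study dynamics, synthetic DiD, or wild-cluster bootstrap.
* The stepwise holdout split and the impute-or-exclude threshold are
  configurable stand-ins for procedures whose exact published forms vary.
* Reporting emits plot-ready tables only; no figure rendering.
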