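# Methods

## Landmarking

Given a grid of landmark times ℓ₀ < … < ℓ_J (default 0, 0.5, …, 5 years)
and a prediction horizon τ (default 3 years), the landmark dataset at ℓ
contains every subject with observed time T > ℓ (strict: a tie T = ℓ is
excluded, which guarantees positive residual time).  Covariates are the
last measured values at or before ℓ (LOCF; a measurement exactly at ℓ is
usable).  Subjects at risk but with no measurement by ℓ are excluded and
counted in the log rather than imputed.  Residual times T − ℓ are
administratively truncated at τ: (min(T−ℓ, τ), δ·1{T−ℓ ≤ τ}).  Stacking
the per-landmark datasets gives the supermodel data; the subject id is the
cluster key since a subject contributes one row per landmark survived.

The time basis is (1, ℓ/s, (ℓ/s)²) with scale s = 5 years, so the basis
spans [0, 1] over the default landmark period.  The design matrix holds an
intercept (no time interaction by default — a switch enables intercept ×
basis terms) plus, for each covariate, the three products X_p·(ℓ/s)^k.
With 8 covariates this is 25 columns (24 for Cox, which has no intercept).

## Pseudo-observations

Within each landmark dataset, on the residual time scale (so the KM curve
is conditional on survival to ℓ), the jackknife pseudo-value of subject i
is Z_i = n·Z − (n−1)·Z^{−i}, with Z either the RMST ∫₀^τ Ŝ or Ŝ(τ).
Conventions:

* ties at identical residual times are grouped; deaths precede censorings
  (both are in the risk set at the tied time);
* the RMST integral includes the leading segment [0, t₁) at height one;
* if Ŝ has not reached zero by the last observed time it is carried
  forward flat to τ.

The leave-one-out curves are computed in closed form from the risk/death
count updates (all subjects sharing a time and status get the same deleted
curve), one O(K) pass per deletion group over the K distinct times.  A
naive O(n²) recomputation is retained (`method="naive"`) and the test
suite requires agreement to 1e-10; lifelines' KM/RMST are used as an
additional independent oracle.

**Jackknife tail note.**  The leave-one-out average of pseudo-values
reproduces the full-sample estimate to machine precision *except* when the
largest observation in the sample is an uncensored failure strictly before
τ whose deletion leaves a censored observation on top — then the deleted
curve switches from dropping to zero to a flat positive carry-forward, and
the average can deviate visibly.  This is a known property of jackknifing
KM integrals, not an implementation artifact (the naive recomputation
agrees).  On the pipeline's actual inputs — residual times truncated at τ
with, in practice, part of the risk set surviving the window, so the
largest observation is a censored τ — the identity is exact; a unit test
documents the corner case.

## Supermodels

* **PM / PP (GEE).**  Pseudo-values are regressed on the expanded design
  by GEE with independence working correlation, clusters = subject, and
  identity link (log, logit, cloglog available for exploration).  Under
  the identity link the point estimates equal least squares; all reported
  variances are the robust cluster sandwich.  Rank deficiency is detected
  up front and reported with the offending columns.
* **Cox.**  The stacked partial likelihood on the study time axis with
  delayed entry at ℓ and administrative censoring at ℓ+τ, fitted via
  lifelines with tightened Newton tolerances (the default stopping rule
  can leave a ~1e-5 final step unapplied, which matters for the oracle
  comparisons).  Ties are handled by Efron's method; simulated times are
  continuous so this coincides with Breslow wherever ties are absent.  A
  single baseline cumulative hazard is used on study time (the data
  provide no information to let Λ₀ depend on ℓ beyond the covariate
  interactions); it is extracted at the zero covariate vector through the
  public prediction API and stored as a step function.
* **Predictions.**  PM predictions are conditional 3-year RMSTs clipped
  to [0, τ]; PP and Cox predictions are probabilities clipped to [0, 1];
  clipping events are logged.  Cox conditional survival uses
  exp{−[Λ₀(ℓ+τ)−Λ₀(ℓ)]·exp(lp)}.
* **Dynamic coefficients.**  β_p(ℓ) = b(ℓ)ᵀc_p with b the time basis and
  c_p the covariate's three coefficients; the delta-method variance
  b ᵀΣ_p b from the sandwich covariance gives 95% bands.  With the
  quadratic term zero the curves are affine in ℓ; with a constant basis,
  horizontal.

### Static comparators

* **SM1** refits, at each landmark, the conditional outcome (per-landmark
  pseudo-values, or a residual-scale Cox model) on covariate values frozen
  at t = 0.  The per-landmark-refit reading keeps SM1's predictions
  genuinely conditional on survival to ℓ; for the Cox family a single
  baseline fit adjusted through Λ₀ differences would be an alternative
  reading.
* **SM2** fits once at ℓ = 0 and evaluates with X(ℓ).  For the Cox family
  the baseline fit uses full follow-up so its cumulative hazard extends
  past τ and later-landmark predictions remain conditional; for PM/PP the
  baseline regression is simply applied to updated covariates (the model's
  crudeness is the point of the comparison).
* **SM3** refits per landmark on X(ℓ).  No static design carries time
  interactions.

## Evaluation

Metrics are computed per landmark on the held-out landmark risk set, never
pooled.  The subject-level split is round(n·fraction) train (default 75%),
reproducible by seed.

* **AUC** is the pairwise concordance Σ 1{T_j<T_i}·1{η_j>η_i}·δ_j /
  Σ 1{T_j<T_i}·δ_j with η a *risk* score; since all three families emit
  survival-type predictions, the evaluator negates them so informative
  models score above 0.5.  Ties in η contribute nothing under the default
  strict reading (an all-tied predictor scores 0); a half-credit option is
  available.  Concordance is computed on the truncated residual pairs, so
  outcomes resolved beyond the horizon do not enter; with no usable pairs
  the value is missing with a warning.
* **IPCW Brier.**  Ĝ is the KM of the censoring times estimated on the
  landmark's raw (untruncated) residual times — the censoring distribution
  conditional on survival to ℓ.  Failures before t weight by 1/Ĝ(T−)
  (left limit), survivors past t by 1/Ĝ(t), and subjects censored inside
  the window contribute zero.  A zero Ĝ at a needed point raises an error
  suggesting a smaller horizon.  With no censoring the probability version
  reduces exactly to the classical Brier score.  The PM analogue replaces
  (0−p̂)², (1−p̂)² with (T−μ̂)², (t−μ̂)²; it is in years² and has no
  upper bound of 1, so PM and PP/Cox calibration are not directly
  comparable.

## Synthetic cohort

The generator emulates a cirrhosis EHR cohort: baseline age/sex and three
etiology indicators; MELD-Na and albumin following per-subject
random-intercept/slope lines with visit-level noise, clipped to clinical
ranges; decompensating events as a homogeneous Poisson process reported as
a cumulative count on top of a Poisson pre-entry history (mean 0.25); HCC
onset as an exponential one-way switch with a small prevalence at entry
(3%).  The entry-time history matters: without it the baseline
decompensation count and HCC indicator would be structurally zero and any
baseline-covariate model (SM1/SM2) would be rank deficient by
construction.  Visits
occur at regular spacing (default 0.25 y) with uniform jitter, first visit
at entry so every subject has baseline values.  The true death hazard is
proportional-hazards in the *current* (LOCF) covariate values — piecewise
constant between visits — so the generator itself is an exact oracle:
`true_conditional_survival` and `true_conditional_rmst` integrate that
hazard in closed form segment by segment (no quadrature error) and back the
parameter-recovery tests.  Censoring is the minimum of an exponential draw
and the administrative end of study; the schedule is generated
incrementally and stops at the observed time, which is statistically
identical to generating the full schedule and truncating.

Per-subject random streams are spawned from the master seed, so the first
k subjects are unchanged when only `n_subjects` grows.  Default baseline
hazard 0.085/yr and censoring hazard 0.55/yr put the default scenario near
a 19% event fraction with median follow-up ≈ 1 year (checked once at
n = 3000: 19.3%, 1.09 y); visit frequency in the emulated setting is not
known, so the default spacing is a configurable choice, not a calibrated
one.

What the generator does *not* emulate: informative censoring,
measurement-error-driven visit timing (visits are independent of health
state), competing risks, covariate-dependent visit frequency, and missing
measurements.  Passing recovery tests therefore demonstrate correctness of
the estimators under these idealized conditions, not robustness to the
messiness of real EHR data.

## Problem sizes and numerical choices

Tests run on cohorts of 200–2400 subjects; the stochastic recovery check
uses 100 seeds at n = 2000 with a single landmark and one binary covariate
(log-HR 0.7, exponential baseline 0.25/yr, censoring 0.15/yr), asserting
3-robust-SE coverage in ≥95 seeds for both the Cox supermodel and the
PM-GEE (against the exact RMST-difference oracle).  The time-constant
calibration check fits 15 replicates at n = 500 and requires the joint
Wald test of the interaction terms to be non-significant at the 5% level
in ≥ 90% of fits.  Endpoint tolerance of the landmark grid is 1e-9;
oracle comparisons run at 1e-8 (Cox vs score root-finding) and 1e-10 to
1e-12 (jackknife, GEE vs OLS, metric transcriptions).

## Known limitations

* Pseudo-value validity assumes censoring independent of covariates; no
  covariate-dependent censoring weights are provided.
* The strict-inequality concordance deliberately scores heavily tied
  predictors near zero; use `ties="half"` for the conventional reading.
* Model selection over the interaction terms is intentionally absent: all
  covariates and both interactions stay in the model for comparability
  across families.
* Spline time bases, sliding-window covariate summaries and competing
  risks are out of scope.
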