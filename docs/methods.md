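# Methods

`regcal` simulates and corrects dose measurement error in grouped
radio-epidemiological dose-response analysis.  This note records the models
implemented, the numerical choices behind them, and what the synthetic data
do and do not establish.

## The dose-error model

The cohort is a set of K dose groups, each with a central dose estimate
`D_cent,k` (Gy) and a person count `n_k`.  The built-in cohort mimics the
person distribution of the Japanese atomic bomb survivor Life Span Study
(LSS) collapsed to five bone-marrow dose groups: central doses 0.01, 0.1,
0.5, 1.5 and 2 Gy with 2591, 334, 438, 102 and 6 persons (3471 in total).
The tiny uppermost group is deliberate: it reproduces the instability that
sparsely populated high-dose groups contribute in real cohort data.

True and surrogate doses for individual *i* in one simulation are
multiplicative lognormal perturbations of the group central estimate:

    D_true,i = D_cent,k(i) · exp(−(σ²_sB + σ²_uB)/2) · exp(σ_sB·ε + σ_uB·δ_i)
    D_surr,i = D_cent,k(i) · exp(−(σ²_sC + σ²_uC)/2) · exp(σ_sC·μ + σ_uC·κ_i)

with ε, δ_i, μ, κ_i i.i.d. standard normal.  ε and μ are *shared* across
the cohort within one realization (a systematic dosimetry error, e.g. a
source-term uncertainty); δ_i and κ_i are *unshared* (per-individual).  The
σ are geometric standard deviations on the log scale, typically 0.2 ("20%")
or 0.5 ("50%").  The Berkson pair (σ_sB, σ_uB) scatters truth around the
assigned dose; the classical pair (σ_sC, σ_uC) scatters the surrogate
(observed) dose around its expectation.  The leading bias factors make
E[D] equal the central estimate exactly, so the model is mean-preserving by
construction; setting either pair to zero degenerates that error component
exactly (the samplers return central doses without consuming random draws).

Two closed-form consequences are used as oracles in the tests:

* the correlation between two individuals' true doses is
  (e^{σ²_sB} − 1)/(e^{σ²_sB+σ²_uB} − 1);
* within one realization, the spread of a group's doses is governed by the
  unshared component alone (the shared deviate is a constant multiplier).

## Outcome model

Each simulation allocates a fixed total of N cases over individuals by a
single multinomial draw with probabilities proportional to the
linear-quadratic relative risk at true dose, RR(d) = 1 + αd + βd², i.e.
p_i = λ·RR(D_true,i) with λ the normalizing constant.  A single multinomial
is equivalent in distribution to a group-level multinomial with
probabilities summed within groups, which the tests verify.  The study
defaults are N = 250, α = 0.25/Gy and β = 2/Gy², values in the range of
linear-quadratic fits to LSS leukaemia data; they imply a relative risk of
9.5 at 2 Gy, a strongly curved response.  Cases are then collapsed to the K
groups (summing cases) for model fitting.

## Grouped Poisson linear relative-risk model

The fitted model for group g with dose covariate d_g is

    y_g ~ Poisson(μ_g),   μ_g = n_g · λ · (1 + α d_g + β d_g²),

with the person counts n_g as offsets.  The log-likelihood drops the
y-only constant.  The feasible region requires every RR to be positive;
outside it the likelihood receives a large negative sentinel (the
likelihood genuinely diverges as any fitted relative risk approaches zero,
which is also why the fitted α̂ and β̂ distributions are right-skewed:
coefficients cannot go far negative without driving a high-dose group's
relative risk negative).

λ is profiled out in closed form, λ̂(α, β) = Σy_g / Σ n_g RR_g, leaving a
2-D maximization (Nelder–Mead from a null and a moment-based start, then a
coordinate polish with the same bounded 1-D optimizer the profiler uses, so
the maximized likelihood is exactly consistent with the profile curves).
Confidence intervals are profile-likelihood intervals: the parameter values
where twice the profile deviance reaches the χ²(1) 95% quantile (3.8415),
found by curvature-guided bracket expansion plus Brent root finding; the
endpoint deviance residual is below 1e-4.  A bound is reported infinite
when the deviance never reaches the cutoff before the search limit
(max(50, 3|θ̂|) per Gy or Gy²; the base limit of 50 is far outside the
plausible range, and the adaptive extension accommodates the occasional
very large β̂ produced by strong shared classical error).  Nuisance
searches run on an expanding window around the current estimate rather than
over the whole feasible range; this matters for MCML (below).  Datasets
with zero total cases are declared non-converged rather than guessed at.

## The four correction strategies

All four consume the identical case vector within an ensemble and differ
only in the dose covariate / likelihood:

* **unadjusted** — group means of a single surrogate-dose realization.
* **regcal** (regression calibration) — the Monte Carlo mean over n
  calibration true-dose realizations of the group-mean dose.  With
  mean-preserving errors this converges to the central doses, so under
  classical-only error the calibration covariate *is* the central-dose
  vector exactly and RC, ERC and MCML coincide.
* **ext_regcal** (extended regression calibration) — designed for shared
  errors with curvature.  Regression calibration evaluates RR at the mean
  dose and therefore misses the second moment.  The adjusted model uses the
  expected relative risk under the Monte Carlo distribution of the
  group-mean dose:

      E[RR(D_g)] = 1 + α D̄_g + β (D̄_g² + Var(D̄_g)),

  i.e. μ_g = n_g λ E[RR(D_g)], with Var(D̄_g) the diagonal of the
  calibration covariance.  Because the model is quadratic in dose this
  second-order correction is *exact* (no Taylor truncation).  It reduces
  identically to RC when the covariance vanishes, and the correction grows
  with the shared error, which dominates Var(D̄_g) after within-group
  averaging.  Two alternative adjustment forms were implemented and
  rejected during development: adding ½·Var(D̄_g)·∂²ℓ/∂D_g² to the
  log-likelihood (observed- or expected-Hessian versions) is a Taylor step
  of tens of log-likelihood units at 50% shared error — far outside its
  radius of validity — and grossly distorts the estimates; a Gaussian
  count-covariance correction collapses β̂ under strong shared error.  The
  adjustment is isolated in one objective class so another form can be
  swapped in without touching callers.
* **mcml** (Monte Carlo maximum likelihood) — maximizes the log of the
  *average* likelihood over the n calibration realizations, each evaluated
  at that realization's group-mean dose vector, computed by log-sum-exp.
  Realizations in which any group's relative risk is non-positive
  contribute likelihood zero.  λ cannot be profiled in closed form and is
  maximized by safeguarded Newton on log λ (warm-started; bracketed Brent
  fallback — the averaged likelihood is not provably concave in λ).

**MCML mode selection.** The averaged likelihood carries spurious distant
maxima in which a single extreme calibration realization reproduces the
case vector almost exactly (with n = 1000 bank members the log-penalty for
cherry-picking one realization is only log n ≈ 6.9, easily repaid by a
near-perfect fit).  These maxima are scientifically meaningless — they
correspond to coefficient values of order 10³ — so MCML starts from the
regression-calibration estimate and all profile searches stay local
(expanding window).  This is the one place the fitting deviates from the
default multi-start policy.

## Study orchestration and random streams

A scenario run simulates m independent dose+cancer ensembles.  Random
streams are pre-assigned with `numpy` seed sequences keyed on
(master seed, error-component family, GSD values, ensemble index, stream):
the true-dose, calibration and case streams depend only on the Berkson
GSDs, the surrogate stream only on the classical GSDs.  Consequently the
calibration-based fits are bit-identical across scenarios that differ only
in classical error — the structure visible as repeated columns in the
reference results — and every run is exactly reproducible from its master
seed.  Coverage is the percentage of converged fits whose 95% profile CI
contains the generating coefficient (fits that fail to converge, or whose
relevant CI bound could not be located, are excluded and counted); bias is
summarised by plain arithmetic means of the point estimates.

## Numerical and scale choices

* The batch calibration sampler draws the unshared deviates in float32
  (generation and exponentiation throughput); group averaging over ≥6
  individuals leaves the precision loss ~1e-7 relative, orders of magnitude
  below Monte Carlo noise.  The per-realization reference sampler is
  float64 and the two are checked against each other statistically.
* Sample covariance of the calibration group means uses divisor n−1 and is
  symmetrized; negative eigenvalues (roundoff) are clipped at zero with a
  warning.
* The acceptance script runs the full study conditions (m = 500, n = 1000,
  N = 250).  The test suite's scenario reproductions run at m = 200
  ensembles with the full n and N, using correspondingly wider Monte Carlo
  tolerances (±3 binomial SE for coverage at the m run; ±20% for mean
  coefficients, whose distributions are heavy-tailed under shared error).

## What the synthetic data do and do not show

The generator reproduces the grouped structure, the error taxonomy
(shared/unshared × Berkson/classical) and the curvature regime of the
motivating cohort, and the study verifies estimator behaviour *given that
the error model and its GSDs are known exactly*.  It does not emulate:
person-time and attained-age structure (cases are a one-shot multinomial,
not rates over follow-up); covariates or effect modifiers; uncertainty in
the error magnitudes themselves (all methods receive the true GSDs through
the calibration samples); dose-dependent (differential) error; or additive
error components.  Passing tests therefore demonstrate correctness of the
machinery and the comparative behaviour of the four estimators under the
stated conditions, not performance on real dosimetry systems.

## Known limitations and open points

* Under strong shared error the effective quadratic coefficient seen by a
  fixed-covariate fit scales by e^{2σ_s ε}, so exact profile CIs cannot
  maintain nominal coverage for β (they are conditional on one shared
  draw).  The package reports the coverage this produces; extended
  regression calibration mitigates but does not remove the deficit, and
  Monte Carlo maximum likelihood overcovers by flattening the profile.
* Mean coefficient estimates over ensembles are means of approximately
  lognormal quantities; at m = 500 their Monte Carlo error is still a few
  percent and is dominated by the upper tail.
* The ERC adjustment uses the covariance diagonal only; because the grouped
  likelihood is separable in the group doses, between-group covariance
  (which is extreme — group-mean correlations exceed 0.95 under shared
  error) does not enter the expected relative risk.  Adjustments that
  exploit the full covariance (e.g. marginal count-covariance corrections)
  are a natural extension but were not retained (see above).
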