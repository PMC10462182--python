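# regcal

Simulation and correction of shared and unshared dose measurement error in
grouped radio-epidemiological dose-response analysis.

## The problem

Cancer risk estimates at low radiation doses rest on extrapolation from
cohorts exposed at moderate and high doses, and on the shape — in
particular the curvature — of the fitted dose response.  Dose estimates in
such cohorts carry both **classical** error (the observed dose scatters
around truth, as in atomic-bomb survivor dosimetry) and **Berkson** error
(truth scatters around the assigned dose, as in source-term or
machine-setting uncertainty), and substantial parts of either can be
**shared** across the whole cohort rather than independent per person.
Measurement error of this kind distorts both the fitted curvature and the
confidence statements made about it.

`regcal` is for biostatisticians and radiation epidemiologists studying
dose-error correction methods.  It simulates a grouped cohort (modelled on
the Life Span Study person distribution) under a composite multiplicative
Berkson-classical lognormal error model, generates cancer cases from a
linear-quadratic excess relative risk model, and compares four estimation
strategies by coverage and bias.

## Model

True and surrogate doses for individual *i* in dose group *k* are

    D_true,i = D_cent,k · exp(−(σ²_sB+σ²_uB)/2) · exp(σ_sB ε + σ_uB δ_i)
    D_surr,i = D_cent,k · exp(−(σ²_sC+σ²_uC)/2) · exp(σ_sC μ + σ_uC κ_i)

with shared (ε, μ) and unshared (δ_i, κ_i) standard-normal deviates and
GSDs σ on the log scale; the bias factors make E[D] = D_cent exactly.
Cases follow a multinomial allocation with probabilities ∝ 1 + αD + βD²
(defaults α = 0.25/Gy, β = 2/Gy², N = 250 cases), and grouped Poisson
linear relative-risk models

    y_g ~ Poisson( n_g · λ · (1 + α d_g + β d_g²) )

are fitted by maximum likelihood with 95% profile-likelihood intervals.
Four dose covariates / likelihoods are compared:

| method | dose input |
|---|---|
| `unadjusted` | group means of one surrogate realization |
| `regcal` | regression calibration: MC mean of true-dose group means |
| `ext_regcal` | extended RC: expected relative risk `1 + αD̄ + β(D̄² + Var D̄)` using the calibration covariance |
| `mcml` | Monte Carlo maximum likelihood: log-average of per-realization likelihoods |

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

```python
from regcal import ErrorScenario, StudyDesign, lss_cohort, run_scenario

cohort = lss_cohort()
scenario = ErrorScenario(gsd_berkson_shared=0.5, gsd_berkson_unshared=0.2)
design = StudyDesign(n_ensembles=50, n_calibration_samples=1000, seed=42)

report = run_scenario(cohort, scenario, design,
                      methods=("unadjusted", "regcal", "ext_regcal"))
print(f"interindividual dose correlation: {report.interind_corr:.3f} "
      f"(analytic {report.interind_corr_analytic:.3f})")
for name, s in report.methods.items():
    print(f"{name:11s}  coverage alpha/beta: {s.coverage_alpha:5.1f}% "
          f"{s.coverage_beta:5.1f}%   mean alpha/beta: "
          f"{s.mean_alpha:6.3f} {s.mean_beta:6.3f}")
```

prints

```
interindividual dose correlation: 0.843 (analytic 0.844)
unadjusted   coverage alpha/beta:  94.0%  46.0%   mean alpha/beta:  0.195  2.887
regcal       coverage alpha/beta:  94.0%  44.0%   mean alpha/beta:  0.197  2.899
ext_regcal   coverage alpha/beta:  94.0%  28.0%   mean alpha/beta:  0.200  2.263
```

Reading this: with a 50% shared Berkson GSD two individuals' true doses are
correlated at 0.84 (the sample estimate matches the lognormal closed form).
Coverage for the linear coefficient α stays near the nominal 95% for every
method, but for the quadratic coefficient β it collapses — the shared error
multiplies the effective curvature seen by the fit by e^{2σ_s ε}, which no
fixed-covariate confidence interval can absorb.  All mean β̂ exceed the
true value 2 (upward bias); extended regression calibration removes most of
that bias (2.26 vs 2.89–2.90) because it corrects the quadratic term by the
variance of the calibrated group doses.  (m = 50 here for speed; Monte
Carlo noise on these entries is a few points.)

A command-line entry point runs steering-file-driven studies:

```
regcal run --steering my_study.txt --out results_dir
regcal run --scenario-grid full --m 100 --seed 7 --out grid_out
```

writing `coverage.csv`, `means.csv` and per-ensemble `fits.csv`.

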