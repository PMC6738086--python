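# Methods note

This note records the statistical model, the numerical choices, and the
deliberate design decisions behind the package, including what the synthetic
cohort generator does and does not emulate.

## 1. Model

### 1.1 Flexible parametric (Royston–Parmar) survival model

Let `t` be survival time in months and `x = ln t`. The model places a
restricted cubic spline on the **log cumulative hazard**:

```
ln H(t | z) = s(x; γ) + βᵀz ,    s(x) = γ0 + γ1 x + Σ_j γ_{j+1} v_j(x)
```

where `v_j` are restricted cubic spline basis functions

```
v_j(x) = (x − k_j)³₊ − λ_j (x − k_min)³₊ − (1 − λ_j)(x − k_max)³₊ ,
λ_j = (k_max − k_j) / (k_max − k_min)
```

with boundary knots `k_min, k_max` and internal knots `k_j`. The restriction
forces `s` to be linear beyond the boundary knots, so extrapolated hazards
stay Weibull-like rather than exploding cubically. Consequences:

- `S(t | z) = exp(−exp(s(ln t) + η))` with `η = βᵀz`;
- proportional hazards across covariates (unless time-dependent effects are
  added, §1.4);
- with **df = 1** (no internal knots) the model is exactly Weibull with shape
  `γ1` and scale `exp(−γ0/γ1)` — the suite exploits this as a closed-form
  oracle for the likelihood machinery.

### 1.2 Published parameter set

The frozen constants live in `src/prosash/data/published_model.json`
(version `prosash-1.0`) and are loaded by `load_published_model()`:

- knots (−1.017, 1.833, 3.443) on the log-month scale (df = 2);
- γ = (−8.167, 2.465, 0.113);
- λ for the single internal knot: 0.361;
- coefficients: vascular invasion 0.327, age (centred at 60) −0.0231,
  age×VI interaction 0.0303, ECOG ≥1 0.455, ln AFP 0.0831, albumin −0.0553,
  ln creatinine 0.709, ln AST 0.349, extra-hepatic spread 0.298, HBV 0.526,
  other aetiology 0.507 (HCV is the reference aetiology);
- risk cutoffs on η: (2.898, 3.666, 4.559], intervals closed above, giving
  four categories.

Exponentiated coefficients reproduce the documented hazard-ratio table at
its printed precision; tiny discrepancies (e.g. exp(0.298)=1.3472 printed as
1.348) are pure rounding artifacts of 3-decimal coefficients, so consistency
checks use absolute tolerance 1e-3 on the HR scale.

### 1.3 Likelihood, gradient, Hessian

With event indicator `d_i` and `x_i = ln t_i`, the log likelihood is

```
ℓ_i = d_i [ ln s'(x_i) − ln t_i + s(x_i) + η_i ] − exp(s(x_i) + η_i)
```

(`s'(x)` is the derivative with respect to x; the `−ln t_i` term is the
Jacobian of the time→log-time change of variable and does not affect the
maximiser). Gradient and Hessian are analytic. If `s'(x_i) ≤ 0` at an event
time the hazard would be negative; the likelihood returns −∞ there ("soft
rejection"), which steers line searches away without hard failure. In
practice the MLE always has `s' > 0` at event times for the problem sizes
used here.

### 1.4 Knot placement, df selection, covariate selection, TD effects

- **Knots**: boundary knots at the min/max *event* log-times, internal knots
  at equal centiles of event log-times (df = number of internal knots + 1).
- **df selection** (`select_df`): sequential likelihood-ratio tests over a
  candidate ladder; the smallest df not rejected against the next larger one
  is kept. On cohorts simulated from the df=2 published model it selects 2.
- **Covariate selection** (`backward_select`): backward elimination by
  likelihood-ratio p-value, removing the least significant term each round at
  α=0.05. Multi-level factors (aetiology) are removed as whole blocks.
- **Time-dependent effects** (`test_td_effect`): a covariate is interacted
  with the non-constant spline basis columns and tested by LR; martingale
  residuals and a linear-trend functional-form check back this up.

### 1.5 Estimation

BFGS (gradient tolerance 1e-8) followed by up to 50 Newton polish steps with
line search on the analytic Hessian; the fit is rejected (`FitError`) if the
final gradient norm exceeds 1e-4. γ is initialised by OLS of
`ln(−ln KM(t))` on the spline basis at event times; β starts at zero. The
covariance matrix is the symmetrised inverse of the observed information.
An n=2000, 14-parameter fit takes ≈0.7 s.

## 2. Validation metrics

- **Harrell's c-index**: a pair (i, j) is comparable iff `t_i < t_j` and
  `d_i = 1`, or the times are tied with exactly one event; tied risk scores
  count 0.5. The implementation is fully vectorised and is verified, pair by
  pair, against a brute-force double loop and against an independent
  implementation.
- **Royston–Sauerbrei D**: subjects are ranked by prognostic index, mapped
  to Blom rankits `Φ⁻¹((r − 3/8)/(n + 1/4))`, scaled by `κ = √(8/π)`, and
  the scaled rankit's coefficient in an auxiliary flexible parametric model
  (df=2) is D — the log hazard ratio between prognostically "average" halves
  of the cohort. `R²_D = (D²/κ²) / (π²/6 + D²/κ²)`.
- **Bootstrap CIs**: percentile intervals from seeded resampling; resamples
  on which the auxiliary model fails to converge are redrawn (up to 10
  retries each) rather than silently dropped.

## 3. Calibration

Observed survival is the Kaplan–Meier estimator (Greenwood variance,
log(−log) confidence bands, Brookmeyer–Crowley median CIs). Predicted
survival for a group is the **arithmetic mean of the individual predicted
curves**, and the predicted median is where that mean curve crosses 0.5
(bisection on a 120-month horizon).

A deliberate distinction: the mean of curves is *not* the curve at the mean
index. The map `η ↦ exp(−H0(t) eᵉᵗᵃ)` is convex only where `S < 1/e` and
concave above, so the mean curve lies *below* the curve-at-mean-η at early
times (high survival) and *above* it at late times — the two differ in both
directions, and only the mean of curves answers "what fraction of this group
is expected to be alive". The test suite asserts this two-sided behaviour.

Risk tables (`build_risk_table`) support two modes: `published` (frozen
cutoffs) and `centile` (type-1 / ceiling-rank 15/50/85 centiles of the
cohort's own index, giving an exact 75/175/175/75 split at n=500).
Between-group hazard ratios come from a df=2 flexible parametric model on
group indicators; an eventless group yields an infinite-CI flag rather than
a crash.

## 4. Synthetic cohort generator

`generate_dataset(CohortConfig(...), model)` draws trial-like cohorts:

- **Covariates** are drawn from the documented *marginal* distributions:
  truncated-normal age; Bernoulli flags for vascular invasion, ECOG ≥1,
  extra-hepatic spread; categorical aetiology; log-normal labs with
  parameters solved from a documented median and IQR width. The log-normal
  solve warns when no log-normal can match the target quantiles exactly and
  uses the nearest fit.
- **Event times** by inverse-transform sampling: `u ~ U(0,1)` is mapped
  through `S⁻¹(u | η)` via bracketed root-finding on the spline.
- **Censoring**: an administrative horizon of 31.3 months (the follow-up
  length the baseline curve was estimated over) plus independent exponential
  dropout at 0.010/month. The dropout rate was calibrated **once**, before
  any test was written, by a single n=20 000 simulation targeting the
  documented ≈0.77 death fraction, and then frozen in `CohortConfig`.
- **Missingness**: `inject_missingness` applies documented per-field
  missing rates (AFP, AST, albumin, INR, tumour-size group) independently,
  so complete-case analysis keeps ≈85% of rows, matching the documented
  500-of-588 complete-case fraction.

### What the generator does and does not emulate

It reproduces the marginal covariate distributions, the documented
survival-time distribution *conditional on covariates* (exactly, since times
come from the model itself), the death fraction, and the complete-case
fraction. It does **not** reproduce the real joint covariate distribution:
covariates are sampled independently, whereas in patients albumin, AST, AFP
and vascular invasion are correlated through underlying liver disease. As a
result the spread of the prognostic index — and hence discrimination — is in
the right range but not a calibration target; missingness is injected
completely at random, not informatively. The generator is a test harness and
power-study tool, not a population simulator.

## 5. Numerical choices and conventions

- Times in **months**, natural logarithms throughout.
- `NOT_REACHED = inf` marks medians beyond the horizon; the CLI writes them
  as empty cells. Evaluations beyond 31.28 months raise
  `ExtrapolationWarning` but still return the (linearly extrapolated
  log-cumulative-hazard) value.
- Individual predicted medians via Brent root-finding on
  `s(x) = ln ln 2 − η`.
- Centile cutoffs use the ceiling-rank (type-1) convention
  `k = ⌈n·c/100⌉`, chosen because it reproduces the exact documented group
  sizes at n=500.
- The CLI hard-errors (exit 1) on `time_unit` other than months and on
  inputs whose median survival time is implausibly small for months
  (median < 1.5 with n ≥ 20), because silent year/month confusion is the
  most damaging realistic failure mode for a survival calculator.
- Test problem sizes (n=500–2000, 5–25 seeds) were sized so that each
  statistical assertion has comfortable power while the whole suite stays
  fast; seeds were fixed before outcomes were inspected, and simulation
  checks assert across-seed aggregates rather than per-seed tail events.

## 6. Limitations

- The refit engine assumes non-informative censoring and, absent explicit
  time-dependent terms, proportional hazards.
- The published model's constants carry 3–4 significant figures; all
  "exact" reproduction is therefore at the precision those figures support.
- Synthetic-cohort findings about discrimination and calibration validate
  the *software*, not the clinical model: self-consistency on data generated
  from the model is a necessary check, not external validation.
- The generator's independence assumption (§4) means joint-distribution
  statistics (e.g. the correlation between index components) should not be
  read off synthetic cohorts.
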