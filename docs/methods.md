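# Methods

This note documents the statistical models, estimators, numerical choices
and limitations behind `cgmfda`.

## Data model

Postprandial glucose curves are treated as noisy discrete observations of
smooth functions on t ∈ [0, 360] minutes, sampled every 5 minutes
(73 grid points), indexed by subject i = 1..n and within-subject meal
ordinal j = 1..J_i. All functional inner products, norms and integrals use
trapezoidal quadrature on this grid; the weights w(t) are (2.5, 5, …, 5,
2.5) minutes and sum to 360.

### Two-level decomposition (MFPCA)

Y_ij(t) = μ(t) + ν_j(t) + U_i(t) + W_ij(t) + e_ij(t), with fixed mean
functions μ and ν_j (the ν_j obey a count-weighted sum-to-zero constraint
and default to zero — there is no reason to expect a day-ordinal mean
shift in free-living dinners), zero-mean random functions U_i (subject
level) and W_ij (meal level), and white measurement noise e with variance
σ². Each random level is expanded in orthonormal eigenfunctions with
independent Gaussian scores whose variances are the eigenvalues; by
convention eigenvalues decrease and eigenfunctions are signed so that the
grid point of largest absolute value is positive (sign is not identified
otherwise, and tests need reproducible signs).

### Regression model (FoSR)

Y_ij(t) = Σ_l X_ij,l β_l(t) + α_i(t) + ε_ij(t), with L scalar covariates
(an intercept plus, by default: age, weight, gender, HbA1c, carbohydrates,
fats, proteins, fiber and the glucose 5 minutes before the meal),
coefficient functions β_l, subject random-effect functions α_i, and
residual ε. Predictors are deliberately *not* standardized: coefficient
functions stay in natural units (mg/dL per year, per gram, …).

## Estimation

### Means and covariances

μ̂ is a penalized-spline smooth of the cross-sectional mean curve. Level
covariances come from method-of-moments residual cross-products: the
same-curve average estimates K_total(s,t) (whose diagonal carries the σ²
nugget), the within-subject different-meal average estimates the
between-subject surface K_B(s,t), and K_W = K_total − K_B. Surfaces are
smoothed by tensor-product cubic P-splines (15 basis functions per axis,
second-order difference penalty, penalty chosen by GCV); K_total and K_W
are fitted with the diagonal excluded, and σ̂² is the average excess of
the raw K_total diagonal over its smoothed version, floored at zero.
Eigenpairs solve the quadrature-weighted eigenproblem
W^{1/2} K W^{1/2} u = λ u, φ = W^{-1/2} u; negative eigenvalues are
truncated to zero.

### Scores

Scores are best linear unbiased predictors: for each subject the J_i
residual curves are stacked and the joint-normal system implied by
(Φ, Λ, Ψ, Γ, σ̂²) is solved with one Cholesky factorization per distinct
J_i. When σ̂² = 0 the system is singular and a 1e-8 ridge is added with a
warning. A plain quadrature-projection estimator is available
(`method="projection"`); BLUP shrinks toward zero under noise, projection
does not.

### Pointwise mixed models

At each grid point the FoSR model is a linear mixed model with one random
intercept per subject. Its marginal covariance is σ_e²(I + ρ Z Zᵀ) with
ρ = σ_u²/σ_e², so REML profiles down to a one-dimensional search over ρ
using only per-subject sufficient statistics (group sums of X and y); each
of the 73 fits costs microseconds, which is what makes the recovery and
coverage simulations (thousands of full fits) affordable. The search runs
over log ρ ∈ [−14, 10] with an explicit comparison against ρ = 0; a
boundary estimate is recorded as a variance-component collapse and the fit
reduces exactly to ordinary least squares there. The implementation is
cross-checked in the test suite against statsmodels' MixedLM on a single
grid point (agreement ~1e-6 relative).

### Coefficient smoothing and uncertainty

Raw β̂_l(t) sequences are smoothed across t by a cubic P-spline (35 basis
functions, GCV penalty; uniform extended knots so the penalty null space
contains exactly the linear functions, leaving linear coefficient
functions untouched). The reported pointwise standard error is the *raw*
REML standard error, not a variance propagated through the smoother:
pointwise estimation errors are strongly correlated across t whenever the
subject deviations α_i(t) are smooth, and under that correlation the
independent-error propagation is badly anti-conservative (simulated
coverage near 50% for subject-level covariates). Keeping the raw standard
error is exact in the perfectly correlated limit and conservative
otherwise; simulated grid-averaged 95% coverage is ≈0.94 for
subject-level and 0.99–1.0 for meal-level covariates at n = 200, J = 4.

Random-effect functions are the per-t BLUPs of the random intercepts,
smoothed across t with one shared GCV penalty (chosen on the
largest-signal subject) and centered so the subject average is exactly
zero at every t.

### Simultaneous confidence bands

Pointwise bands are β̂ ± z·se. Joint bands resample subjects with
replacement B times (default 1000, seeded); each resample is refit
pointwise by GLS with the variance ratio ρ(t) and the coefficient
smoother frozen at their full-data values — refitting with a *matched*
estimator matters, since ordinary-least-squares refits are far less
efficient for within-subject covariates and would inflate the band
multiplier several-fold. The band multiplier is the level-quantile of the
maximum standardized deviation over the grid, floored at z so the joint
band always contains the pointwise band. B < 100 triggers a warning.

### Functional R²

R̃²(t) = 1 − SSE(t)/SST(t) over all (i,j) curves, with the cross-curve
mean as reference; sums run over observed pairs, so unbalanced J_i are
handled by definition. Values may be negative (a predictor worse than the
mean) and are never floored. Grid points with zero SST are flagged
undefined and excluded with weight renormalization. The global statistic
is the trapezoid-weighted average — exact for piecewise-linear pointwise
curves. Variants: MFPCA participant-level (μ̂ + ν̂_j + Σ a φ) versus full
(adds Σ b ψ), and FoSR marginal (fixed part) versus conditional (adds
α̂_i). All R² values are in-sample by design; they measure representation,
not prediction. `select_components_by_r2` refits scores at K = H = 1..max
against eigenpairs estimated once at the maximum (the truncations are
nested), reporting the full-model global R̃² per K; the default K = H = 3
reflects the elbow of that curve on postprandial CGM data.

## Preprocessing rules

- The entire first midnight-to-midnight wear day is discarded (sensor
  accuracy is markedly lower on day one).
- Any later calendar day containing a missing run *strictly* longer than
  120 minutes is discarded whole; a 120-minute run is retained. Days are
  midnight-to-midnight; runs at day boundaries count only within the
  stream's observed span. Filtering is idempotent because the original
  wear start is carried on the filtered stream.
- Windows sample the stream at meal time + grid offsets, accepting the
  nearest observation within ±2.5 minutes (half the cadence), ties broken
  toward the later (post-meal) sample.
- A window is kept iff ≥80% of grid points are observed and no missing
  run exceeds 30 minutes; retained gaps are filled by linear interpolation
  (nearest-value extension at the window edges). The rule is a design
  choice — the day-level exclusion philosophy applied within windows.
- Meals closer together than the window span produce overlapping windows;
  both are retained and the overlap is flagged, since there is no
  principled reason to prefer one meal.
- An optional finger-stick calibration-count predicate can be supplied to
  the filters by composing with `apply_quality_filters`; it is off by
  default because the synthetic streams carry no calibration channel.

## Synthetic data generator

The generator exists so that every estimator can be validated by parameter
recovery. Defaults define the study conditions:

- Grid 0–360 min by 5 min; global mean 100 + 45·(t/60)·exp(1 − t/60)
  mg/dL (baseline ~100, peak ~145 near 60–75 min).
- Three orthonormal eigenfunctions per level, built by Gram–Schmidt from a
  shape library: a near-constant level shift with shallow concavity
  peaking ~100 min, a pronounced peak at 60–80 min, and a late-versus-
  early peak contrast. The same library serves both levels (their
  empirical modes are similar in real postprandial data).
- Eigenvalue mass 400·360 (time-averaged pointwise process variance
  (20 mg/dL)²), split 33:67 between subject and meal levels and 60:30:10
  within each level. Measurement noise 2 mg/dL — small relative to the
  process, keeping recovery tests sharp; the sensor's true noise magnitude
  is not publicly characterized beyond an overall MARD ≈ 12%, so this is
  a modeling choice.
- Day effects ν_j default to zero; non-zero sets must sum to zero.
- α_i(t) is a squared-exponential Gaussian process, sd 10 mg/dL,
  length-scale 60 min — any smooth zero-mean process satisfies the model
  assumptions; this one is the simplest with a controllable scale.
- Covariates mimic published cohort marginals (glycemic group drawn with
  P(prediabetes) = 58/377, then group-specific truncated normals for age,
  weight, HbA1c, macronutrients, initial glucose; gender Bernoulli).
  Draws are independent given the group: joint dependence between
  covariates is *not* modeled, so collinearity-driven behavior of real
  cohorts is outside what these tests can show.
- ε_ij(t) in the regression generator is white noise (sd = `noise_sd`),
  exactly the model's residual term; real residuals are smoother.
- One root seed feeds fixed per-component substreams (subject scores,
  meal scores, noise, covariates, random effects, raw stream), so adding
  meals does not perturb subject-level draws and identical seeds give
  bit-identical output.
- The raw-stream generator overlays model curves on a flat basal level at
  one dinner per day, at a configurable clock time, with scripted missing
  runs; it emulates gaps and truncation, not circadian baselines,
  activity, snacking or sensor drift.

Because the generator realizes the estimation models exactly, passing
recovery tests demonstrates correctness of the estimators — not robustness
to model misspecification on real CGM data.

## Numerical choices

- Quadrature: trapezoidal everywhere.
- P-spline penalty selection: GCV over a fixed log-spaced grid
  (Demmler–Reinsch form, so all penalties reuse one eigendecomposition);
  `smoothing="none"` bypasses the smoother entirely.
- Eigenvalue truncation at zero; covariance symmetrization by averaging
  with the transpose.
- Singular score systems: ridge jitter 1e-8 with a warning. Singular
  bootstrap design matrices (e.g. an all-female resample): pseudo-inverse
  fallback.
- Serialization: all numeric text output at 12 significant digits; reading
  canonicalizes row order. Two pipeline runs with one seed are
  byte-identical.
- Simulation sizes in the test suite (n = 150–200 subjects, 4 meals,
  20–50 replicates) were chosen as the smallest designs at which the
  recovery targets are stable across seeds.

## Known limitations

- The mean-function recovery bound (max error < 2 mg/dL at n = 150) holds
  in the median across replicates, not per replicate; subject-level
  sampling noise alone produces occasional ~3–4 mg/dL worst-case errors.
- The estimated subject-level variance share runs ~1–3 points below the
  generative 33% at n = 150 (smoothing shrinkage and finite-sample
  truncation); the recovery test tolerates ±7 points.
- Pointwise intervals are conservative for meal-level covariates (coverage
  near 1) — the price of the correlation-robust standard error.
- Joint bands are bootstrap-based; their level is approximate and no
  multiplicity correction beyond joint-over-t per covariate is applied.
- No sparse/irregular-grid support: all curves share one grid. Timezone
  arithmetic is naive local time.
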