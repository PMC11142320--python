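# cgmfda

Multilevel functional data analysis of postprandial continuous glucose
monitoring (CGM) curves.

## The problem

A CGM sensor samples interstitial glucose every 5 minutes. After each meal
the glucose trace follows a smooth 6-hour trajectory Y_ij(t), t ∈ [0, 360]
minutes, for subject i and meal j — and the interesting structure lives at
two levels at once: stable differences *between* people and meal-to-meal
variation *within* a person. Classical scalar summaries (2-h AUC, peak
glucose) throw the temporal information away. This package implements the
hierarchical functional pipeline that keeps it, for biostatisticians and
epidemiologists analysing free-living CGM cohorts:

1. **Preprocessing** — quality filters (first wear day discarded; any
   calendar day with a signal-loss run strictly longer than 2 h discarded)
   and extraction of 6-hour post-dinner windows on a common 5-minute grid,
   plus the initial-glucose covariate measured 5 minutes before the meal.
2. **Multilevel functional PCA (MFPCA)** — the two-level decomposition

       Y_ij(t) = μ(t) + ν_j(t) + U_i(t) + W_ij(t),
       U_i(t)  = Σ_k a_ik φ_k(t),     W_ij(t) = Σ_h b_ijh ψ_h(t),

   with orthonormal eigenfunctions φ_k (subject level) and ψ_h (meal
   level), Gaussian scores with variances λ_k and γ_h, estimated by
   method-of-moments covariance separation, penalized-spline surface
   smoothing, quadrature eigendecomposition, and BLUP scores.
3. **Function-on-scalar regression (FoSR)** — pointwise linear mixed models

       Y_ij(t) = Σ_l X_ij,l β_l(t) + α_i(t) + ε_ij(t)

   fit by closed-form profile REML at every grid point (a random intercept
   per subject), coefficient functions smoothed across t, subject
   random-effect functions α_i(t), and simultaneous confidence bands from
   a subject-level bootstrap of the maximum standardized deviation.
4. **Functional R²** — pointwise R̃²(t) = 1 − SSE(t)/SST(t) across all
   (i, j) curves and its trapezoid-weighted global summary
   R̃² = (1/360) Σ_t w(t) R̃²(t), in four variants: MFPCA participant-level
   and full-hierarchy, FoSR marginal (fixed effects) and conditional
   (fixed + random). The same statistic drives elbow-style selection of
   the number of eigenfunctions.
5. **Synthetic data** — a generator that draws data from exactly these two
   models with known ground truth (default: 33% of process variance at the
   subject level, 67% at the meal level; covariate marginals matching a
   population cohort), so every stage is validated by parameter recovery.

## Worked example

```python
import numpy as np
from cgmfda import (GenerativeConfig, FoSROptions, fit_fosr, fit_mfpca,
                    fosr_r2, mfpca_r2, variance_proportions)
from cgmfda.simulate import simulate_fosr_dataset, simulate_mfpca_dataset

# two-level curves: 150 subjects x 4 dinners on the 73-point grid
cfg = GenerativeConfig(n_subjects=150, meals_per_subject=4, seed=1)
dataset, truth = simulate_mfpca_dataset(cfg)
model = fit_mfpca(dataset, K=3, H=3)
subject_share, meal_share = variance_proportions(model)
print(f"subject-level variance share: {subject_share:.2f}")
print(f"meal-level variance share:    {meal_share:.2f}")
part, full = mfpca_r2(model, dataset)
print(f"participant-level global R2:  {part.global_value:.2f}")
print(f"full-model global R2:         {full.global_value:.2f}")

# regression: 200 subjects, 10 covariates, subject random-effect functions
cfg = GenerativeConfig(n_subjects=200, meals_per_subject=4, seed=2)
dataset, covariates, truth = simulate_fosr_dataset(cfg)
fosr = fit_fosr(dataset, covariates, options=FoSROptions(band_B=500, seed=2))
carb = fosr.coef_names.index("carbohydrates")
peak = np.argmax(fosr.beta[carb])
print(f"carbohydrate effect peaks at t = {fosr.grid.points[peak]:.0f} min "
      f"({fosr.beta[carb][peak]:.3f} mg/dL per gram)")
marg, cond = fosr_r2(fosr, dataset, covariates)
print(f"marginal global R2:    {marg.global_value:.2f}")
print(f"conditional global R2: {cond.global_value:.2f}")
```

Output:

```
subject-level variance share: 0.30
meal-level variance share:    0.70
participant-level global R2:  0.40
full-model global R2:         0.99
carbohydrate effect peaks at t = 70 min (0.198 mg/dL per gram)
marginal global R2:    0.30
conditional global R2: 0.97
```

Reading the numbers: roughly a third of the process variance sits between
subjects, matching the generator's 33:67 calibration. The participant-level
MFPCA reconstruction explains ~40% of curve variance while the full
hierarchy explains ~99% (noise is small relative to the meal-level
process). In the regression, the carbohydrate coefficient function peaks
near 70 minutes post-meal at ~0.2 mg/dL per gram, and adding the subject
random-effect functions lifts the variance explained from 0.30 (marginal)
to 0.97 (conditional) — the signature of strong between-person
heterogeneity.

## Command line

Every stage is also a `cgmfda` subcommand (`simulate`, `preprocess`,
`mfpca`, `fosr`, `r2`, `run`), each accepting `--seed`, `--out` and
`--log-level`. `cgmfda run` executes the whole pipeline from a YAML config
(or demo defaults) and writes a manifest sufficient to re-run
byte-identically.

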