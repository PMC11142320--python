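"""Function-on-scalar regression with subject random-effect functions.

The model is Y_ij(t) = sum_l X_ij,l beta_l(t) + alpha_i(t) + eps_ij(t).
Estimation is pointwise: at each grid point a linear mixed model with a
subject random intercept is fit by REML; the coefficient sequences are
then smoothed across t with penalized splines, with the pointwise
variance propagated through the (linear) smoother.  Joint confidence
bands come from a subject-level bootstrap of the maximum standardized
deviation over the grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .containers import CovariateTable, PostprandialDataset, check_design_rank
from .grid import Grid
from .lmm import PointwiseLMMFit, fit_random_intercept, gls_beta_fixed_rho
from .smoothing import PSpline1D


@dataclass
class FoSROptions:
    smoothing: str = "gcv"      # "gcv" (penalized spline) or "none"
    compute_bands: bool = True
    band_level: float = 0.95
    band_B: int = 1000
    seed: int = 0
    score_se_floor: float = 1e-10


@dataclass
class FoSRModel:
    grid: Grid
    coef_names: list[str]
    beta: np.ndarray            # (L, m) smoothed coefficient functions
    beta_se: np.ndarray         # (L, m) propagated pointwise standard errors
    beta_raw: np.ndarray        # (L, m) pointwise REML estimates
    beta_se_raw: np.ndarray     # (L, m)
    alpha: np.ndarray           # (n, m) smoothed, centered random-effect functions
    subject_labels: np.ndarray  # (n,)
    sigma2_eps: np.ndarray      # (m,) residual variance per grid point
    sigma2_alpha: np.ndarray    # (m,) random-intercept variance per grid point
    stratum: str = "all"
    bands: dict = field(default_factory=dict)
    # internal state needed by the bootstrap band machinery
    _X: np.ndarray | None = field(default=None, repr=False)
    _Y: np.ndarray | None = field(default=None, repr=False)
    _codes: np.ndarray | None = field(default=None, repr=False)
    _smoothers: list | None = field(default=None, repr=False)

    def subject_code(self, label) -> int:
        idx = np.where(self.subject_labels == label)[0]
        if idx.size == 0:
            raise ValueError(
                f"subject {label!r} was not in the fitted data; conditional "
                "prediction is unavailable -- use marginal prediction instead"
            )
        return int(idx[0])


def _align(dataset: PostprandialDataset, covariates: CovariateTable) -> None:
    if covariates.n_rows != dataset.n_rows:
        raise ValueError("covariate table and dataset have different row counts")
    same_subj = np.array_equal(
        covariates.frame["subject_id"].to_numpy(), dataset.subject_ids
    )
    same_meal = np.array_equal(
        covariates.frame["meal_index"].to_numpy(dtype=int), dataset.meal_index
    )
    if not (same_subj and same_meal):
        raise ValueError("covariate rows are not aligned with dataset rows")


def fit_fosr_pointwise(
    dataset: PostprandialDataset, covariates: CovariateTable
) -> PointwiseLMMFit:
    """Raw pointwise REML estimates at every grid point."""
    _align(dataset, covariates)
    codes, labels = dataset.subject_codes()
    if labels.size < 2:
        raise ValueError("a single subject cannot identify the random effect")
    counts = np.bincount(codes)
    if np.sum(counts >= 2) < 2:
        raise ValueError(
            "need at least two subjects with two or more meals to separate "
            "the random-effect variance from the residual variance"
        )
    X = covariates.design_matrix()
    check_design_rank(X, covariates.design_columns)
    fit = fit_random_intercept(X, dataset.curves, codes, n_groups=labels.size)
    if fit.collapsed.any():
        warnings.warn(
            f"random-effect variance collapsed to zero at "
            f"{int(fit.collapsed.sum())} grid points (generalized least squares "
            "with zero random variance used there)"
        )
    return fit


def smooth_coefficients(
    raw: PointwiseLMMFit,
    grid: Grid,
    coef_names: list[str],
    smoothing: str = "gcv",
) -> tuple[np.ndarray, np.ndarray, list]:
    """Smooth each beta_l(t) across t, keeping the pointwise REML variance.

    The pointwise errors of beta_l(t) are strongly correlated across t
    whenever the subject deviations are smooth, so propagating the raw
    variance through the smoother as if the errors were independent is
    anti-conservative; the raw REML standard error is exact in the
    perfectly correlated limit and conservative otherwise, so it is kept
    as the pointwise uncertainty of the smoothed estimate.

    Returns (beta, beta_se, smoother_matrices); with smoothing "none" the
    smoother is the identity and the raw estimates pass through unchanged.
    """
    m, L = raw.beta.shape
    beta = np.empty((L, m))
    beta_se = raw.beta_se.T.copy()
    smoothers: list = []
    if smoothing == "none":
        for l in range(L):
            beta[l] = raw.beta[:, l]
            smoothers.append(None)
        return beta, beta_se, smoothers
    if smoothing != "gcv":
        raise ValueError(f"unknown smoothing option: {smoothing!r}")
    sm = PSpline1D(grid.points, n_basis=35)
    for l in range(L):
        try:
            lam = sm.select_lambda(raw.beta[:, l])
        except Exception:  # pragma: no cover - defensive fallback
            warnings.warn(
                f"smoothing-parameter search failed for {coef_names[l]}; "
                "using a fixed moderate penalty"
            )
            lam = 1.0
        S = sm.smoother_matrix(lam)
        beta[l] = S @ raw.beta[:, l]
        smoothers.append(S)
    return beta, beta_se, smoothers


def estimate_random_effect_functions(
    raw: PointwiseLMMFit, grid: Grid, smoothing: str = "gcv"
) -> np.ndarray:
    """Smooth per-subject pointwise predictions, centered to mean zero."""
    blup = raw.blup
    if smoothing == "gcv":
        sm = PSpline1D(grid.points)
        # one shared penalty, chosen on the subject with the largest signal,
        # keeps the n smoothing problems cheap and the curves comparable
        ref = blup[np.argmax(np.sum(blup**2, axis=1))]
        lam = sm.select_lambda(ref)
        S = sm.smoother_matrix(lam)
        alpha = blup @ S.T
    else:
        alpha = blup.copy()
    alpha -= alpha.mean(axis=0, keepdims=True)
    return alpha


def joint_confidence_bands(
    model: FoSRModel,
    level: float = 0.95,
    B: int = 1000,
    seed: int = 0,
) -> dict:
    """Pointwise and joint (simultaneous) bands for every coefficient.

    Pointwise: beta +- z * se.  Joint: subjects are resampled with
    replacement B times; each resample is refit pointwise by generalized
    least squares with the variance ratio and the coefficient smoother
    frozen at their full-data values, and the max over t of the
    standardized deviation from the full-data estimate is collected.  The
    band multiplier is the ``level`` quantile of that max statistic,
    floored at the pointwise normal quantile so the joint band always
    contains the pointwise band.
    """
    if model._X is None:
        raise ValueError("model lacks band machinery (was it deserialized?)")
    if B < 100:
        warnings.warn("B < 100 bootstrap resamples give an unstable quantile")
    rng = np.random.default_rng(seed)
    X, Y, codes = model._X, model._Y, model._codes
    n = model.subject_labels.size
    L, m = model.beta.shape
    z = float(norm.ppf(0.5 + level / 2.0))
    se = np.maximum(model.beta_se, 1e-12)

    rho = np.where(
        model.sigma2_eps > 0, model.sigma2_alpha / np.maximum(model.sigma2_eps, 1e-300), 0.0
    )
    rows_of = [np.where(codes == i)[0] for i in range(n)]
    maxdev = np.empty((B, L))
    for b_i in range(B):
        pick = rng.integers(0, n, size=n)
        rows = np.concatenate([rows_of[i] for i in pick])
        new_codes = np.repeat(np.arange(n), [rows_of[i].size for i in pick])
        beta_raw = gls_beta_fixed_rho(
            X[rows], Y[rows], new_codes, rho, n_groups=n
        )  # (m, L)
        for l in range(L):
            bl = beta_raw[:, l]
            if model._smoothers is not None and model._smoothers[l] is not None:
                bl = model._smoothers[l] @ bl
            maxdev[b_i, l] = np.max(np.abs(bl - model.beta[l]) / se[l])
    bands: dict = {}
    for l, name in enumerate(model.coef_names):
        q = float(np.quantile(maxdev[:, l], level))
        mult = max(q, z)
        bands[name] = {
            "pointwise_lower": model.beta[l] - z * se[l],
            "pointwise_upper": model.beta[l] + z * se[l],
            "joint_lower": model.beta[l] - mult * se[l],
            "joint_upper": model.beta[l] + mult * se[l],
            "multiplier": mult,
            "level": level,
        }
    return bands


def predict(
    model: FoSRModel, covariates: CovariateTable, mode: str = "marginal"
) -> np.ndarray:
    """Fitted trajectories: fixed part only (marginal) or plus alpha_i
    (conditional); conditional minus marginal is exactly alpha_i(t)."""
    if mode not in ("marginal", "conditional"):
        raise ValueError(f"mode must be 'marginal' or 'conditional', got {mode!r}")
    X = covariates.design_matrix(model.coef_names)
    fitted = X @ model.beta
    if mode == "conditional":
        codes = np.array(
            [model.subject_code(s) for s in covariates.frame["subject_id"]]
        )
        fitted = fitted + model.alpha[codes]
    return fitted


def fit_fosr(
    dataset: PostprandialDataset,
    covariates: CovariateTable,
    stratum: str | None = None,
    options: FoSROptions | None = None,
) -> FoSRModel:
    """Fit the full FoSR pipeline, optionally within one glycemic stratum."""
    opts = options or FoSROptions()
    if stratum not in (None, "all"):
        mask = (covariates.frame["group"] == stratum).to_numpy()
        if not mask.any():
            raise ValueError(f"stratum {stratum!r} selects no rows")
        dataset = PostprandialDataset(
            grid=dataset.grid,
            curves=dataset.curves[mask],
            subject_ids=dataset.subject_ids[mask],
            meal_index=dataset.meal_index[mask],
        )
        covariates = covariates.subset(mask)

    codes, labels = dataset.subject_codes()
    if labels.size < 10:
        warnings.warn(
            f"stratum has only {labels.size} subjects; confidence bands will "
            "be unreliable at this sample size"
        )
    raw = fit_fosr_pointwise(dataset, covariates)
    beta, beta_se, smoothers = smooth_coefficients(
        raw, dataset.grid, covariates.design_columns, smoothing=opts.smoothing
    )
    alpha = estimate_random_effect_functions(raw, dataset.grid, smoothing=opts.smoothing)
    model = FoSRModel(
        grid=dataset.grid,
        coef_names=list(covariates.design_columns),
        beta=beta,
        beta_se=beta_se,
        beta_raw=raw.beta.T.copy(),
        beta_se_raw=raw.beta_se.T.copy(),
        alpha=alpha,
        subject_labels=labels,
        sigma2_eps=raw.sigma2_e.copy(),
        sigma2_alpha=raw.sigma2_u.copy(),
        stratum=stratum or "all",
        _X=covariates.design_matrix(),
        _Y=dataset.curves,
        _codes=codes,
        _smoothers=smoothers,
    )
    if opts.compute_bands:
        model.bands = joint_confidence_bands(
            model, level=opts.band_level, B=opts.band_B, seed=opts.seed
        )
    return model
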