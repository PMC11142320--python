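"""Pointwise and global R-squared for hierarchical functional models.

At each grid point the classical coefficient of determination is computed
across all (subject, meal) curves,

    R2(t) = 1 - SSE(t) / SST(t),

with the cross-curve mean as the reference; the global summary integrates
the pointwise curve over the 6-hour domain with trapezoidal quadrature
weights and divides by the domain length.  Four variants are supported:
MFPCA restricted to the participant level or using the full hierarchy,
and FoSR with fixed effects only (marginal) or fixed plus subject
random-effect functions (conditional).  Pointwise values may be negative
(a predictor worse than the mean); they are never floored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CovariateTable, PostprandialDataset
from .fosr import FoSRModel, predict
from .grid import Grid
from .mfpca import MFPCAModel, fit_mfpca, reconstruct


@dataclass
class R2Result:
    """Pointwise curve, quadrature weights and global scalar for one variant.

    ``weights`` are the trapezoidal weights actually used: zero at grid
    points where R2 is undefined (zero total sum of squares), so that
    ``global_value`` always equals the weighted average of the finite
    pointwise values with the stored weights.
    """

    grid: Grid
    pointwise: np.ndarray     # (m,), NaN where undefined
    weights: np.ndarray       # (m,), zeroed at undefined points
    global_value: float
    variant: str

    def recompute_global(self) -> float:
        ok = self.weights > 0
        return float(np.sum(self.weights[ok] * self.pointwise[ok]) / np.sum(self.weights[ok]))


def pointwise_r2(observed: np.ndarray, fitted: np.ndarray) -> np.ndarray:
    """R2(t) across curves; NaN where all observed values coincide."""
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if observed.shape != fitted.shape:
        raise ValueError("observed and fitted curve arrays must have equal shape")
    if observed.ndim != 2 or observed.shape[0] < 2:
        raise ValueError("need at least two curves")
    ybar = observed.mean(axis=0)
    sse = np.sum((observed - fitted) ** 2, axis=0)
    sst = np.sum((observed - ybar) ** 2, axis=0)
    out = np.full(observed.shape[1], np.nan)
    ok = sst > 0
    if not ok.all():
        warnings.warn(
            f"zero total sum of squares at {int((~ok).sum())} grid points; "
            "R2 undefined there and excluded from the global average"
        )
    out[ok] = 1.0 - sse[ok] / sst[ok]
    return out


def global_r2(pointwise: np.ndarray, grid: Grid) -> float:
    """Quadrature-weighted global value, (1/T) * sum w(t) R2(t).

    Exact for piecewise-linear pointwise curves; undefined (NaN) points
    are dropped with the weights renormalized.
    """
    pointwise = np.asarray(pointwise, dtype=float)
    if grid.n_points < 2:
        raise ValueError("global R2 needs at least two grid points")
    if pointwise.shape != (grid.n_points,):
        raise ValueError("pointwise curve does not match the grid")
    w = grid.trapezoid_weights()
    ok = np.isfinite(pointwise)
    if not ok.any():
        raise ValueError("R2 is undefined at every grid point")
    return float(np.sum(w[ok] * pointwise[ok]) / np.sum(w[ok]))


def _result(observed, fitted, grid: Grid, variant: str) -> R2Result:
    pw = pointwise_r2(observed, fitted)
    w = grid.trapezoid_weights()
    weights = np.where(np.isfinite(pw), w, 0.0)
    return R2Result(
        grid=grid,
        pointwise=pw,
        weights=weights,
        global_value=global_r2(pw, grid),
        variant=variant,
    )


def mfpca_r2(model: MFPCAModel, dataset: PostprandialDataset) -> tuple[R2Result, R2Result]:
    """(participant-level, full-hierarchy) R2 of an MFPCA fit."""
    if model.grid != dataset.grid:
        raise ValueError("model and dataset grids differ")
    if model.meal_index.size != dataset.n_rows:
        raise ValueError("model was not fitted on this dataset")
    part = _result(
        dataset.curves, reconstruct(model, "participant"), dataset.grid,
        "mfpca_participant",
    )
    full = _result(
        dataset.curves, reconstruct(model, "full"), dataset.grid, "mfpca_full"
    )
    return part, full


def fosr_r2(
    model: FoSRModel, dataset: PostprandialDataset, covariates: CovariateTable
) -> tuple[R2Result, R2Result]:
    """(marginal, conditional) R2 of a FoSR fit."""
    if model.grid != dataset.grid:
        raise ValueError("model and dataset grids differ")
    if covariates.n_rows != dataset.n_rows:
        raise ValueError("covariate table does not match the dataset")
    marg = _result(
        dataset.curves, predict(model, covariates, "marginal"), dataset.grid,
        "fosr_marginal",
    )
    cond = _result(
        dataset.curves, predict(model, covariates, "conditional"), dataset.grid,
        "fosr_conditional",
    )
    return marg, cond


def select_components_by_r2(
    dataset: PostprandialDataset,
    max_K: int = 6,
    include_day_effects: bool = False,
    smooth: bool = True,
    score_method: str = "blup",
) -> pd.DataFrame:
    """Global full-model R2 for K = H = 1..max_K (elbow diagnostics).

    The covariance surfaces and eigenpairs are estimated once at
    ``max_K``; truncations reuse the leading eigenpairs and only the
    scores are refit, so the sequence is the nested-model comparison the
    elbow rule requires.
    """
    if max_K < 1:
        raise ValueError("max_K must be at least 1")
    from .mfpca import MFPCAModel as _M  # local alias, avoids confusion below
    from .mfpca import estimate_scores

    full = fit_mfpca(
        dataset, K=max_K, H=max_K, include_day_effects=include_day_effects,
        smooth=smooth, score_method=score_method,
    )
    rows = []
    for k in range(1, max_K + 1):
        sub = _M(
            grid=full.grid,
            mu=full.mu,
            nu=full.nu,
            phi=full.phi[:k],
            lam=full.lam[:k],
            psi=full.psi[:k],
            gam=full.gam[:k],
            scores_subject=np.zeros((full.n_subjects, k)),
            scores_meal=np.zeros((full.meal_index.size, k)),
            noise_var=full.noise_var,
            subject_codes=full.subject_codes,
            subject_labels=full.subject_labels,
            meal_index=full.meal_index,
        )
        a, b = estimate_scores(dataset, sub, method=score_method)
        sub.scores_subject, sub.scores_meal = a, b
        _, r2_full = mfpca_r2(sub, dataset)
        rows.append({"K": k, "global_r2_full": r2_full.global_value})
    return pd.DataFrame(rows)
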