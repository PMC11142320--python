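"""Fast profile-REML random-intercept linear mixed models.

The function-on-scalar regression stage fits, at every grid point t, the
model

    y = X beta + Z u + e,   u_i ~ N(0, sigma_u^2),  e ~ N(0, sigma_e^2 I),

with one random intercept per subject.  For this covariance structure the
marginal precision has a closed blockwise form, so the REML criterion can
be profiled down to a one-dimensional search over the variance ratio
rho = sigma_u^2 / sigma_e^2 using only per-group sufficient statistics.
That makes the pointwise fit cheap enough to run tens of thousands of
times inside recovery and coverage simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

_LOG_RHO_LO = -14.0
_LOG_RHO_HI = 10.0
_RHO_ZERO_TOL = 1e-8


@dataclass
class PointwiseLMMFit:
    """Per-grid-point REML fits of the random-intercept model.

    All arrays are indexed by grid point along the first axis unless noted.
    """

    beta: np.ndarray        # (m, p) fixed-effect estimates
    beta_se: np.ndarray     # (m, p) standard errors
    beta_cov: np.ndarray    # (m, p, p) covariance of beta-hat
    sigma2_e: np.ndarray    # (m,) residual variance
    sigma2_u: np.ndarray    # (m,) random-intercept variance
    blup: np.ndarray        # (n_groups, m) predicted random intercepts
    collapsed: np.ndarray   # (m,) bool, True where sigma2_u -> 0


def _reml_criterion(rho, mg, XtX, Sg, XtY_t, Tg_t, yty_t, N, p):
    """-2 restricted log-likelihood (up to constants), profiled over
    sigma_e^2 and beta, as a function of the variance ratio rho."""
    c = rho / (1.0 + rho * mg)
    XtWX = XtX - (Sg * c[:, None]).T @ Sg
    XtWy = XtY_t - Sg.T @ (c * Tg_t)
    yWy = yty_t - float(c @ (Tg_t**2))
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    rss = max(yWy - float(beta @ XtWy), 1e-300)
    sign, logdet_xwx = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return np.inf, None, None
    logdet_v = float(np.sum(np.log1p(rho * mg)))
    crit = (N - p) * np.log(rss) + logdet_v + logdet_xwx
    return crit, beta, (XtWX, rss)


def fit_random_intercept(
    X: np.ndarray, Y: np.ndarray, codes: np.ndarray, n_groups: int | None = None
) -> PointwiseLMMFit:
    """Fit the random-intercept LMM by REML at every column of ``Y``.

    Parameters
    ----------
    X : (N, p) design matrix, shared across grid points.
    Y : (N, m) responses; column t is the glucose at grid point t.
    codes : (N,) integer subject codes in 0..n_groups-1.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    codes = np.asarray(codes, dtype=int)
    N, p = X.shape
    m = Y.shape[1]
    if n_groups is None:
        n_groups = int(codes.max()) + 1
    if n_groups < 2:
        raise ValueError("random intercept needs at least two subjects")

    mg = np.bincount(codes, minlength=n_groups).astype(float)
    XtX = X.T @ X
    Sg = np.zeros((n_groups, p))
    np.add.at(Sg, codes, X)
    XtY = X.T @ Y
    Tg = np.zeros((n_groups, m))
    np.add.at(Tg, codes, Y)
    yty = np.einsum("nm,nm->m", Y, Y)

    beta = np.empty((m, p))
    beta_se = np.empty((m, p))
    beta_cov = np.empty((m, p, p))
    sigma2_e = np.empty(m)
    sigma2_u = np.empty(m)
    blup = np.empty((n_groups, m))
    collapsed = np.zeros(m, dtype=bool)

    for t in range(m):
        args = (mg, XtX, Sg, XtY[:, t], Tg[:, t], yty[t], N, p)

        def crit_of_zeta(zeta):
            return _reml_criterion(np.exp(zeta), *args)[0]

        res = minimize_scalar(
            crit_of_zeta,
            bounds=(_LOG_RHO_LO, _LOG_RHO_HI),
            method="bounded",
            options={"xatol": 1e-6},
        )
        rho = float(np.exp(res.x))
        crit_zero, _, _ = _reml_criterion(0.0, *args)
        if crit_zero <= res.fun or rho < _RHO_ZERO_TOL:
            rho = 0.0
        crit, b, extra = _reml_criterion(rho, *args)
        XtWX, rss = extra
        s2e = rss / (N - p)
        cov = s2e * np.linalg.inv(XtWX)
        beta[t] = b
        beta_cov[t] = cov
        beta_se[t] = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        sigma2_e[t] = s2e
        sigma2_u[t] = rho * s2e
        collapsed[t] = rho == 0.0
        resid_sums = Tg[:, t] - Sg @ b
        blup[:, t] = rho * resid_sums / (1.0 + rho * mg)

    return PointwiseLMMFit(
        beta=beta,
        beta_se=beta_se,
        beta_cov=beta_cov,
        sigma2_e=sigma2_e,
        sigma2_u=sigma2_u,
        blup=blup,
        collapsed=collapsed,
    )


def pointwise_ols(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """OLS coefficients for every column of ``Y`` at once; returns (m, p)."""
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return coef.T


def gls_beta_fixed_rho(
    X: np.ndarray, Y: np.ndarray, codes: np.ndarray, rho: np.ndarray,
    n_groups: int | None = None,
) -> np.ndarray:
    """GLS coefficients at every grid point with frozen variance ratios.

    ``rho`` holds sigma_u^2/sigma_e^2 per grid point (e.g. the full-data
    REML estimates); the solve is batched over grid points, which makes
    bootstrap refits with the same estimator as the original fit cheap.
    Returns (m, p).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    codes = np.asarray(codes, dtype=int)
    rho = np.asarray(rho, dtype=float)
    N, p = X.shape
    m = Y.shape[1]
    if n_groups is None:
        n_groups = int(codes.max()) + 1
    mg = np.bincount(codes, minlength=n_groups).astype(float)
    S = np.zeros((n_groups, p))
    np.add.at(S, codes, X)
    Tg = np.zeros((n_groups, m))
    np.add.at(Tg, codes, Y)
    C = rho[None, :] / (1.0 + rho[None, :] * mg[:, None])  # (G, m)
    XtWX = (X.T @ X)[None, :, :] - np.einsum("gt,gp,gq->tpq", C, S, S)
    XtWy = (X.T @ Y).T - np.einsum("gt,gp->tp", C * Tg, S)
    try:
        return np.linalg.solve(XtWX, XtWy[..., None])[..., 0]
    except np.linalg.LinAlgError:
        # resampling can momentarily flatten a covariate (e.g. an all-female
        # bootstrap draw); the pseudo-inverse keeps the replicate usable
        return np.einsum("tpq,tq->tp", np.linalg.pinv(XtWX), XtWy)
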