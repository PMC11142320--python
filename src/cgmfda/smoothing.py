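"""Penalized B-spline smoothers.

One-dimensional smoothing (mean functions, coefficient functions, random
effect functions) uses cubic B-splines with a second-order difference
penalty in Demmler-Reinsch form, so the smoother matrix and effective
degrees of freedom are cheap for any penalty value; the penalty is chosen
by generalized cross-validation (GCV).

Two-dimensional smoothing (covariance surfaces) uses a tensor-product of
the same basis with an additive difference penalty; the diagonal of the
surface can be excluded from the fit, which is how the measurement-error
nugget is separated from the smooth covariance.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve, cholesky, eigh, solve_triangular


def bspline_basis(x: np.ndarray, n_basis: int, degree: int = 3) -> np.ndarray:
    """Evaluate an equally spaced B-spline basis on ``x`` (dense, m x p)."""
    x = np.asarray(x, dtype=float)
    n_seg = n_basis - degree
    if n_seg < 1:
        raise ValueError("n_basis too small for the requested degree")
    h = (x[-1] - x[0]) / n_seg
    # uniform knots extended beyond both ends: keeps the difference-penalty
    # null space exactly equal to the polynomials it should contain
    knots = x[0] + h * np.arange(-degree, n_seg + degree + 1)
    dm = BSpline.design_matrix(x, knots, degree, extrapolate=True)
    return np.asarray(dm.todense())


def difference_penalty(p: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(p), n=order, axis=0)
    return d.T @ d


DEFAULT_LAMBDAS = np.logspace(-4.0, 10.0, 29)


class PSpline1D:
    """Cubic P-spline smoother on a fixed grid with GCV penalty selection."""

    def __init__(self, x: np.ndarray, n_basis: int | None = None):
        x = np.asarray(x, dtype=float)
        self.x = x
        m = x.size
        if n_basis is None:
            n_basis = min(max(m // 3, 8), 30)
        self.n_basis = n_basis
        B = bspline_basis(x, n_basis)
        P = difference_penalty(n_basis)
        BtB = B.T @ B
        # tiny ridge keeps the Cholesky stable when basis functions overlap little
        BtB[np.diag_indices_from(BtB)] += 1e-10 * np.trace(BtB) / n_basis
        R = cholesky(BtB, lower=False)
        Rinv = solve_triangular(R, np.eye(n_basis), lower=False)
        A = Rinv.T @ P @ Rinv
        s, U = eigh((A + A.T) / 2.0)
        self.s = np.clip(s, 0.0, None)
        self.Q = B @ (Rinv @ U)  # m x p, Q'Q = I

    def smoother_matrix(self, lam: float) -> np.ndarray:
        d = 1.0 / (1.0 + lam * self.s)
        return (self.Q * d) @ self.Q.T

    def select_lambda(self, y: np.ndarray, lambdas: np.ndarray = DEFAULT_LAMBDAS) -> float:
        """GCV choice of the penalty for one curve."""
        y = np.asarray(y, dtype=float)
        m = y.size
        z = self.Q.T @ y
        yty = float(y @ y)
        best = (np.inf, lambdas[0])
        for lam in lambdas:
            d = 1.0 / (1.0 + lam * self.s)
            # rss = ||y||^2 - 2 z'(dz) + ||dz||^2
            rss = max(yty - 2.0 * float(z @ (d * z)) + float((d * z) @ (d * z)), 0.0)
            edf = float(np.sum(d))
            denom = max(m - edf, 1e-8)
            gcv = m * rss / denom**2
            if gcv < best[0]:
                best = (gcv, lam)
        return float(best[1])

    def fit(self, y: np.ndarray, lam: float | None = None) -> tuple[np.ndarray, float]:
        """Smooth one curve; returns (fitted, lambda used)."""
        y = np.asarray(y, dtype=float)
        if lam is None:
            lam = self.select_lambda(y)
        d = 1.0 / (1.0 + lam * self.s)
        return self.Q @ (d * (self.Q.T @ y)), lam


class PSpline2D:
    """Tensor-product P-spline smoother for symmetric covariance surfaces."""

    def __init__(self, x: np.ndarray, n_basis: int = 15, omit_diagonal: bool = False):
        x = np.asarray(x, dtype=float)
        self.x = x
        self.omit_diagonal = omit_diagonal
        self.B = bspline_basis(x, n_basis)
        p = n_basis
        P1 = difference_penalty(p)
        I = np.eye(p)
        self.P2 = np.kron(P1, I) + np.kron(I, P1)
        G = np.kron(self.B.T @ self.B, self.B.T @ self.B)
        if omit_diagonal:
            for srow in self.B:
                bb = np.outer(srow, srow)
                G -= np.kron(bb, bb)
        G[np.diag_indices_from(G)] += 1e-10 * np.trace(G) / G.shape[0]
        self.G = G
        self.p = p

    def _rhs(self, K: np.ndarray) -> np.ndarray:
        rhs = self.B.T @ K @ self.B
        if self.omit_diagonal:
            rhs -= np.einsum("s,si,sj->ij", np.diag(K), self.B, self.B)
        return rhs.ravel()

    def fit(
        self, K: np.ndarray, lambdas: np.ndarray = np.logspace(-2.0, 12.0, 15)
    ) -> np.ndarray:
        """Smooth a symmetric surface, selecting the penalty by GCV."""
        K = np.asarray(K, dtype=float)
        m = K.shape[0]
        rhs = self._rhs(K)
        mask = ~np.eye(m, dtype=bool) if self.omit_diagonal else np.ones((m, m), bool)
        n_pts = int(mask.sum())
        best = (np.inf, None)
        for lam in lambdas:
            M = self.G + lam * self.P2
            try:
                c = cho_factor(M)
            except np.linalg.LinAlgError:
                continue
            coef = cho_solve(c, rhs)
            edf = float(np.trace(cho_solve(c, self.G)))
            C = coef.reshape(self.p, self.p)
            F = self.B @ C @ self.B.T
            rss = float(np.sum((K - F)[mask] ** 2))
            denom = max(n_pts - edf, 1e-8)
            gcv = n_pts * rss / denom**2
            if gcv < best[0]:
                best = (gcv, F)
        if best[1] is None:
            raise RuntimeError("covariance smoothing failed for every penalty value")
        F = best[1]
        return (F + F.T) / 2.0
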