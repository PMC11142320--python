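"""Orthonormal eigenfunction libraries for the synthetic generator.

The generator needs orthonormal (under trapezoidal quadrature) basis
functions that look like the modes of variation seen in postprandial CGM
curves: a first, almost level-shift component with a shallow concavity
peaking near 100 min, a second component with a pronounced peak around
60-80 min, and a third contrasting late versus early peaks.  Shapes are
specified freely and orthonormalized numerically by Gram-Schmidt.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

from .grid import Grid

ShapeFn = Callable[[np.ndarray], np.ndarray]


def default_shapes() -> list[ShapeFn]:
    """Raw (non-orthogonal) shape library for both hierarchy levels."""
    return [
        lambda t: 1.0 + 0.25 * np.exp(-(((t - 100.0) / 90.0) ** 2)),
        lambda t: np.exp(-(((t - 70.0) / 45.0) ** 2)),
        lambda t: np.exp(-(((t - 100.0) / 40.0) ** 2))
        - np.exp(-(((t - 55.0) / 40.0) ** 2)),
    ]


def gram_schmidt(grid: Grid, funcs: np.ndarray) -> np.ndarray:
    """Orthonormalize rows of ``funcs`` under quadrature, with one
    re-orthogonalization pass for numerical hygiene."""
    w = grid.trapezoid_weights()
    out = np.array(funcs, dtype=float, copy=True)
    k = out.shape[0]
    for _pass in range(2):
        for i in range(k):
            for j in range(i):
                out[i] -= np.sum(w * out[i] * out[j]) * out[j]
            nrm = np.sqrt(np.sum(w * out[i] ** 2))
            if nrm < 1e-12:
                raise ValueError(f"shape {i} is linearly dependent on earlier shapes")
            out[i] /= nrm
    return out


def orthonormal_basis(
    grid: Grid, shapes: Sequence[ShapeFn] | np.ndarray | None = None, k: int = 3
) -> np.ndarray:
    """Evaluate ``k`` shapes on the grid and orthonormalize them.

    Returns an array of shape (k, n_points) whose rows satisfy
    |<f_a, f_b> - delta_ab| < 1e-8 under trapezoidal quadrature.
    """
    if shapes is None:
        shapes = default_shapes()
    if isinstance(shapes, np.ndarray):
        mat = np.asarray(shapes, dtype=float)[:k]
    else:
        if k > len(shapes):
            raise ValueError(f"requested {k} basis functions, library has {len(shapes)}")
        mat = np.vstack([np.asarray(s(grid.points), dtype=float) for s in shapes[:k]])
    return gram_schmidt(grid, mat)


def check_orthonormal(grid: Grid, funcs: np.ndarray, tol: float = 1e-8) -> None:
    """Raise if rows of ``funcs`` are not orthonormal under quadrature."""
    w = grid.trapezoid_weights()
    gram = (funcs * w) @ funcs.T
    err = np.max(np.abs(gram - np.eye(funcs.shape[0])))
    if err > tol:
        raise ValueError(f"basis not orthonormal under quadrature (max dev {err:.2e})")
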