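"""Time grids and quadrature for postprandial curves.

Curves are observed on a common, equally spaced grid of minutes since the
meal (default 0, 5, ..., 360).  All functional inner products in the package
use trapezoidal quadrature on this grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class Grid:
    """Equally spaced time grid, in minutes since the meal.

    Attributes
    ----------
    points : np.ndarray
        Strictly increasing grid points (inclusive of both endpoints).
    """

    points: np.ndarray = field()

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("grid needs at least two points")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("grid points must be strictly increasing")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.size

    @property
    def step(self) -> float:
        return float(self.points[1] - self.points[0])

    @property
    def span(self) -> float:
        return float(self.points[-1] - self.points[0])

    def trapezoid_weights(self) -> np.ndarray:
        """Trapezoidal quadrature weights w(t); they sum to the grid span."""
        pts = self.points
        w = np.empty_like(pts)
        w[0] = (pts[1] - pts[0]) / 2.0
        w[-1] = (pts[-1] - pts[-2]) / 2.0
        w[1:-1] = (pts[2:] - pts[:-2]) / 2.0
        return w

    def inner(self, f: np.ndarray, g: np.ndarray) -> float:
        """Quadrature inner product <f, g> = integral of f*g over the grid."""
        w = self.trapezoid_weights()
        return float(np.sum(w * np.asarray(f) * np.asarray(g)))

    def norm(self, f: np.ndarray) -> float:
        return float(np.sqrt(max(self.inner(f, f), 0.0)))

    def __eq__(self, other) -> bool:  # value equality for dataclass with array
        if not isinstance(other, Grid):
            return NotImplemented
        return self.points.shape == other.points.shape and bool(
            np.allclose(self.points, other.points)
        )

    def __hash__(self) -> int:
        return hash((self.points.size, float(self.points[0]), float(self.points[-1])))


def make_grid(start: float = 0.0, end: float = 360.0, step: float = 5.0) -> Grid:
    """Build an inclusive-endpoint grid from ``start`` to ``end``.

    The range must be an exact multiple of ``step``; a 6-hour window sampled
    every 5 minutes gives 73 points.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    span = end - start
    if span <= 0:
        raise ValueError("end must exceed start")
    n_steps = span / step
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(
            f"grid range {span} min is not an exact multiple of step {step} min"
        )
    n = int(round(n_steps)) + 1
    return Grid(points=start + step * np.arange(n))


DEFAULT_GRID = make_grid(0.0, 360.0, 5.0)
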