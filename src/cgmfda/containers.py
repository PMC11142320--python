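"""In-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import Grid


@dataclass
class PostprandialDataset:
    """Postprandial glucose curves Y_ij(t) on a common grid.

    Rows of ``curves`` are (subject i, meal j) pairs; ``subject_ids`` and
    ``meal_index`` give the per-row indexing.  Meal ordinals j are
    chronological within subject, starting at 1.
    """

    grid: Grid
    curves: np.ndarray  # (N, m) mg/dL
    subject_ids: np.ndarray  # (N,) labels
    meal_index: np.ndarray  # (N,) int, 1-based within subject
    extraction_log: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.curves = np.asarray(self.curves, dtype=float)
        self.subject_ids = np.asarray(self.subject_ids)
        self.meal_index = np.asarray(self.meal_index, dtype=int)
        n_rows, m = self.curves.shape
        if m != self.grid.n_points:
            raise ValueError("curve length does not match grid")
        if self.subject_ids.shape != (n_rows,) or self.meal_index.shape != (n_rows,):
            raise ValueError("row index arrays must match curve count")

    @property
    def n_rows(self) -> int:
        return self.curves.shape[0]

    @property
    def subjects(self) -> np.ndarray:
        """Unique subject labels in order of first appearance."""
        _, idx = np.unique(self.subject_ids, return_index=True)
        return self.subject_ids[np.sort(idx)]

    @property
    def n_subjects(self) -> int:
        return self.subjects.size

    def meals_per_subject(self) -> dict:
        """J_i: number of curves per subject."""
        vals, counts = np.unique(self.subject_ids, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def subject_codes(self) -> tuple[np.ndarray, np.ndarray]:
        """(codes, labels): integer code per row, in first-appearance order."""
        labels = self.subjects
        lookup = {lab: k for k, lab in enumerate(labels.tolist())}
        codes = np.array([lookup[s] for s in self.subject_ids.tolist()], dtype=int)
        return codes, labels

    def to_frame(self) -> pd.DataFrame:
        """Long format: subject_id, meal_index, t_minutes, glucose_mgdl."""
        m = self.grid.n_points
        return pd.DataFrame(
            {
                "subject_id": np.repeat(self.subject_ids, m),
                "meal_index": np.repeat(self.meal_index, m),
                "t_minutes": np.tile(self.grid.points, self.n_rows),
                "glucose_mgdl": self.curves.ravel(),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, grid: Grid | None = None) -> "PostprandialDataset":
        required = {"subject_id", "meal_index", "t_minutes", "glucose_mgdl"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"missing required columns: {sorted(missing)}")
        frame = frame.sort_values(
            ["subject_id", "meal_index", "t_minutes"], kind="mergesort"
        )
        t = np.unique(frame["t_minutes"].to_numpy(dtype=float))
        if grid is None:
            grid = Grid(points=t)
        elif t.size != grid.n_points or not np.allclose(t, grid.points):
            raise ValueError("frame time points do not match the given grid")
        keys = frame[["subject_id", "meal_index"]].drop_duplicates()
        n_rows = len(keys)
        curves = frame["glucose_mgdl"].to_numpy(dtype=float).reshape(n_rows, grid.n_points)
        return cls(
            grid=grid,
            curves=curves,
            subject_ids=keys["subject_id"].to_numpy(),
            meal_index=keys["meal_index"].to_numpy(dtype=int),
        )


#: covariate columns of the default design, in model order
DEFAULT_DESIGN_COLUMNS = [
    "intercept",
    "age",
    "weight",
    "gender",
    "hba1c",
    "carbohydrates",
    "fats",
    "proteins",
    "fiber",
    "initial_glucose",
]

META_COLUMNS = ["subject_id", "meal_index", "group"]


@dataclass
class CovariateTable:
    """Scalar covariates X_ij,l, one row per curve of a PostprandialDataset.

    ``frame`` holds meta columns (subject_id, meal_index, group) plus the
    design columns; subject-level design columns are constant within subject.
    """

    frame: pd.DataFrame
    design_columns: list[str] = field(default_factory=lambda: list(DEFAULT_DESIGN_COLUMNS))

    def __post_init__(self) -> None:
        missing = [c for c in self.design_columns if c not in self.frame.columns]
        if missing:
            raise ValueError(f"covariate table lacks design columns: {missing}")

    @property
    def n_rows(self) -> int:
        return len(self.frame)

    def design_matrix(self, columns: list[str] | None = None) -> np.ndarray:
        cols = columns if columns is not None else self.design_columns
        return self.frame[cols].to_numpy(dtype=float)

    def complete_mask(self) -> np.ndarray:
        """Rows with no missing design values (FoSR-ready)."""
        return ~self.frame[self.design_columns].isna().any(axis=1).to_numpy()

    def subset(self, mask: np.ndarray) -> "CovariateTable":
        return CovariateTable(
            frame=self.frame.loc[mask].reset_index(drop=True),
            design_columns=list(self.design_columns),
        )


def check_design_rank(X: np.ndarray, columns: list[str]) -> None:
    """Reject rank-deficient designs, naming a culprit column when obvious."""
    if X.shape[0] < X.shape[1]:
        raise ValueError("fewer rows than design columns")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # find a constant non-intercept column to blame, if any
        for j, name in enumerate(columns):
            if name != "intercept" and np.ptp(X[:, j]) == 0:
                raise ValueError(
                    f"design is rank deficient: column '{name}' is constant "
                    "alongside an intercept"
                )
        raise ValueError("design matrix is rank deficient within this stratum")
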