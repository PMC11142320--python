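"""Synthetic postprandial CGM data with a known two-level structure.

The generator draws curves

    Y_ij(t) = mu(t) + nu_j(t) + sum_k a_ik phi_k(t) + sum_h b_ijh psi_h(t) + noise

with orthonormal eigenfunctions at the subject (phi_k) and meal (psi_h)
levels and Gaussian scores whose variances are the eigenvalues, plus the
regression variant

    Y_ij(t) = sum_l X_ij,l beta_l(t) + alpha_i(t) + eps_ij(t)

with subject random-effect functions alpha_i drawn from a smooth
squared-exponential Gaussian process.  Defaults calibrate the subject:meal
process-variance split to 33:67 and mimic published population marginals
for the covariates, so every downstream stage can be validated by
parameter recovery without any external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .basis import check_orthonormal, default_shapes, orthonormal_basis
from .containers import (
    DEFAULT_DESIGN_COLUMNS,
    CovariateTable,
    PostprandialDataset,
    check_design_rank,
)
from .grid import DEFAULT_GRID, Grid
from .preprocess import NOMINAL_CADENCE_MIN as NOMINAL_CADENCE
from .preprocess import CGMStream

# Eigenfunctions are unit-norm under quadrature (integral of phi^2 = 1), so
# the time-averaged pointwise process variance is (sum of eigenvalues)/360.
# Calibrating that average to (20 mg/dL)^2 over the 6-h window gives a total
# eigenvalue mass of 400 * 360, split 33:67 between subject and meal levels.
_TOTAL_EIGENVALUE_MASS = 400.0 * 360.0
_SUBJECT_SHARE = 0.33
_LEVEL_PROPORTIONS = np.array([0.6, 0.3, 0.1])


def default_mean(t: np.ndarray) -> np.ndarray:
    """Postprandial mean: ~100 mg/dL baseline rising to ~145 near 60 min."""
    x = np.asarray(t, dtype=float) / 60.0
    return 100.0 + 45.0 * x * np.exp(1.0 - x)


def default_subject_eigenvalues(k: int = 3) -> np.ndarray:
    return _SUBJECT_SHARE * _TOTAL_EIGENVALUE_MASS * _LEVEL_PROPORTIONS[:k] / _LEVEL_PROPORTIONS[:k].sum()


def default_meal_eigenvalues(h: int = 3) -> np.ndarray:
    return (1 - _SUBJECT_SHARE) * _TOTAL_EIGENVALUE_MASS * _LEVEL_PROPORTIONS[:h] / _LEVEL_PROPORTIONS[:h].sum()


def default_beta_functions() -> dict[str, Callable[[np.ndarray], np.ndarray]]:
    """Coefficient functions (mg/dL per covariate unit) shaped like the
    effects reported for postprandial dinners: carbohydrates raise the
    response around the peak, fats blunt the early rise, fiber acts after
    ~90 min, initial glucose matters most immediately after the meal."""
    return {
        "intercept": lambda t: 40.0 + 30.0 * (t / 60.0) * np.exp(1.0 - t / 60.0),
        "age": lambda t: 0.10 * np.exp(-(((t - 90.0) / 110.0) ** 2)),
        "weight": lambda t: 0.05 * np.ones_like(t),
        "gender": lambda t: np.zeros_like(t),
        "hba1c": lambda t: 6.0 * np.ones_like(t),
        "carbohydrates": lambda t: 0.20 * np.exp(-(((t - 70.0) / 80.0) ** 2)),
        "fats": lambda t: -0.15 * np.exp(-(((t - 25.0) / 35.0) ** 2))
        + 0.06 / (1.0 + np.exp(-(t - 150.0) / 50.0)),
        "proteins": lambda t: np.zeros_like(t),
        "fiber": lambda t: -0.12 / (1.0 + np.exp(-(t - 120.0) / 25.0)),
        "initial_glucose": lambda t: 0.15 + 0.65 * np.exp(-t / 90.0),
    }


# population marginals (normoglycemic / prediabetes) used for covariates
_COVARIATE_MARGINALS = {
    "normoglycemic": {
        "age": (44.6, 13.7, 18.0, 85.0),
        "weight": (73.7, 14.3, 40.0, 140.0),
        "p_male": 0.379,
        "hba1c": (5.25, 0.25, 3.1, 5.6),
        "carbohydrates": (59.9, 40.5, 0.0, 300.0),
        "fats": (30.1, 23.8, 0.0, 200.0),
        "proteins": (27.5, 17.9, 0.0, 150.0),
        "fiber": (8.8, 6.7, 0.0, 60.0),
        "initial_glucose": (103.0, 15.3, 50.0, 240.0),
    },
    "prediabetes": {
        "age": (58.7, 12.0, 20.0, 85.0),
        "weight": (83.0, 19.6, 45.0, 150.0),
        "p_male": 0.310,
        "hba1c": (5.86, 0.20, 5.7, 6.4),
        "carbohydrates": (53.7, 37.5, 0.0, 250.0),
        "fats": (25.7, 22.3, 0.0, 180.0),
        "proteins": (25.9, 17.0, 0.0, 120.0),
        "fiber": (9.1, 7.0, 0.0, 60.0),
        "initial_glucose": (110.0, 19.4, 50.0, 200.0),
    },
}
_P_PREDIABETES = 58.0 / 377.0


@dataclass
class GenerativeConfig:
    """Everything the simulator needs; defaults define the study conditions."""

    n_subjects: int = 150
    meals_per_subject: int | Sequence[int] = 4
    grid: Grid = field(default_factory=lambda: DEFAULT_GRID)
    mean_fn: Callable[[np.ndarray], np.ndarray] = default_mean
    day_effects: np.ndarray | None = None  # (J, m), weighted-sum-to-zero
    subject_eigenfunctions: np.ndarray | None = None  # (K, m)
    subject_eigenvalues: np.ndarray | None = None
    meal_eigenfunctions: np.ndarray | None = None  # (H, m)
    meal_eigenvalues: np.ndarray | None = None
    noise_sd: float = 2.0  # mg/dL, white measurement noise
    beta_functions: dict | None = None  # name -> callable or array
    covariate_sampler: Callable | None = None  # (rng, labels, counts) -> DataFrame
    random_effect_sd: float = 10.0  # mg/dL, sd of alpha_i(t)
    random_effect_lengthscale: float = 60.0  # minutes
    seed: int = 0

    def resolved(self) -> "GenerativeConfig":
        """Fill derived defaults and validate invariants."""
        cfg = GenerativeConfig(**self.__dict__)
        m = cfg.grid.n_points
        if cfg.subject_eigenvalues is None:
            cfg.subject_eigenvalues = default_subject_eigenvalues()
        cfg.subject_eigenvalues = np.asarray(cfg.subject_eigenvalues, dtype=float)
        if cfg.meal_eigenvalues is None:
            cfg.meal_eigenvalues = default_meal_eigenvalues()
        cfg.meal_eigenvalues = np.asarray(cfg.meal_eigenvalues, dtype=float)
        if cfg.subject_eigenfunctions is None:
            cfg.subject_eigenfunctions = orthonormal_basis(
                cfg.grid, k=len(cfg.subject_eigenvalues)
            )
        if cfg.meal_eigenfunctions is None:
            cfg.meal_eigenfunctions = orthonormal_basis(
                cfg.grid, k=len(cfg.meal_eigenvalues)
            )
        cfg.subject_eigenfunctions = np.atleast_2d(
            np.asarray(cfg.subject_eigenfunctions, dtype=float)
        )
        cfg.meal_eigenfunctions = np.atleast_2d(
            np.asarray(cfg.meal_eigenfunctions, dtype=float)
        )

        for name, funcs, vals in (
            ("subject", cfg.subject_eigenfunctions, cfg.subject_eigenvalues),
            ("meal", cfg.meal_eigenfunctions, cfg.meal_eigenvalues),
        ):
            if funcs.shape[0] != vals.size:
                raise ValueError(f"{name}: eigenfunction/eigenvalue lengths differ")
            if funcs.shape[1] != m:
                raise ValueError(f"{name}: eigenfunctions not on the grid")
            if np.any(vals < 0) or np.any(np.diff(vals) > 1e-12):
                raise ValueError(f"{name}: eigenvalues must be nonnegative, decreasing")
            check_orthonormal(cfg.grid, funcs, tol=1e-8)

        if cfg.day_effects is not None:
            cfg.day_effects = np.atleast_2d(np.asarray(cfg.day_effects, dtype=float))
            if cfg.day_effects.shape[1] != m:
                raise ValueError("day effects not on the grid")
            if np.max(np.abs(cfg.day_effects.sum(axis=0))) > 1e-8:
                raise ValueError("day effects must sum to zero at every grid point")
        if cfg.noise_sd < 0 or cfg.random_effect_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        return cfg

    def meal_counts(self) -> np.ndarray:
        if np.isscalar(self.meals_per_subject):
            return np.full(self.n_subjects, int(self.meals_per_subject))
        counts = np.asarray(self.meals_per_subject, dtype=int)
        if counts.size != self.n_subjects:
            raise ValueError("per-subject meal counts must have length n_subjects")
        return counts


@dataclass
class GenerativeTruth:
    """Ground truth realized by one simulator call, for recovery testing."""

    grid: Grid
    mu: np.ndarray | None = None
    nu: np.ndarray | None = None  # (J, m)
    phi: np.ndarray | None = None  # (K, m)
    lam: np.ndarray | None = None
    scores_subject: np.ndarray | None = None  # (n, K)
    psi: np.ndarray | None = None  # (H, m)
    gam: np.ndarray | None = None
    scores_meal: np.ndarray | None = None  # (N, H)
    beta: dict[str, np.ndarray] | None = None
    alpha: np.ndarray | None = None  # (n, m)


def _rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


_KEY_SUBJECT, _KEY_MEAL, _KEY_NOISE, _KEY_COVARIATE, _KEY_ALPHA, _KEY_STREAM = range(6)


def _subject_labels(n: int) -> np.ndarray:
    width = max(3, len(str(n)))
    return np.array([f"S{i + 1:0{width}d}" for i in range(n)], dtype=object)


def simulate_mfpca_dataset(
    config: GenerativeConfig,
) -> tuple[PostprandialDataset, GenerativeTruth]:
    """Draw curves from the two-level eigen-decomposition model."""
    cfg = config.resolved()
    grid = cfg.grid
    t = grid.points
    counts = cfg.meal_counts()
    n, total = cfg.n_subjects, int(counts.sum())
    K = cfg.subject_eigenvalues.size
    H = cfg.meal_eigenvalues.size

    mu = np.asarray(cfg.mean_fn(t), dtype=float)
    a = _rng(cfg.seed, _KEY_SUBJECT).standard_normal((n, K)) * np.sqrt(
        cfg.subject_eigenvalues
    )
    b = _rng(cfg.seed, _KEY_MEAL).standard_normal((total, H)) * np.sqrt(
        cfg.meal_eigenvalues
    )
    noise = cfg.noise_sd * _rng(cfg.seed, _KEY_NOISE).standard_normal(
        (total, grid.n_points)
    )

    labels = _subject_labels(n)
    subject_ids = np.repeat(labels, counts)
    meal_index = np.concatenate([np.arange(1, c + 1) for c in counts])

    curves = mu + np.repeat(a @ cfg.subject_eigenfunctions, counts, axis=0)
    curves = curves + b @ cfg.meal_eigenfunctions + noise
    if cfg.day_effects is not None:
        j_idx = np.minimum(meal_index - 1, cfg.day_effects.shape[0] - 1)
        curves = curves + cfg.day_effects[j_idx]

    dataset = PostprandialDataset(
        grid=grid, curves=curves, subject_ids=subject_ids, meal_index=meal_index
    )
    truth = GenerativeTruth(
        grid=grid,
        mu=mu,
        nu=cfg.day_effects,
        phi=cfg.subject_eigenfunctions,
        lam=cfg.subject_eigenvalues,
        scores_subject=a,
        psi=cfg.meal_eigenfunctions,
        gam=cfg.meal_eigenvalues,
        scores_meal=b,
    )
    return dataset, truth


def _se_gp_draws(
    rng: np.random.Generator, t: np.ndarray, n: int, sd: float, lengthscale: float
) -> np.ndarray:
    """Zero-mean squared-exponential GP realizations, (n, m)."""
    if sd == 0:
        return np.zeros((n, t.size))
    d = (t[:, None] - t[None, :]) / lengthscale
    cov = sd**2 * np.exp(-0.5 * d**2)
    cov[np.diag_indices_from(cov)] += 1e-10 * sd**2
    chol = np.linalg.cholesky(cov)
    return rng.standard_normal((n, t.size)) @ chol.T


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Normal draws clipped by redrawing (simple rejection, then clip)."""
    x = rng.normal(mean, sd, size)
    bad = (x < lo) | (x > hi)
    for _ in range(10):
        if not bad.any():
            break
        x[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (x < lo) | (x > hi)
    return np.clip(x, lo, hi)


def draw_covariates(
    config: GenerativeConfig, counts: np.ndarray
) -> pd.DataFrame:
    """Subject- and meal-level covariates mimicking published marginals.

    Subject-level values are constant across a subject's meals; the
    glycemic group is drawn first and the marginals are group-specific.
    """
    rng = _rng(config.seed, _KEY_COVARIATE)
    n = config.n_subjects
    labels = _subject_labels(n)
    groups = np.where(
        rng.random(n) < _P_PREDIABETES, "prediabetes", "normoglycemic"
    )

    rows = []
    for i in range(n):
        marg = _COVARIATE_MARGINALS[groups[i]]
        subj = {
            "age": float(_truncnorm(rng, *marg["age"], size=1)[0]),
            "weight": float(_truncnorm(rng, *marg["weight"], size=1)[0]),
            "gender": float(rng.random() < marg["p_male"]),
            "hba1c": float(_truncnorm(rng, *marg["hba1c"], size=1)[0]),
        }
        for j in range(int(counts[i])):
            meal = {
                k: float(_truncnorm(rng, *marg[k], size=1)[0])
                for k in ("carbohydrates", "fats", "proteins", "fiber", "initial_glucose")
            }
            rows.append(
                {
                    "subject_id": labels[i],
                    "meal_index": j + 1,
                    "group": groups[i],
                    "intercept": 1.0,
                    **subj,
                    **meal,
                }
            )
    return pd.DataFrame(rows)


def simulate_fosr_dataset(
    config: GenerativeConfig,
) -> tuple[PostprandialDataset, CovariateTable, GenerativeTruth]:
    """Draw curves from the function-on-scalar regression model."""
    cfg = config.resolved()
    grid = cfg.grid
    t = grid.points
    counts = cfg.meal_counts()
    n, total = cfg.n_subjects, int(counts.sum())

    beta_spec = cfg.beta_functions or default_beta_functions()
    names = list(beta_spec.keys())
    beta = {
        name: (np.asarray(f(t), dtype=float) if callable(f) else np.asarray(f, dtype=float))
        for name, f in beta_spec.items()
    }
    for name, arr in beta.items():
        if arr.shape != t.shape:
            raise ValueError(f"beta function '{name}' is not on the grid")

    if cfg.covariate_sampler is not None:
        cov_frame = cfg.covariate_sampler(
            _rng(cfg.seed, _KEY_COVARIATE), _subject_labels(n), counts
        )
    else:
        cov_frame = draw_covariates(cfg, counts)
    missing = [c for c in names if c not in cov_frame.columns]
    if missing:
        raise ValueError(f"no covariate sampler for beta functions: {missing}")
    covariates = CovariateTable(frame=cov_frame, design_columns=names)
    X = covariates.design_matrix()
    check_design_rank(X, names)

    B = np.vstack([beta[name] for name in names])  # (L, m)
    fixed = X @ B

    alpha = _se_gp_draws(
        _rng(cfg.seed, _KEY_ALPHA), t, n, cfg.random_effect_sd,
        cfg.random_effect_lengthscale,
    )
    eps = cfg.noise_sd * _rng(cfg.seed, _KEY_NOISE).standard_normal((total, t.size))

    labels = _subject_labels(n)
    subject_ids = np.repeat(labels, counts)
    meal_index = np.concatenate([np.arange(1, c + 1) for c in counts])
    curves = fixed + np.repeat(alpha, counts, axis=0) + eps

    dataset = PostprandialDataset(
        grid=grid, curves=curves, subject_ids=subject_ids, meal_index=meal_index
    )
    truth = GenerativeTruth(grid=grid, beta=beta, alpha=alpha)
    return dataset, covariates, truth


def simulate_raw_cgm_stream(
    config: GenerativeConfig,
    days: int = 7,
    gap_spec: Sequence[tuple[int, float, float]] = (),
    dinner_minute: float = 20 * 60.0,
    start: str | pd.Timestamp = "2021-03-01",
    baseline_level: float = 95.0,
) -> tuple[list[CGMStream], pd.DataFrame]:
    """Multi-day 5-minute streams with one dinner per day and scripted gaps.

    Glucose follows a flat basal level with measurement noise outside the
    postprandial windows; from each dinner onward the two-level model curve
    is overlaid for six hours.  ``gap_spec`` entries (day, start_minute,
    duration) blank out samples on the given wear day (0-based) for every
    subject; overlapping gaps are merged with a warning.  Dinners whose
    window runs past the end of the stream are flagged incomplete.
    """
    cfg = config.resolved()
    grid = cfg.grid
    t0 = pd.Timestamp(start)
    per_day = int(24 * 60 / NOMINAL_CADENCE)
    n_samples = days * per_day
    times = pd.date_range(t0, periods=n_samples, freq="5min")

    # merge overlapping gaps per day
    by_day: dict[int, list[list[float]]] = {}
    for day, start_min, dur in sorted(gap_spec):
        if day < 0 or day >= days or start_min < 0 or start_min + dur > 24 * 60:
            raise ValueError(f"gap ({day}, {start_min}, {dur}) outside the simulated span")
        intervals = by_day.setdefault(int(day), [])
        if intervals and start_min <= intervals[-1][1]:
            warnings.warn("overlapping gaps merged")
            intervals[-1][1] = max(intervals[-1][1], start_min + dur)
        else:
            intervals.append([start_min, start_min + dur])

    mask = np.zeros(n_samples, dtype=bool)  # True -> missing
    minutes_of_day = (np.arange(n_samples) % per_day) * NOMINAL_CADENCE
    day_idx = np.arange(n_samples) // per_day
    for day, intervals in by_day.items():
        for lo, hi in intervals:
            mask |= (day_idx == day) & (minutes_of_day >= lo) & (minutes_of_day < hi)

    rng_stream = _rng(cfg.seed, _KEY_STREAM)
    rng_subject = _rng(cfg.seed, _KEY_SUBJECT)
    rng_meal = _rng(cfg.seed, _KEY_MEAL)
    counts = np.full(cfg.n_subjects, days)
    cov_frame = draw_covariates(cfg, counts)

    K = cfg.subject_eigenvalues.size
    H = cfg.meal_eigenvalues.size
    mu = np.asarray(cfg.mean_fn(grid.points), dtype=float)
    labels = _subject_labels(cfg.n_subjects)
    offsets = (grid.points / NOMINAL_CADENCE).astype(int)

    streams: list[CGMStream] = []
    meal_rows = []
    for i in range(cfg.n_subjects):
        glucose = baseline_level + cfg.noise_sd * rng_stream.standard_normal(n_samples)
        a_i = rng_subject.standard_normal(K) * np.sqrt(cfg.subject_eigenvalues)
        for day in range(days):
            b_ij = rng_meal.standard_normal(H) * np.sqrt(cfg.meal_eigenvalues)
            curve = (
                mu
                + a_i @ cfg.subject_eigenfunctions
                + b_ij @ cfg.meal_eigenfunctions
                + cfg.noise_sd * rng_stream.standard_normal(grid.n_points)
            )
            start_idx = day * per_day + int(dinner_minute / NOMINAL_CADENCE)
            idx = start_idx + offsets
            inside = idx < n_samples
            glucose[idx[inside]] = curve[inside]
            meal_time = t0 + pd.Timedelta(days=day, minutes=dinner_minute)
            mrow = cov_frame[
                (cov_frame["subject_id"] == labels[i])
                & (cov_frame["meal_index"] == day + 1)
            ].iloc[0]
            meal_rows.append(
                {
                    "subject_id": labels[i],
                    "meal_time": meal_time,
                    "meal_label": "dinner",
                    "carbohydrates": mrow["carbohydrates"],
                    "fats": mrow["fats"],
                    "proteins": mrow["proteins"],
                    "fiber": mrow["fiber"],
                    "window_complete": bool(inside.all()),
                }
            )
        glucose = glucose.copy()
        glucose[mask] = np.nan
        streams.append(
            CGMStream(subject_id=labels[i], times=times, glucose=glucose, wear_start=t0)
        )
    meal_log = pd.DataFrame(meal_rows)
    cols = ["subject_id", "group", "age", "weight", "gender", "hba1c"]
    meal_log.attrs["subjects"] = (
        cov_frame[cols].drop_duplicates("subject_id").reset_index(drop=True)
    )
    return streams, meal_log


def subject_table(config: GenerativeConfig, counts: np.ndarray | None = None) -> pd.DataFrame:
    """Subject-level covariate table matching ``draw_covariates`` draws.

    ``counts`` must equal the meal counts used when the covariates were
    drawn (the covariate stream interleaves subject and meal draws).
    """
    cfg = config.resolved()
    frame = draw_covariates(cfg, counts if counts is not None else cfg.meal_counts())
    cols = ["subject_id", "group", "age", "weight", "gender", "hba1c"]
    return frame[cols].drop_duplicates("subject_id").reset_index(drop=True)
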