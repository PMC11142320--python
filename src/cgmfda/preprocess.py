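"""Raw CGM stream handling: quality filters and postprandial window extraction.

The quality rules are conservative: the entire first midnight-to-midnight
calendar day of wear is discarded (sensor accuracy is markedly lower on
day one), and any later calendar day containing a run of signal loss
strictly longer than two hours is dropped wholesale.  Retained streams are
then cut into 6-hour post-dinner windows on the common 5-minute grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    DEFAULT_DESIGN_COLUMNS,
    CovariateTable,
    PostprandialDataset,
)
from .grid import Grid

NOMINAL_CADENCE_MIN = 5.0
SNAP_TOLERANCE_MIN = 2.5
MAX_GAP_MIN = 120.0  # a day is dropped when signal loss exceeds this, strictly


@dataclass
class CGMStream:
    """One subject's CGM time series at nominal 5-minute cadence.

    ``wear_start`` is kept separate from the first retained timestamp so
    that the first-day exclusion refers to the original wear period and
    quality filtering stays idempotent.
    """

    subject_id: object
    times: pd.DatetimeIndex
    glucose: np.ndarray
    wear_start: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        self.times = pd.DatetimeIndex(self.times)
        self.glucose = np.asarray(self.glucose, dtype=float)
        if len(self.times) != len(self.glucose):
            raise ValueError("times and glucose must have equal length")
        if len(self.times) and not self.times.is_monotonic_increasing:
            raise ValueError(f"timestamps not increasing for subject {self.subject_id}")
        if len(self.times) and self.times.has_duplicates:
            raise ValueError(f"duplicate timestamps for subject {self.subject_id}")
        if self.wear_start is None and len(self.times):
            self.wear_start = self.times[0]

    def observed(self) -> tuple[pd.DatetimeIndex, np.ndarray]:
        """Timestamps and values of finite (non-missing) samples."""
        ok = np.isfinite(self.glucose)
        return self.times[ok], self.glucose[ok]


@dataclass
class MissingPolicy:
    """Within-window missingness rules.

    A window is kept iff at least ``min_fraction`` of grid points have an
    observation and no missing run exceeds ``max_gap_minutes``; runs within
    tolerance are filled (linear interpolation inside the window, nearest
    value at the edges).
    """

    min_fraction: float = 0.8
    max_gap_minutes: float = 30.0


@dataclass
class ExclusionReport:
    entries: list[dict] = field(default_factory=list)

    def add(self, subject_id, unit, reason: str, detail: str = "") -> None:
        self.entries.append(
            {"subject_id": subject_id, "unit": str(unit), "reason": reason, "detail": detail}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, columns=["subject_id", "unit", "reason", "detail"]
        )


def _missing_runs_minutes(day_obs: pd.DatetimeIndex, lo: pd.Timestamp, hi: pd.Timestamp) -> list[float]:
    """Durations (minutes) of missing runs within [lo, hi] given observed stamps."""
    runs: list[float] = []
    if len(day_obs) == 0:
        runs.append((hi - lo).total_seconds() / 60.0)
        return runs
    lead = (day_obs[0] - lo).total_seconds() / 60.0
    if lead > 0:
        runs.append(lead)
    diffs = np.diff(day_obs.asi8) / 60e9
    runs.extend((diffs[diffs > NOMINAL_CADENCE_MIN] - NOMINAL_CADENCE_MIN).tolist())
    trail = (hi - day_obs[-1]).total_seconds() / 60.0 - NOMINAL_CADENCE_MIN
    if trail > 0:
        runs.append(trail)
    return runs


def apply_quality_filters(stream: CGMStream) -> tuple[CGMStream, ExclusionReport]:
    """Drop the first wear day and any day with >2 h of consecutive signal loss.

    A 120-minute loss is retained: the rule is *strictly* more than two hours.
    """
    report = ExclusionReport()
    if len(stream.times) == 0:
        raise ValueError("empty CGM stream")
    obs_times, obs_vals = stream.observed()
    if len(obs_times) == 0:
        warnings.warn(f"subject {stream.subject_id}: no finite glucose values")
        return (
            CGMStream(stream.subject_id, obs_times, obs_vals, wear_start=stream.wear_start),
            report,
        )
    span_minutes = (obs_times[-1] - obs_times[0]).total_seconds() / 60.0
    if span_minutes < 24 * 60:
        warnings.warn(
            f"subject {stream.subject_id}: stream shorter than 24 h; "
            "everything falls under the first-day exclusion"
        )

    first_day = pd.Timestamp(stream.wear_start).normalize()
    dates = obs_times.normalize()
    keep = np.ones(len(obs_times), dtype=bool)

    on_first = dates == first_day
    if on_first.any():
        keep &= ~np.asarray(on_first)
        report.add(stream.subject_id, first_day.date(), "first_day", "first 24 h of wear")

    span_lo, span_hi = obs_times[0], obs_times[-1]
    for day in pd.DatetimeIndex(np.unique(dates[np.asarray(keep)])):
        in_day = np.asarray((dates == day) & keep)
        day_obs = obs_times[in_day]
        lo = max(day, span_lo)
        hi = min(day + pd.Timedelta(days=1), span_hi + pd.Timedelta(minutes=NOMINAL_CADENCE_MIN))
        runs = _missing_runs_minutes(day_obs, lo, hi)
        worst = max(runs) if runs else 0.0
        if worst > MAX_GAP_MIN:
            keep &= ~in_day
            report.add(
                stream.subject_id,
                day.date(),
                "gap",
                f"missing run of {worst:.0f} min exceeds {MAX_GAP_MIN:.0f} min",
            )

    filtered = CGMStream(
        subject_id=stream.subject_id,
        times=obs_times[keep],
        glucose=obs_vals[keep],
        wear_start=stream.wear_start,
    )
    return filtered, report


def _snap(obs_ns: np.ndarray, obs_vals: np.ndarray, target: pd.Timestamp) -> float:
    """Nearest observation within the snap tolerance; ties go to the later
    sample (the post-meal direction).  Returns NaN when nothing qualifies."""
    t_ns = target.value
    idx = np.searchsorted(obs_ns, t_ns)
    best_val, best_dist = np.nan, np.inf
    for j in (idx, idx - 1):  # later candidate first so ties keep the later one
        if 0 <= j < obs_ns.size:
            dist = abs(obs_ns[j] - t_ns) / 60e9
            if dist <= SNAP_TOLERANCE_MIN + 1e-9 and dist < best_dist - 1e-12:
                best_val, best_dist = obs_vals[j], dist
    return float(best_val)


def baseline_glucose(stream: CGMStream, meal_time: pd.Timestamp) -> float:
    """Glucose 5 minutes before the meal (nearest sample within +-2.5 min)."""
    obs_times, obs_vals = stream.observed()
    if len(obs_times) == 0:
        return float("nan")
    return _snap(obs_times.asi8, obs_vals, pd.Timestamp(meal_time) - pd.Timedelta(minutes=5))


def _window_ok(values: np.ndarray, step: float, policy: MissingPolicy) -> tuple[bool, str]:
    finite = np.isfinite(values)
    frac = finite.mean()
    if frac < policy.min_fraction:
        return False, f"only {frac:.0%} of grid points observed"
    # longest missing run, in minutes of grid spacing
    longest = 0
    run = 0
    for f in finite:
        run = 0 if f else run + 1
        longest = max(longest, run)
    if longest * step > policy.max_gap_minutes:
        return False, f"internal gap of {longest * step:.0f} min exceeds policy"
    return True, ""


def _fill_window(values: np.ndarray, points: np.ndarray) -> np.ndarray:
    finite = np.isfinite(values)
    if finite.all():
        return values
    filled = values.copy()
    filled[~finite] = np.interp(points[~finite], points[finite], values[finite])
    return filled


def extract_windows(
    streams: CGMStream | list[CGMStream],
    meals: pd.DataFrame,
    grid: Grid,
    missing_policy: MissingPolicy | None = None,
    meal_label: str | None = None,
) -> PostprandialDataset:
    """Cut quality-filtered streams into postprandial windows on ``grid``.

    Each retained meal yields one curve sampled at meal_time + grid offsets
    (nearest sample within +-2.5 min).  Windows violating the missing-data
    policy are dropped and logged; overlapping windows (meals closer than
    the grid span) are retained but flagged.  Rows are ordered by subject
    then meal time, and the meal ordinal j is chronological within subject.
    """
    if isinstance(streams, CGMStream):
        streams = [streams]
    policy = missing_policy or MissingPolicy()
    if meal_label is not None and "meal_label" in meals.columns:
        meals = meals[meals["meal_label"] == meal_label]

    by_subject = {s.subject_id: s for s in streams}
    log_rows: list[dict] = []
    curves, subj_out, meal_times_out = [], [], []

    for subject_id, sub_meals in meals.groupby("subject_id", sort=True):
        stream = by_subject.get(subject_id)
        if stream is None:
            for mt in sub_meals["meal_time"]:
                log_rows.append(
                    {"subject_id": subject_id, "meal_time": mt, "status": "dropped",
                     "reason": "no CGM stream for subject"}
                )
            continue
        obs_times, obs_vals = stream.observed()
        obs_ns = obs_times.asi8
        retained_times: list[pd.Timestamp] = []
        for mt in sorted(pd.to_datetime(sub_meals["meal_time"])):
            values = np.array(
                [_snap(obs_ns, obs_vals, mt + pd.Timedelta(minutes=float(off)))
                 for off in grid.points]
            )
            ok, why = _window_ok(values, grid.step, policy)
            if not ok:
                log_rows.append(
                    {"subject_id": subject_id, "meal_time": mt, "status": "dropped",
                     "reason": why}
                )
                continue
            flag = ""
            if retained_times and (mt - retained_times[-1]).total_seconds() / 60.0 < grid.span:
                flag = "overlaps previous window"
            retained_times.append(mt)
            log_rows.append(
                {"subject_id": subject_id, "meal_time": mt, "status": "retained",
                 "reason": flag}
            )
            curves.append(_fill_window(values, grid.points))
            subj_out.append(subject_id)
            meal_times_out.append(mt)

    log = pd.DataFrame(log_rows, columns=["subject_id", "meal_time", "status", "reason"])
    if not curves:
        warnings.warn("no postprandial windows survived extraction")
        dataset = PostprandialDataset(
            grid=grid,
            curves=np.empty((0, grid.n_points)),
            subject_ids=np.empty(0, dtype=object),
            meal_index=np.empty(0, dtype=int),
            extraction_log=log,
        )
        dataset.meal_times = np.empty(0, dtype="datetime64[ns]")
        return dataset

    subj_arr = np.asarray(subj_out, dtype=object)
    ordinals = np.empty(len(subj_out), dtype=int)
    for s in np.unique(subj_arr):
        rows = np.where(subj_arr == s)[0]  # already in chronological order
        ordinals[rows] = np.arange(1, rows.size + 1)

    dataset = PostprandialDataset(
        grid=grid,
        curves=np.vstack(curves),
        subject_ids=subj_arr,
        meal_index=ordinals,
        extraction_log=log,
    )
    dataset.meal_times = np.asarray(meal_times_out, dtype="datetime64[ns]")
    return dataset


def attach_covariates(
    dataset: PostprandialDataset,
    subjects: pd.DataFrame,
    meals: pd.DataFrame,
    baseline: pd.Series | np.ndarray | None = None,
) -> CovariateTable:
    """Build the per-curve covariate table (default 10-column design).

    ``subjects`` needs columns subject_id, age, weight, gender, hba1c, group;
    ``meals`` needs subject_id, meal_time and the four macronutrient columns.
    ``baseline`` is the initial (-5 min) glucose aligned with ``meals`` rows;
    missing baselines propagate as NaN and are excluded later from the
    FoSR-ready subset while remaining usable for MFPCA.
    """
    meal_times = getattr(dataset, "meal_times", None)
    if meal_times is None:
        raise ValueError("dataset lacks meal times; extract windows first")
    meals = meals.reset_index(drop=True)
    if baseline is None:
        baseline = np.full(len(meals), np.nan)
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape[0] != len(meals):
        raise ValueError("baseline must align with the meal log rows")

    subj_lookup = subjects.set_index("subject_id")
    meal_lookup = {
        (row.subject_id, pd.Timestamp(row.meal_time)): (i, row)
        for i, row in enumerate(meals.itertuples())
    }

    gender_map = {"male": 1.0, "m": 1.0, "female": 0.0, "f": 0.0}
    rows = []
    for r in range(dataset.n_rows):
        sid = dataset.subject_ids[r]
        mt = pd.Timestamp(meal_times[r])
        if sid not in subj_lookup.index:
            raise ValueError(f"row {r}: no subject record for {sid!r}")
        key = (sid, mt)
        if key not in meal_lookup:
            raise ValueError(f"row {r}: no meal record for {sid!r} at {mt}")
        srec = subj_lookup.loc[sid]
        midx, mrec = meal_lookup[key]
        g = srec["gender"]
        g = gender_map[g.lower()] if isinstance(g, str) else float(g)
        rows.append(
            {
                "subject_id": sid,
                "meal_index": int(dataset.meal_index[r]),
                "group": srec.get("group", "all"),
                "intercept": 1.0,
                "age": float(srec["age"]),
                "weight": float(srec["weight"]),
                "gender": g,
                "hba1c": float(srec["hba1c"]),
                "carbohydrates": float(mrec.carbohydrates),
                "fats": float(mrec.fats),
                "proteins": float(mrec.proteins),
                "fiber": float(mrec.fiber),
                "initial_glucose": float(baseline[midx]),
            }
        )
    frame = pd.DataFrame(rows)
    return CovariateTable(frame=frame, design_columns=list(DEFAULT_DESIGN_COLUMNS))
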