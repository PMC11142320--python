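"""Readers and writers for every persisted artifact.

All numeric output is serialized at 12 significant digits so that
re-running a pipeline with the same seed produces byte-identical files.
Readers canonicalize row order, so shuffled files round-trip to the same
in-memory objects.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CovariateTable, PostprandialDataset
from .fosr import FoSRModel
from .grid import Grid
from .mfpca import MFPCAModel
from .preprocess import CGMStream

FLOAT_FORMAT = "%.12g"


def _round12(obj):
    """Recursively pass floats through 12-significant-digit text form."""
    if isinstance(obj, dict):
        return {k: _round12(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round12(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round12(obj.tolist())
    if isinstance(obj, (float, np.floating)):
        return float(FLOAT_FORMAT % float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def write_json(obj, path: Path) -> None:
    Path(path).write_text(json.dumps(_round12(obj), indent=1, sort_keys=True) + "\n")


def _write_csv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------- datasets

def write_dataset_csv(dataset: PostprandialDataset, path: Path) -> None:
    _write_csv(dataset.to_frame(), path)


def read_dataset_csv(path: Path, grid: Grid | None = None) -> PostprandialDataset:
    return PostprandialDataset.from_frame(pd.read_csv(path), grid=grid)


def write_covariates_csv(covariates: CovariateTable, path: Path) -> None:
    _write_csv(covariates.frame, path)


def read_covariates_csv(path: Path, design_columns: list[str] | None = None) -> CovariateTable:
    frame = pd.read_csv(path)
    frame = frame.sort_values(["subject_id", "meal_index"], kind="mergesort").reset_index(drop=True)
    if design_columns is None:
        design_columns = [
            c for c in frame.columns
            if c not in ("subject_id", "meal_index", "group")
        ]
    return CovariateTable(frame=frame, design_columns=design_columns)


# ------------------------------------------------------------- CGM streams

CGM_COLUMNS = ["subject_id", "timestamp", "glucose_mgdl"]


def write_cgm_csv(streams: list[CGMStream], path: Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "subject_id": s.subject_id,
                "timestamp": s.times.strftime("%Y-%m-%dT%H:%M:%S"),
                "glucose_mgdl": s.glucose,
            }
        )
        for s in streams
    ]
    _write_csv(pd.concat(frames, ignore_index=True), path)


def read_cgm_csv(path: Path) -> list[CGMStream]:
    frame = pd.read_csv(path)
    missing = [c for c in CGM_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"CGM file lacks required columns: {missing}")
    extra = [c for c in frame.columns if c not in CGM_COLUMNS]
    if extra:
        warnings.warn(f"CGM file has unknown columns (ignored): {extra}")
    frame["timestamp"] = pd.to_datetime(frame["timestamp"])
    streams = []
    for sid, sub in frame.groupby("subject_id", sort=True):
        sub = sub.sort_values("timestamp", kind="mergesort")
        streams.append(
            CGMStream(
                subject_id=sid,
                times=pd.DatetimeIndex(sub["timestamp"]),
                glucose=sub["glucose_mgdl"].to_numpy(dtype=float),
            )
        )
    return streams


def write_meals_csv(meals: pd.DataFrame, path: Path) -> None:
    out = meals.copy()
    out["meal_time"] = pd.to_datetime(out["meal_time"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
    _write_csv(out, path)


def read_meals_csv(path: Path) -> pd.DataFrame:
    meals = pd.read_csv(path)
    if "meal_time" not in meals.columns or "subject_id" not in meals.columns:
        raise ValueError("meal log needs subject_id and meal_time columns")
    meals["meal_time"] = pd.to_datetime(meals["meal_time"])
    return meals.sort_values(["subject_id", "meal_time"], kind="mergesort").reset_index(drop=True)


def write_subjects_csv(subjects: pd.DataFrame, path: Path) -> None:
    _write_csv(subjects, path)


def read_subjects_csv(path: Path) -> pd.DataFrame:
    subjects = pd.read_csv(path)
    if "subject_id" not in subjects.columns:
        raise ValueError("subject table needs a subject_id column")
    return subjects


# ------------------------------------------------------------------ models

def write_mfpca_model(model: MFPCAModel, path: Path) -> None:
    write_json(
        {
            "kind": "mfpca",
            "grid": model.grid.points,
            "mu": model.mu,
            "nu": model.nu if model.nu is not None else None,
            "phi": model.phi,
            "lambda": model.lam,
            "psi": model.psi,
            "gamma": model.gam,
            "scores_subject": model.scores_subject,
            "scores_meal": model.scores_meal,
            "noise_var": model.noise_var,
            "subject_codes": model.subject_codes,
            "subject_labels": [str(s) for s in model.subject_labels],
            "meal_index": model.meal_index,
        },
        path,
    )


def read_mfpca_model(path: Path) -> MFPCAModel:
    d = json.loads(Path(path).read_text())
    if d.get("kind") != "mfpca":
        raise ValueError("not an MFPCA model file")
    return MFPCAModel(
        grid=Grid(points=np.asarray(d["grid"], dtype=float)),
        mu=np.asarray(d["mu"], dtype=float),
        nu=None if d["nu"] is None else np.asarray(d["nu"], dtype=float),
        phi=np.asarray(d["phi"], dtype=float),
        lam=np.asarray(d["lambda"], dtype=float),
        psi=np.asarray(d["psi"], dtype=float),
        gam=np.asarray(d["gamma"], dtype=float),
        scores_subject=np.asarray(d["scores_subject"], dtype=float),
        scores_meal=np.asarray(d["scores_meal"], dtype=float),
        noise_var=float(d["noise_var"]),
        subject_codes=np.asarray(d["subject_codes"], dtype=int),
        subject_labels=np.asarray(d["subject_labels"], dtype=object),
        meal_index=np.asarray(d["meal_index"], dtype=int),
    )


def write_fosr_model(model: FoSRModel, path: Path) -> None:
    bands = {
        name: {k: v for k, v in info.items()}
        for name, info in model.bands.items()
    }
    write_json(
        {
            "kind": "fosr",
            "grid": model.grid.points,
            "coef_names": model.coef_names,
            "beta": model.beta,
            "beta_se": model.beta_se,
            "beta_raw": model.beta_raw,
            "beta_se_raw": model.beta_se_raw,
            "alpha": model.alpha,
            "subject_labels": [str(s) for s in model.subject_labels],
            "sigma2_eps": model.sigma2_eps,
            "sigma2_alpha": model.sigma2_alpha,
            "stratum": model.stratum,
            "bands": bands,
        },
        path,
    )


def read_fosr_model(path: Path) -> FoSRModel:
    d = json.loads(Path(path).read_text())
    if d.get("kind") != "fosr":
        raise ValueError("not a FoSR model file")
    bands = {
        name: {
            k: (np.asarray(v, dtype=float) if isinstance(v, list) else v)
            for k, v in info.items()
        }
        for name, info in d["bands"].items()
    }
    return FoSRModel(
        grid=Grid(points=np.asarray(d["grid"], dtype=float)),
        coef_names=list(d["coef_names"]),
        beta=np.asarray(d["beta"], dtype=float),
        beta_se=np.asarray(d["beta_se"], dtype=float),
        beta_raw=np.asarray(d["beta_raw"], dtype=float),
        beta_se_raw=np.asarray(d["beta_se_raw"], dtype=float),
        alpha=np.asarray(d["alpha"], dtype=float),
        subject_labels=np.asarray(d["subject_labels"], dtype=object),
        sigma2_eps=np.asarray(d["sigma2_eps"], dtype=float),
        sigma2_alpha=np.asarray(d["sigma2_alpha"], dtype=float),
        stratum=d["stratum"],
        bands=bands,
    )


def write_truth_json(truth, path: Path) -> None:
    payload = {"grid": truth.grid.points}
    for name in (
        "mu", "nu", "phi", "lam", "scores_subject", "psi", "gam",
        "scores_meal", "alpha",
    ):
        val = getattr(truth, name)
        payload[name] = val if val is not None else None
    if truth.beta is not None:
        payload["beta"] = {k: v for k, v in truth.beta.items()}
    write_json(payload, path)
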