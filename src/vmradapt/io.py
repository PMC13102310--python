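"""Trial-table CSV input/output, JSON sidecars, and data-cleaning filters.

Angles are stored in degrees, signed, target-relative, with the direction
countering the perturbation positive.  The long-form trial table carries
one row per participant per trial.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ModelParams
from .schedules import TRIAL_TYPES, schedule_from_frame
from .simulate import NoiseSpec, SimulatedDataset

__all__ = ["SchemaError", "REQUIRED_COLUMNS", "write_trials", "read_trials",
           "clean_trials"]

REQUIRED_COLUMNS = (
    "participant_id",
    "condition",
    "trial",
    "cycle",
    "trial_type",
    "rotation_deg",
    "hand_deg",
    "aim_report_deg",
    "percept_report_deg",
    "regime",
)

_ANGLE_COLUMNS = ("rotation_deg", "hand_deg", "aim_report_deg", "percept_report_deg")


class SchemaError(ValueError):
    """The trial table does not conform to the expected schema."""


def _sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def write_trials(dataset: SimulatedDataset, path, sidecar: bool = True) -> Path:
    """Write a dataset to CSV (plus a JSON sidecar with generator provenance)."""
    path = Path(path)
    df = dataset.trials.copy()
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"dataset is missing required column {col!r}")
    df.to_csv(path, index=False)
    if sidecar:
        meta = {
            "design": dataset.design,
            "condition": dataset.condition,
            "seed": dataset.seed,
            "params": _params_to_dict(dataset.params),
            "noise": dataclasses.asdict(dataset.noise) if dataset.noise else None,
        }
        _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def _params_to_dict(params: ModelParams | None):
    if params is None:
        return None
    d = dataclasses.asdict(params)
    d["model_kind"] = params.model_kind.value
    d["uncertainty_form"] = params.uncertainty_form.value
    return d


def params_from_dict(d: dict | None) -> ModelParams | None:
    if d is None:
        return None
    return ModelParams(**{k: v for k, v in d.items() if v is not None or k in
                          ("Af", "Bf", "As", "Bs")})


def read_trials(path) -> SimulatedDataset:
    """Read a long-form trial CSV; lossless round-trip with `write_trials`.

    Unknown columns are preserved.  A missing required column raises
    :class:`SchemaError` naming the column; non-numeric angles raise with
    the offending row index.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    df["participant_id"] = df["participant_id"].astype(str)
    df["condition"] = df["condition"].astype(str)
    for col in _ANGLE_COLUMNS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"non-numeric value in column {col!r} at row index {int(bad[0])}"
            )
        df[col] = coerced
    unknown = set(df["trial_type"].unique()) - set(TRIAL_TYPES)
    if unknown:
        raise SchemaError(f"unknown trial_type values {sorted(unknown)}")
    dup = df.duplicated(subset=["participant_id", "trial"])
    if dup.any():
        raise SchemaError("trial indices must be unique per participant")

    design, condition, seed, params, noise = "custom", "custom", None, None, None
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        design = meta.get("design", design)
        condition = str(meta.get("condition", condition))
        seed = meta.get("seed")
        params = params_from_dict(meta.get("params"))
        if meta.get("noise"):
            noise = NoiseSpec(**meta["noise"])
    pid0 = df["participant_id"].iloc[0]
    schedule = schedule_from_frame(df[df["participant_id"] == pid0], design, condition)
    return SimulatedDataset(design, condition, schedule, df, params, noise, seed)


def clean_trials(
    dataset: SimulatedDataset,
    min_dir: float = -20.0,
    max_dir: float = 120.0,
) -> tuple[SimulatedDataset, pd.DataFrame]:
    """Drop movement rows outside the plausible direction window.

    Removes rows whose executed hand direction falls outside
    ``[min_dir, max_dir]`` (systematic wrong-direction movements) and
    returns the cleaned dataset together with a per-participant exclusion
    log.  Infinite thresholds disable the filter.
    """
    df = dataset.trials
    hand = df["hand_deg"]
    bad = hand.notna() & ((hand < min_dir) | (hand > max_dir))
    log = (
        df[bad].groupby("participant_id").size().rename("n_excluded").reset_index()
    )
    cleaned = SimulatedDataset(
        design=dataset.design,
        condition=dataset.condition,
        schedule=dataset.schedule,
        trials=df[~bad].reset_index(drop=True),
        params=dataset.params,
        noise=dataset.noise,
        seed=dataset.seed,
    )
    return cleaned, log
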