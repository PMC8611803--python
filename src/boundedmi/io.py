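"""Dataset / configuration / results serialization.

Datasets travel as plain CSV with columns
``id,time,event,aux,time_missing,interval_left,interval_right`` plus, in the
"oracle" view only, ``time_true`` (the generated value retained for
truth-tracking in simulation studies). In the "analysis" view the ``time``
cell of a flagged record is empty — not sentinel-coded — and ``time_true`` is
dropped, so the file contains exactly what an analyst would be given.

Times are serialized as decimal days: imputed values may be non-integer.
All internal computation is in proportions; reporting layers multiply by 100.
"""

from __future__ import annotations

import json
import time as _time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import DATASET_COLUMNS, MissingnessSpec, SimulationConfig
from .study import StudyDesign

__all__ = [
    "write_dataset",
    "read_dataset",
    "load_simulation_config",
    "load_missingness_spec",
    "load_study_design",
    "write_manifest",
]

_ANALYSIS_COLUMNS = DATASET_COLUMNS[:-1]  # without time_true


def write_dataset(dataset: pd.DataFrame, path, view: str = "analysis") -> None:
    """Write a dataset CSV in the ``analysis`` or ``oracle`` view.

    The analysis view blanks the time of flagged records and omits
    ``time_true``; the oracle view keeps both and is intended for harness use
    only.
    """
    if view not in ("analysis", "oracle"):
        raise ValueError("view must be 'analysis' or 'oracle'")
    df = dataset.copy()
    df["time_missing"] = df["time_missing"].astype(bool).astype(int)
    if view == "analysis":
        df.loc[df["time_missing"] == 1, "time"] = np.nan
        df = df[_ANALYSIS_COLUMNS]
    else:
        df = df[DATASET_COLUMNS]
    df.to_csv(path, index=False)


def read_dataset(path) -> pd.DataFrame:
    """Read a dataset CSV (either view) back into the in-memory layout.

    Validates the schema and the per-record invariants; violations are
    reported with 1-based data line numbers.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in _ANALYSIS_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    df["time_missing"] = df["time_missing"].astype(bool)
    if "time_true" not in df.columns:
        df["time_true"] = df["time"]
    for col in ("time", "time_true", "interval_left", "interval_right"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df["time_missing"] & ~(df["interval_left"] < df["interval_right"])
    if bad.any():
        lines = (np.flatnonzero(bad) + 2).tolist()
        raise ValueError(f"{path}: flagged records without valid bounds at lines {lines}")
    bad = ~df["time_missing"] & ~(df["time"] > 0)
    if bad.any():
        lines = (np.flatnonzero(bad) + 2).tolist()
        raise ValueError(f"{path}: non-positive or empty times at lines {lines}")
    return df[DATASET_COLUMNS]


def _load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return data


def load_simulation_config(path) -> SimulationConfig:
    """Build a SimulationConfig from a YAML/JSON mapping, validating fields."""
    data = _load_yaml(path)
    fields = {k: v for k, v in data.items() if k in SimulationConfig.__dataclass_fields__}
    for key in ("event_probs", "lognormal_mu", "lognormal_sigma", "bounds"):
        if key in fields and isinstance(fields[key], list):
            fields[key] = tuple(fields[key])
    return SimulationConfig(**fields)


def load_missingness_spec(path_or_mapping) -> MissingnessSpec:
    data = (
        path_or_mapping
        if isinstance(path_or_mapping, dict)
        else _load_yaml(path_or_mapping)
    )
    fields = {k: v for k, v in data.items() if k in MissingnessSpec.__dataclass_fields__}
    return MissingnessSpec(**fields)


def load_study_design(path) -> StudyDesign:
    data = _load_yaml(path)
    fields = {k: v for k, v in data.items() if k in StudyDesign.__dataclass_fields__}
    for key in ("methods", "mechanisms", "fractions"):
        if key in fields and isinstance(fields[key], list):
            fields[key] = tuple(fields[key])
    return StudyDesign(**fields)


def write_manifest(path, *, config=None, design=None, seeds=None, cells=None) -> None:
    """Record everything needed to reproduce a results file exactly."""
    from . import __version__

    def _as_dict(obj):
        if obj is None:
            return None
        return {k: getattr(obj, k) for k in obj.__dataclass_fields__}

    manifest = {
        "package": "boundedmi",
        "version": __version__,
        "timestamp": _time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "config": _as_dict(config),
        "design": _as_dict(design),
        "seeds": seeds,
        "cells": cells,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
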