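"""Tabular I/O contracts: gaze-sample CSV, phenotype CSV, fit JSON.

All numeric output is serialized with six significant digits so reports
and tables diff cleanly across runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

GAZE_COLUMNS = ["infant_id", "pair_id", "zygosity", "trial_index",
                "stimulus_id", "t_ms", "x_px", "y_px", "valid"]
PHENO_REQUIRED = ["infant_id", "face_orienting", "face_preference",
                  "exploration", "n_valid_trials", "mean_prop_missing"]


def _require(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required columns: {missing}")


def _format_float(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def write_table_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def write_gaze_csv(gaze: pd.DataFrame, path) -> None:
    _require(gaze, GAZE_COLUMNS, "gaze table")
    write_table_csv(gaze[GAZE_COLUMNS], path)


def read_gaze_csv(path) -> pd.DataFrame:
    gaze = pd.read_csv(path)
    _require(gaze, GAZE_COLUMNS, str(path))
    for (_, _), g in gaze.groupby(["infant_id", "trial_index"], sort=False):
        t = g["t_ms"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(
                f"non-monotone t_ms for infant {g['infant_id'].iloc[0]!r} "
                f"trial {g['trial_index'].iloc[0]}")
    return gaze


def write_phenotypes_csv(pheno: pd.DataFrame, path) -> None:
    _require(pheno, PHENO_REQUIRED, "phenotype table")
    write_table_csv(pheno, path)


def read_phenotypes_csv(path) -> pd.DataFrame:
    pheno = pd.read_csv(path)
    _require(pheno, PHENO_REQUIRED, str(path))
    return pheno


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        return float(f"{float(obj):.6g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(payload), indent=2) + "\n")


def write_fit_json(fit, path) -> None:
    payload = fit.summary_row()
    if fit.params is not None:
        payload["estimates"] = {
            "paths": {c: L for c, L in fit.params["paths"].items()},
            "means": fit.params["means"],
            "beta_age": fit.params["beta_age"],
            "beta_sex": fit.params["beta_sex"],
        }
    write_json(payload, path)
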