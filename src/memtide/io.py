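"""CSV/JSON readers and writers with schema validation.

All tables are comma-separated UTF-8 with a mandatory header row and '.'
decimals; nested structures (protocols, truth files, results) are JSON.
Numbers are serialized with 12 significant digits so generator output
round-trips bit-identically through read -> write -> read.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError

__all__ = [
    "SCHEMAS",
    "read_trace",
    "write_trace",
    "read_json",
    "write_json",
]

#: Column schemas: name -> (required columns, optional columns, time column)
SCHEMAS: dict[str, dict] = {
    "force_trace": {
        "required": ["time_s", "dr_um", "force_pN"],
        "optional": ["tension_pN_per_um"],
        "time": "time_s",
    },
    "probe_response": {
        "required": ["time_s", "delta_sigma_pN_per_um"],
        "optional": [],
        "time": "time_s",
    },
    "frap": {
        "required": ["time_s", "intensity_au"],
        "optional": [],
        "time": "time_s",
    },
    "stimulus": {
        "required": ["time_s", "tension_pN_per_um", "dF_over_F"],
        "optional": [],
        "time": "time_s",
    },
    "drag_frames": {
        "required": ["time_s", "base_x_um", "base_y_um", "bead_x_um",
                     "bead_y_um", "force_pN"],
        "optional": [],
        "time": "time_s",
    },
    "drag_contours": {
        "required": ["frame", "idx", "x_um", "y_um"],
        "optional": [],
        "time": None,
    },
    "trap_records": {
        "required": ["A_bead_um", "f_hydro_pN"],
        "optional": [],
        "time": None,
    },
}


def read_trace(path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV table against a named schema.

    Checks: required columns present, numeric, time strictly increasing
    (when the schema has a time column), and no NaNs in required columns.
    Raises SchemaError naming the offending field.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema '{schema}'")
    spec = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"file not found: {path}")
    df = pd.read_csv(path)
    for col in spec["required"]:
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing required column '{col}'")
    keep = spec["required"] + [c for c in spec["optional"] if c in df.columns]
    df = df[keep]
    for col in keep:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise SchemaError(
                f"{path.name}: column '{col}' is not numeric") from exc
        if df[col].isna().any():
            raise SchemaError(f"{path.name}: column '{col}' contains NaN")
    tcol = spec["time"]
    if tcol is not None and len(df) > 1:
        if np.any(np.diff(df[tcol].to_numpy()) <= 0):
            raise SchemaError(
                f"{path.name}: column '{tcol}' is not strictly increasing")
    return df


def write_trace(df: pd.DataFrame, path, schema: str | None = None) -> Path:
    """Write a table as CSV with 12-significant-digit floats."""
    path = Path(path)
    if schema is not None:
        spec = SCHEMAS[schema]
        for col in spec["required"]:
            if col not in df.columns:
                raise SchemaError(f"refusing to write: missing '{col}'")
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.12g")
    return path


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


def read_json(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def write_json(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path
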