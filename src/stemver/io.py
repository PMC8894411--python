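"""CSV input/output for angle tables and femoral landmarks.

Angle tables: one row per hip, columns ``hip_id``, ``ci_deg``, ``si_deg``
and optionally ``tv_deg`` (degrees).  Landmark tables: one row per femur,
columns ``hip_id`` plus ``<landmark>_{x,y,z}`` in mm for the femoral head
center, knee center and the medial/lateral posterior condyle points.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trig_core import FemoralLandmarks

__all__ = [
    "ANGLE_COLUMNS",
    "LANDMARK_COLUMNS",
    "read_angle_table",
    "write_angle_table",
    "read_landmarks",
    "read_rater_table",
]

ANGLE_COLUMNS = ("hip_id", "ci_deg", "si_deg")
_LANDMARK_STEMS = ("head", "knee", "med_cond", "lat_cond")
LANDMARK_COLUMNS = ("hip_id",) + tuple(
    f"{stem}_{axis}" for stem in _LANDMARK_STEMS for axis in "xyz"
)


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")


def _numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ValueError(f"{path}: non-numeric value in column {col!r} at line {row}")
        df[col] = coerced
    return df


def read_angle_table(path) -> pd.DataFrame:
    """Read a per-hip angle CSV (``tv_deg`` optional)."""
    df = pd.read_csv(path)
    _require_columns(df, ANGLE_COLUMNS, path)
    cols = [c for c in ("ci_deg", "si_deg", "tv_deg") if c in df.columns]
    return _numeric(df, cols, path)


def write_angle_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_landmarks(path) -> dict[object, FemoralLandmarks]:
    """Read a landmark CSV into per-hip :class:`FemoralLandmarks`."""
    df = pd.read_csv(path)
    _require_columns(df, LANDMARK_COLUMNS, path)
    df = _numeric(df, [c for c in LANDMARK_COLUMNS if c != "hip_id"], path)
    out: dict[object, FemoralLandmarks] = {}
    for _, row in df.iterrows():
        point = {stem: np.array([row[f"{stem}_{ax}"] for ax in "xyz"]) for stem in _LANDMARK_STEMS}
        out[row["hip_id"]] = FemoralLandmarks(
            head_center=point["head"],
            knee_center=point["knee"],
            medial_posterior_condyle=point["med_cond"],
            lateral_posterior_condyle=point["lat_cond"],
        )
    return out


def read_rater_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a wide CSV (one column per rater/measurement, optional
    ``hip_id`` label column) into ``(labels, n x k matrix)``."""
    df = pd.read_csv(path)
    if "hip_id" in df.columns:
        labels = df["hip_id"].to_numpy()
        df = df.drop(columns=["hip_id"])
    else:
        labels = np.arange(1, len(df) + 1)
    df = _numeric(df, list(df.columns), path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least two rater/measurement columns")
    return labels, df.to_numpy(dtype=float)
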