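"""File adapters: CSV/JSON readers and writers for every stage.

All files are UTF-8 CSV with header rows (JSON for nested structures).
Dialects:

* photometry: ``time_s,f465,f405``
* tracking: ``time_s,x_mm,y_mm`` (+ a JSON file of named zone polygons)
* pose: the standard multi-row-header pose-estimation dialect
  (scorer / bodyparts / coords header rows, one x/y/likelihood triple per
  body part)
* sweeps: ``time_s,value,command``
* events: ``kind,onset_s,offset_s,peak_speed``
* startle results: ``trial,type,amplitude,valid``
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .behavior import BehaviorEvent, Trajectory
from .ephys import EphysSweep
from .photometry import PhotometrySession
from .startle import StartleTrialResult

__all__ = [
    "read_photometry_csv",
    "write_photometry_csv",
    "read_tracking_csv",
    "write_tracking_csv",
    "read_zones_json",
    "write_zones_json",
    "read_pose_csv",
    "write_pose_csv",
    "read_sweep_csv",
    "write_sweep_csv",
    "write_events_csv",
    "read_events_csv",
    "write_startle_results_csv",
]


class SchemaError(ValueError):
    """A file does not match the expected column schema."""


def _require_columns(df: pd.DataFrame, cols: tuple, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


def _infer_fs(time_s: np.ndarray, path) -> float:
    if len(time_s) < 2:
        raise SchemaError(f"{path}: need at least 2 samples to infer sampling rate")
    dt = np.diff(time_s)
    if np.any(dt <= 0):
        bad = int(np.argmax(dt <= 0)) + 2  # 1-based line after header
        raise SchemaError(f"{path}: non-increasing time at data line {bad}")
    return 1.0 / float(np.median(dt))


# -- photometry --------------------------------------------------------------


def read_photometry_csv(path, labels: dict | None = None) -> PhotometrySession:
    df = pd.read_csv(path)
    _require_columns(df, ("time_s", "f465", "f405"), path)
    t = df["time_s"].to_numpy(dtype=float)
    return PhotometrySession(
        t=t,
        f465=df["f465"].to_numpy(dtype=float),
        f405=df["f405"].to_numpy(dtype=float),
        fs=_infer_fs(t, path),
        labels=labels or {},
    )


def write_photometry_csv(session: PhotometrySession, path) -> None:
    pd.DataFrame({"time_s": session.t, "f465": session.f465, "f405": session.f405}).to_csv(
        path, index=False
    )


# -- tracking + zones --------------------------------------------------------


def read_tracking_csv(path, zones: dict, arena_name: str = "") -> Trajectory:
    df = pd.read_csv(path)
    _require_columns(df, ("time_s", "x_mm", "y_mm"), path)
    t = df["time_s"].to_numpy(dtype=float)
    return Trajectory(
        t=t,
        x=df["x_mm"].to_numpy(dtype=float),
        y=df["y_mm"].to_numpy(dtype=float),
        fps=_infer_fs(t, path),
        zones=zones,
        arena_name=arena_name,
    )


def write_tracking_csv(traj: Trajectory, path) -> None:
    pd.DataFrame({"time_s": traj.t, "x_mm": traj.x, "y_mm": traj.y}).to_csv(path, index=False)


def write_zones_json(zones: dict, path) -> None:
    payload = {
        name: [list(xy) for xy in np.asarray(poly.exterior.coords)]
        for name, poly in zones.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_zones_json(path) -> dict:
    payload = json.loads(Path(path).read_text())
    return {name: Polygon(coords) for name, coords in payload.items()}


# -- pose (multi-row-header dialect) ----------------------------------------


def write_pose_csv(keypoints: pd.DataFrame, path, scorer: str = "synthetic") -> None:
    """Write a (bodypart, coord) MultiIndex frame in the three-row-header
    pose-estimation dialect."""
    df = keypoints.copy()
    df.columns = pd.MultiIndex.from_tuples(
        [(scorer, bp, coord) for bp, coord in df.columns],
        names=["scorer", "bodyparts", "coords"],
    )
    df.to_csv(path, index_label="frame")


def read_pose_csv(path) -> pd.DataFrame:
    """Read the multi-row-header pose dialect into a (bodypart, coord)
    MultiIndex frame; body-part names are recovered from the header."""
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    if df.columns.nlevels != 3:
        raise SchemaError(f"{path}: expected 3 header rows (scorer/bodyparts/coords)")
    df.columns = pd.MultiIndex.from_tuples(
        [(bp, coord) for (_, bp, coord) in df.columns], names=["bodyparts", "coords"]
    )
    return df.astype(float)


# -- ephys sweeps ------------------------------------------------------------


def read_sweep_csv(path, protocol: str = "", clamp: str = "current", meta: dict | None = None) -> EphysSweep:
    df = pd.read_csv(path)
    _require_columns(df, ("time_s", "value", "command"), path)
    t = df["time_s"].to_numpy(dtype=float)
    return EphysSweep(
        t=t,
        trace=df["value"].to_numpy(dtype=float),
        command=float(df["command"].iloc[0]),
        fs=_infer_fs(t, path),
        protocol=protocol,
        clamp=clamp,
        meta=meta or {},
    )


def write_sweep_csv(sweep: EphysSweep, path) -> None:
    pd.DataFrame(
        {"time_s": sweep.t, "value": sweep.trace, "command": sweep.command}
    ).to_csv(path, index=False)


# -- events and results ------------------------------------------------------


def write_events_csv(events: list[BehaviorEvent], path) -> None:
    pd.DataFrame(
        [
            {
                "kind": e.kind,
                "onset_s": e.onset_s,
                "offset_s": e.offset_s,
                "peak_speed": e.peak_speed,
            }
            for e in events
        ],
        columns=["kind", "onset_s", "offset_s", "peak_speed"],
    ).to_csv(path, index=False)


def read_events_csv(path) -> list[BehaviorEvent]:
    df = pd.read_csv(path)
    _require_columns(df, ("kind", "onset_s", "offset_s", "peak_speed"), path)
    return [
        BehaviorEvent(
            kind=r.kind, onset_s=r.onset_s, offset_s=r.offset_s, peak_speed=r.peak_speed
        )
        for r in df.itertuples()
    ]


def write_startle_results_csv(results: list[StartleTrialResult], path) -> None:
    pd.DataFrame(
        [
            {
                "trial": r.trial_index,
                "type": r.trial_type,
                "amplitude": r.amplitude,
                "valid": r.valid,
            }
            for r in results
        ],
        columns=["trial", "type", "amplitude", "valid"],
    ).to_csv(path, index=False)
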