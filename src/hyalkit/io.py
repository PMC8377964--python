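"""Shared I/O: unit-annotated CSV tables, trace files and gel images.

Tables are plain CSV with one extra header line of units, e.g.::

    sample_id,group,viscosity_cp
    ,,cP
    S000,healthy,81.2

All indices are 0-based with half-open intervals; units are recorded per
column and checked on read when a schema declares them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .nanopore import CurrentTrace
from .rheology import Trajectory

__all__ = [
    "read_table",
    "write_table",
    "read_trace_csv",
    "read_trace_raw",
    "write_trace_raw",
    "read_trajectories_csv",
    "read_gel_image",
]


class SchemaError(ValueError):
    pass


def write_table(df: pd.DataFrame, path, units: Dict[str, str]) -> None:
    """Write a CSV with a units row under the header (empty string = unitless)."""
    path = Path(path)
    cols = list(df.columns)
    unit_row = ",".join(units.get(c, "") for c in cols)
    with open(path, "w", newline="") as fh:
        fh.write(",".join(cols) + "\n")
        fh.write(unit_row + "\n")
        df.to_csv(fh, header=False, index=False)


def read_table(
    path, schema: Optional[Dict[str, str]] = None
) -> Tuple[pd.DataFrame, Dict[str, str]]:
    """Read a unit-annotated CSV; validates required columns and units.

    ``schema`` maps required column names to expected unit strings (use ""
    for unitless).  Tolerates a UTF-8 BOM.
    """
    path = Path(path)
    with open(path, encoding="utf-8-sig") as fh:
        header = fh.readline().strip().split(",")
        unit_line = fh.readline().strip().split(",")
        df = pd.read_csv(fh, header=None, names=header)
    units = {c: (u if i < len(unit_line) else "") for i, (c, u) in enumerate(zip(header, unit_line + [""] * len(header)))}
    if schema:
        for col, unit in schema.items():
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
            if unit and units.get(col, "") != unit:
                raise SchemaError(
                    f"unit mismatch for {col!r}: expected {unit!r}, found {units.get(col, '')!r}"
                )
    return df, units


# -- nanopore traces --------------------------------------------------------


def read_trace_csv(path) -> CurrentTrace:
    """CSV with columns time_s, current_pa; sample rate from the time step."""
    df = pd.read_csv(path)
    for col in ("time_s", "current_pa"):
        if col not in df.columns:
            raise SchemaError(f"trace CSV missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise SchemaError("trace needs >= 2 samples")
    rate = 1.0 / (t[1] - t[0])
    return CurrentTrace(df["current_pa"].to_numpy(dtype=float), rate)


def write_trace_raw(trace: CurrentTrace, path) -> None:
    """Little-endian float32 samples plus a JSON metadata sidecar."""
    path = Path(path)
    trace.current_pa.astype("<f4").tofile(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"sample_rate_hz": trace.sample_rate, "units": "pA"})
    )


def read_trace_raw(path) -> CurrentTrace:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    data = np.fromfile(path, dtype="<f4").astype(float)
    return CurrentTrace(data, float(meta["sample_rate_hz"]), {"units": meta.get("units", "pA")})


# -- trajectories -----------------------------------------------------------


def read_trajectories_csv(path, fps: float = 16.0):
    """Trajectory CSV: track_id, frame, x_um, y_um (optional time_s)."""
    df = pd.read_csv(path)
    required = {"track_id", "frame", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"trajectory CSV missing columns {sorted(missing)}")
    tracks = []
    for tid, sub in df.groupby("track_id"):
        sub = sub.sort_values("frame")
        if "time_s" in sub.columns:
            times = sub["time_s"].to_numpy(dtype=float)
        else:
            times = sub["frame"].to_numpy(dtype=float) / fps
        tracks.append(
            Trajectory(int(tid), times, sub["x_um"].to_numpy(float), sub["y_um"].to_numpy(float))
        )
    return tracks


def write_trajectories_csv(tracks, path, fps: float = 16.0) -> None:
    rows = []
    for tr in tracks:
        frames = np.round(tr.frame_times_s * fps).astype(int)
        for f, t, x, y in zip(frames, tr.frame_times_s, tr.x_um, tr.y_um):
            rows.append((tr.track_id, f, t, x, y))
    pd.DataFrame(rows, columns=["track_id", "frame", "time_s", "x_um", "y_um"]).to_csv(
        path, index=False
    )


# -- gel images -------------------------------------------------------------


def read_gel_image(path, invert: bool = False) -> np.ndarray:
    """8/16-bit grayscale TIFF or PNG as float; optional inversion to the
    dark-background (signal = high) convention."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:  # collapse RGB(A)
        img = img[..., :3].mean(axis=-1)
    if invert:
        img = img.max() - img
    return img
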