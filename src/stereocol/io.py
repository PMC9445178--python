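"""Reading and writing the package's on-disk formats.

* Point patterns: CSV with header ``x_um,y_um,z_um`` plus a JSON sidecar
  ``{"lx": ..., "ly": ..., "lz": ...}`` holding the window (µm).
* Label volumes: multi-page TIFF, pages along z, plus a JSON sidecar
  ``{"vx_nm": ..., "vy_nm": ..., "vz_nm": ...}`` holding the voxel pitch.
* Curves: tidy CSV with columns subject, group, direction, r, value.
* Counting designs and test results: JSON.

Units are never guessed: a missing sidecar is an error.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import PointPattern3D, Window3D
from .morph3d import CellLabelVolume

__all__ = [
    "write_point_pattern",
    "read_point_pattern",
    "write_label_volume",
    "read_label_volume",
    "write_curves",
    "read_curves",
    "sidecar_path",
]


def sidecar_path(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix(p.suffix + ".json")


def write_point_pattern(pattern: PointPattern3D, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(pattern.points, columns=["x_um", "y_um", "z_um"])
    df.to_csv(path, index=False, float_format="%.9g")
    w = pattern.window
    sidecar_path(path).write_text(json.dumps({"lx": w.lx, "ly": w.ly, "lz": w.lz}))


def read_point_pattern(path: str | Path) -> PointPattern3D:
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(
            f"window sidecar {side} is missing; units/window are never guessed"
        )
    meta = json.loads(side.read_text())
    window = Window3D(lx=float(meta["lx"]), ly=float(meta["ly"]), lz=float(meta["lz"]))
    df = pd.read_csv(path)
    expected = ["x_um", "y_um", "z_um"]
    if list(df.columns) != expected:
        raise ValueError(f"{path}: expected header {expected}, got {list(df.columns)}")
    arr = df.to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(arr))
    if bad.size:
        # +2: 1-based data rows below the header line
        raise ValueError(f"{path}: non-finite coordinate at data row {int(bad[0, 0]) + 2}")
    return PointPattern3D(points=arr.reshape(-1, 3), window=window)


def write_label_volume(volume: CellLabelVolume, path: str | Path) -> None:
    path = Path(path)
    # pages along z: transpose internal (x, y, z) axes to (z, y, x)
    tifffile.imwrite(path, volume.labels.transpose(2, 1, 0).astype(np.int32),
                     photometric="minisblack")
    vx, vy, vz = volume.voxel_pitch_nm
    sidecar_path(path).write_text(json.dumps({"vx_nm": vx, "vy_nm": vy, "vz_nm": vz}))


def read_label_volume(path: str | Path) -> CellLabelVolume:
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"voxel-pitch sidecar {side} is missing; units are never guessed")
    meta = json.loads(side.read_text())
    pitch = (float(meta["vx_nm"]), float(meta["vy_nm"]), float(meta["vz_nm"]))
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    return CellLabelVolume(labels=pages.transpose(2, 1, 0), voxel_pitch_nm=pitch)


def write_curves(df: pd.DataFrame, path: str | Path) -> None:
    required = {"subject", "group", "direction", "r", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"curve table must contain columns {sorted(required)}")
    df.to_csv(path, index=False, float_format="%.9g")


def read_curves(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject", "group", "direction", "r", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["r"] = df["r"].astype(float)
    df["value"] = df["value"].astype(float)
    bad = df.index[~np.isfinite(df["value"].to_numpy(dtype=float))]
    if len(bad):
        raise ValueError(f"{path}: non-finite value at data row {int(bad[0]) + 2}")
    return df
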