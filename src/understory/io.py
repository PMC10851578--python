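"""Reading and writing the pipeline's file formats.

Point clouds are persisted as plain-text XYZ/CSV tables (columns ``x,y,z,
classification,segment,truth_id,truth_layer``); rasters as ESRI ASCII grids
(``.asc``) with an explicit NODATA sentinel; inventories and reports as CSV.
All formats round-trip losslessly at the stated precision.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import PointCloud, Raster

_POINT_COLUMNS = ["x", "y", "z", "classification", "segment", "truth_id", "truth_layer"]

#: no-data sentinel written to ESRI ASCII grids
NODATA = -9999.0


def write_points(cloud: PointCloud, path) -> Path:
    """Write a point cloud as a CSV table with full per-point attributes."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "x": cloud.x,
            "y": cloud.y,
            "z": cloud.z,
            "classification": cloud.classification,
            "segment": cloud.segment,
            "truth_id": cloud.truth_id,
            "truth_layer": cloud.truth_layer,
        }
    )
    try:
        df.to_csv(path, index=False, float_format="%.6f")
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise OSError(f"cannot write point file {path}: {exc}") from exc
    return path


def read_points(path) -> PointCloud:
    """Read a point cloud written by :func:`write_points`.

    Bare ``x,y,z`` tables (no attribute columns) are accepted too.
    """
    path = Path(path)
    if not path.exists():
        raise OSError(f"point file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise OSError(f"cannot parse point file {path}: {exc}") from exc
    missing = [c for c in ("x", "y", "z") if c not in df.columns]
    if missing:
        raise OSError(f"point file {path} lacks columns {missing}")
    xyz = df[["x", "y", "z"]].to_numpy(dtype=np.float64)
    kwargs = {}
    for col in ("classification", "segment", "truth_id", "truth_layer"):
        if col in df.columns:
            kwargs[col] = df[col].to_numpy()
    return PointCloud(xyz, **kwargs)


def write_raster(raster: Raster, path) -> Path:
    """Write a raster as an ESRI ASCII grid (NaN -> NODATA sentinel)."""
    path = Path(path)
    data = raster.data
    grid = np.where(np.isfinite(data), data, NODATA)
    header = (
        f"ncols {data.shape[1]}\n"
        f"nrows {data.shape[0]}\n"
        f"xllcorner {raster.origin[0]:.6f}\n"
        f"yllcorner {raster.origin[1]:.6f}\n"
        f"cellsize {raster.resolution:.6f}\n"
        f"NODATA_value {NODATA:.1f}\n"
    )
    # ESRI ASCII rows run north to south; our row 0 is the southern edge.
    body = "\n".join(
        " ".join(f"{v:.6f}" for v in row) for row in grid[::-1]
    )
    path.write_text(header + body + "\n")
    return path


def read_raster(path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_raster`."""
    path = Path(path)
    if not path.exists():
        raise OSError(f"raster file not found: {path}")
    lines = path.read_text().splitlines()
    meta: dict[str, float] = {}
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in (
            "ncols",
            "nrows",
            "xllcorner",
            "yllcorner",
            "cellsize",
            "nodata_value",
        ):
            meta[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required <= meta.keys():
        warnings.warn(f"incomplete header in {path}; proceeding with raw grid")
    nodata = meta.get("nodata_value", NODATA)
    grid = np.loadtxt(lines[i:], dtype=np.float64, ndmin=2)
    grid = grid[::-1].copy()  # back to row 0 = south
    grid[grid == nodata] = np.nan
    return Raster(
        grid,
        (meta.get("xllcorner", 0.0), meta.get("yllcorner", 0.0)),
        meta.get("cellsize", 1.0),
    )


def write_inventory(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_inventory(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise OSError(f"inventory file not found: {path}")
    return pd.read_csv(path)
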