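"""Shared point-to-grid helpers."""

from __future__ import annotations

import numpy as np

from .containers import Raster


def points_to_max_grid(
    xy: np.ndarray,
    z: np.ndarray,
    resolution: float,
    bounds: tuple[float, float, float, float] | None = None,
) -> Raster:
    """Rasterize points to a max-height grid; empty cells are NaN.

    ``bounds`` = (xmin, ymin, xmax, ymax); defaults to the point extent.
    """
    xy = np.asarray(xy, dtype=float)
    z = np.asarray(z, dtype=float)
    if bounds is None:
        if len(xy) == 0:
            raise ValueError("empty point set and no bounds given")
        xmin, ymin = xy.min(axis=0)
        xmax, ymax = xy.max(axis=0)
    else:
        xmin, ymin, xmax, ymax = bounds
    ncols = max(1, int(np.ceil((xmax - xmin) / resolution)))
    nrows = max(1, int(np.ceil((ymax - ymin) / resolution)))
    grid = np.full((nrows, ncols), -np.inf)
    if len(xy):
        col = np.clip(((xy[:, 0] - xmin) / resolution).astype(int), 0, ncols - 1)
        row = np.clip(((xy[:, 1] - ymin) / resolution).astype(int), 0, nrows - 1)
        np.maximum.at(grid, (row, col), z)
    grid[~np.isfinite(grid)] = np.nan
    return Raster(grid, (xmin, ymin), resolution)
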