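"""Understory point extraction: trunk-buffer removal, denoising, sapling CHM.

Mature-tree trunks pierce the understory stratum and would be detected as
spurious saplings.  Their footprint is predicted from a linear DBH-height
model fitted on field pairs; every understory point within a vertical buffer
cylinder of radius 1.5 x predicted DBH around a mature stem is removed.
Remaining isolated returns (shrub/grass residue) are dropped with a 0.3 m
voxel-neighborhood rule, and the sapling canopy height model is rasterized
at 0.05 m with constrained invalid-cell filling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from scipy.stats import linregress

from ._raster import points_to_max_grid
from .containers import PointCloud, Raster


@dataclass(frozen=True)
class DbhModel:
    """Linear stem-diameter model DBH = slope * height + intercept (meters)."""

    slope: float
    intercept: float
    n: int
    r_squared: float
    dbh_floor: float = 0.02  # predictions clipped at a positive floor

    def predict(self, height) -> np.ndarray:
        h = np.asarray(height, dtype=float)
        return np.maximum(self.slope * h + self.intercept, self.dbh_floor)


def fit_dbh_model(heights, dbhs) -> DbhModel:
    """Ordinary least squares DBH-height fit from field pairs."""
    h = np.asarray(heights, dtype=float)
    d = np.asarray(dbhs, dtype=float)
    if len(h) < 2 or len(h) != len(d):
        raise ValueError("need at least 2 (height, DBH) pairs")
    if np.ptp(h) < 1e-12:
        raise ValueError("degenerate fit: all heights identical")
    res = linregress(h, d)
    return DbhModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        n=len(h),
        r_squared=float(res.rvalue**2),
    )


def remove_trunks(
    points: np.ndarray,
    stem_xy: np.ndarray,
    stem_heights: np.ndarray,
    model: DbhModel,
    buffer_factor: float = 1.5,
) -> np.ndarray:
    """Boolean keep-mask: False inside any mature-tree trunk buffer.

    Each buffer is a full-height vertical cylinder of radius
    ``buffer_factor`` x predicted DBH around the stem position.  The
    predicate is purely spatial: order-independent and idempotent.
    """
    if model is None:
        raise ValueError("a fitted DBH model is required")
    points = np.asarray(points, dtype=float)
    stem_xy = np.asarray(stem_xy, dtype=float).reshape(-1, 2)
    keep = np.ones(len(points), dtype=bool)
    if len(stem_xy) == 0 or len(points) == 0:
        return keep
    radii = buffer_factor * model.predict(stem_heights)
    tree = cKDTree(points[:, :2])
    for (sx, sy), r in zip(stem_xy, radii):
        inside = tree.query_ball_point([sx, sy], r)
        keep[inside] = False
    return keep


def remove_isolated(
    points: np.ndarray, cell: float = 0.3, min_neighbors: int = 1
) -> np.ndarray:
    """Boolean keep-mask dropping isolated points (voxel-neighborhood rule).

    A point is removed iff its 3 x 3 x 3 block of ``cell``-sized voxels
    contains at most ``min_neighbors`` *other* points.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n == 0:
        return np.ones(0, dtype=bool)
    ijk = np.floor(points / cell).astype(np.int64)
    ijk -= ijk.min(axis=0)
    ijk += 1  # pad so +-1 neighbor indices never wrap across rows
    dims = ijk.max(axis=0) + 2
    key = (ijk[:, 0] * dims[1] + ijk[:, 1]) * dims[2] + ijk[:, 2]
    uniq, counts = np.unique(key, return_counts=True)
    neighborhood = np.zeros(n, dtype=np.int64)
    offsets = [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
    ]
    for di, dj, dk in offsets:
        nk = ((ijk[:, 0] + di) * dims[1] + (ijk[:, 1] + dj)) * dims[2] + (
            ijk[:, 2] + dk
        )
        pos = np.searchsorted(uniq, nk)
        pos_c = np.minimum(pos, len(uniq) - 1)
        hit = uniq[pos_c] == nk
        neighborhood += np.where(hit, counts[pos_c], 0)
    other = neighborhood - 1  # exclude the point itself
    return other > min_neighbors


def build_chm(
    points: np.ndarray,
    resolution: float = 0.05,
    bounds: tuple[float, float, float, float] | None = None,
    fill_radius: float = 0.3,
    max_fill_iterations: int = 50,
) -> Raster:
    """Sapling canopy height model: per-cell max height with constrained fill.

    Empty cells within ``fill_radius`` of any occupied cell are filled by
    iterative 3 x 3 valid-neighbor means (filling never exceeds observed
    heights); empty cells farther away stay no-data so open ground is not
    invented.
    """
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        warnings.warn("empty cloud: all-no-data CHM")
        if bounds is None:
            bounds = (0.0, 0.0, resolution, resolution)
        return points_to_max_grid(
            np.empty((0, 2)), np.empty(0), resolution, bounds
        )
    chm = points_to_max_grid(points[:, :2], points[:, 2], resolution, bounds)
    grid = chm.data
    occupied = np.isfinite(grid)
    r_cells = max(1, int(round(fill_radius / resolution)))
    fill_zone = ndimage.binary_dilation(occupied, iterations=r_cells)
    kernel = np.ones((3, 3))
    for _ in range(max_fill_iterations):
        hole = fill_zone & ~np.isfinite(grid)
        if not hole.any():
            break
        filled = np.where(np.isfinite(grid), grid, 0.0)
        valid = np.isfinite(grid).astype(float)
        s = ndimage.convolve(filled, kernel, mode="constant")
        c = ndimage.convolve(valid, kernel, mode="constant")
        mean = np.divide(s, c, out=np.full_like(s, np.nan), where=c > 0)
        update = hole & np.isfinite(mean)
        grid[update] = mean[update]
        if not update.any():
            break
    return Raster(grid, chm.origin, chm.resolution)


def extract_sapling_points(
    understory_points: np.ndarray,
    stem_xy: np.ndarray,
    stem_heights: np.ndarray,
    model: DbhModel | None,
    buffer_factor: float = 1.5,
    noise_cell: float = 0.3,
    min_neighbors: int = 1,
) -> tuple[np.ndarray, dict]:
    """Trunk-buffer removal then isolated-point removal; returns (mask, stats)."""
    keep = np.ones(len(understory_points), dtype=bool)
    if model is not None and len(np.atleast_2d(stem_xy)) and np.size(stem_xy):
        keep &= remove_trunks(
            understory_points, stem_xy, stem_heights, model, buffer_factor
        )
    n_trunk = int((~keep).sum())
    idx = np.flatnonzero(keep)
    sub = remove_isolated(understory_points[idx], noise_cell, min_neighbors)
    keep[idx[~sub]] = False
    stats = {
        "trunk_removed": n_trunk,
        "isolated_removed": int((~sub).sum()),
        "kept": int(keep.sum()),
    }
    return keep, stats
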