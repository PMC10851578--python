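"""Ground classification and fine height normalization.

The fine-normalization procedure guards against tree-height underestimation
caused by grass/shrub returns misclassified as ground: classified ground
points are gridded in x/y at step ``delta`` (default 0.5 m), the lowest point
per cell becomes *true ground*, every other ground point becomes *pseudo
ground* and is forced to height 0, and each nonground point is normalized
against its horizontally nearest true-ground point.

The ground/nonground split itself is pluggable.  The built-in filter is a
progressive grid-minimum surface estimate (per-cell minima, morphological
opening to reject canopy-only cells, light smoothing) — a drop-in for any
external ground filter that fills the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator
from scipy.spatial import cKDTree

from .containers import (
    CLASS_GROUND,
    CLASS_NOISE,
    CLASS_PSEUDO_GROUND,
    CLASS_TRUE_GROUND,
    CLASS_UNCLASSIFIED,
    PointCloud,
)


@dataclass(frozen=True)
class NormalizationConfig:
    """Parameters of the fine-normalization stage."""

    delta: float = 0.5  # true-ground refinement grid step, m
    ground_cell: float = 1.0  # ground-filter surface cell, m
    ground_tolerance: float = 0.25  # max height above surface to call ground, m
    surface_window_cells: int = 5  # median window for the reference surface
    max_search_radius: float = 25.0  # nearest true-ground search limit, m

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")


def classify_ground(
    cloud: PointCloud, config: NormalizationConfig | None = None
) -> PointCloud:
    """Label every point ground or nonground (grid-minimum filter).

    Builds a per-cell minimum-elevation grid, rejects cells whose minimum is
    a canopy return (minimum far above the windowed median of minima), and
    classifies points within ``ground_tolerance`` of the resulting surface
    as ground.
    """
    cfg = config or NormalizationConfig()
    if len(cloud) < 3:
        raise ValueError("need at least 3 points to classify ground")
    x, y, z = cloud.x, cloud.y, cloud.z
    if np.ptp(x) < 1e-9 and np.ptp(y) < 1e-9:
        raise ValueError("degenerate vertical cloud: no horizontal extent")

    cell = cfg.ground_cell
    x0, y0 = x.min(), y.min()
    ncols = max(1, int(np.floor((x.max() - x0) / cell)) + 1)
    nrows = max(1, int(np.floor((y.max() - y0) / cell)) + 1)
    col = np.minimum(((x - x0) / cell).astype(int), ncols - 1)
    row = np.minimum(((y - y0) / cell).astype(int), nrows - 1)

    zmin = np.full((nrows, ncols), np.inf)
    np.minimum.at(zmin, (row, col), z)
    empty = ~np.isfinite(zmin)
    if empty.all():
        raise ValueError("no populated cells")
    if empty.any():
        # nearest-populated fill
        idx = ndimage.distance_transform_edt(
            empty, return_distances=False, return_indices=True
        )
        zmin = zmin[tuple(idx)]

    # a cell minimum is trusted as ground unless it stands well above the
    # local median of minima (the cell saw only canopy returns); the median
    # reference is unbiased on planar slopes, so crests survive.  Untrusted
    # cells are filled from the nearest trusted ones.
    k = max(1, cfg.surface_window_cells)
    reference = ndimage.median_filter(zmin, size=(k, k), mode="nearest")
    trusted = (zmin - reference) <= 0.5
    if not trusted.any():
        raise ValueError("ground filter found no trustworthy ground cells")
    surf = zmin.copy()
    if (~trusted).any():
        idx = ndimage.distance_transform_edt(
            ~trusted, return_distances=False, return_indices=True
        )
        surf = surf[tuple(idx)]

    interp = RegularGridInterpolator(
        (
            y0 + (np.arange(nrows) + 0.5) * cell,
            x0 + (np.arange(ncols) + 0.5) * cell,
        ),
        surf,
        bounds_error=False,
        fill_value=None,
    )
    z_surf = interp(np.column_stack([y, x]))
    out = cloud.copy()
    is_ground = z - z_surf <= cfg.ground_tolerance
    out.classification = np.where(
        is_ground, CLASS_GROUND, CLASS_UNCLASSIFIED
    ).astype(np.int16)
    return out


def refine_true_ground(
    cloud: PointCloud, delta: float = 0.5
) -> PointCloud:
    """Split classified ground into true ground vs pseudo ground.

    Per delta x delta horizontal cell exactly the minimum-z classified ground
    point becomes true ground; every other ground point in the cell becomes
    pseudo ground.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    ground_idx = np.flatnonzero(cloud.classification == CLASS_GROUND)
    if len(ground_idx) == 0:
        raise ValueError("no classified ground points to refine")
    x = cloud.x[ground_idx]
    y = cloud.y[ground_idx]
    z = cloud.z[ground_idx]
    x0, y0 = x.min(), y.min()
    ci = ((x - x0) / delta).astype(np.int64)
    ri = ((y - y0) / delta).astype(np.int64)
    key = ri * (ci.max() + 1) + ci
    order = np.lexsort((z, key))
    key_sorted = key[order]
    first = np.ones(len(key_sorted), dtype=bool)
    first[1:] = key_sorted[1:] != key_sorted[:-1]
    out = cloud.copy()
    out.classification[ground_idx] = CLASS_PSEUDO_GROUND
    out.classification[ground_idx[order[first]]] = CLASS_TRUE_GROUND
    return out


def normalize_heights(
    cloud: PointCloud, max_search_radius: float = 25.0
) -> PointCloud:
    """Replace z by height above the horizontally nearest true-ground point.

    True- and pseudo-ground points get height 0.  Nonground points with no
    true-ground point within ``max_search_radius`` are flagged noise.
    Negative normalized heights are clipped to 0.
    """
    true_mask = cloud.classification == CLASS_TRUE_GROUND
    if not true_mask.any():
        raise ValueError("no true-ground points; run refine_true_ground first")
    out = cloud.copy()
    tg_xy = cloud.xyz[true_mask][:, :2]
    tg_z = cloud.z[true_mask]
    tree = cKDTree(tg_xy)
    nonground = ~np.isin(
        cloud.classification, (CLASS_TRUE_GROUND, CLASS_PSEUDO_GROUND)
    )
    idx = np.flatnonzero(nonground)
    if len(idx):
        d, nn = tree.query(cloud.xyz[idx][:, :2])
        hz = cloud.z[idx] - tg_z[nn]
        out.xyz[idx, 2] = np.maximum(hz, 0.0)
        far = d > max_search_radius
        if far.any():
            out.classification[idx[far]] = CLASS_NOISE
    out.xyz[~nonground, 2] = 0.0
    return out


def normalize(
    cloud: PointCloud, config: NormalizationConfig | None = None
) -> PointCloud:
    """Full fine normalization: classify, refine, normalize heights."""
    cfg = config or NormalizationConfig()
    c = classify_ground(cloud, cfg)
    c = refine_true_ground(c, cfg.delta)
    return normalize_heights(c, cfg.max_search_radius)
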