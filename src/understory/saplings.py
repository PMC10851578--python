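"""Adaptive-bandwidth mean-shift segmentation of understory saplings.

Seeds come from local maxima of the 0.05 m sapling CHM.  For the m-th seed,
the local stem density ``sd_m`` is the mean planar distance to its 4 nearest
seeds and the crown size ``radius_m`` is the radius of the circle
circumscribing the region-grown crown boundary; the kernel bandwidth at that
seed is

    h_loc_m = partial * radius_m / sd_m

with a single global control factor ``partial`` (default 0.5).  Every 3D
sapling point inherits the bandwidth of its nearest seed and is iterated
under the kernel-weighted centroid update

    x0 <- sum_i x_i K(||(x0 - x_i)/h||^2) / sum_i K(...)

with the truncated Gaussian K(u) = exp(-u/2) for u <= 1, else 0, until the
shift falls below tolerance.  Converged modes within half the local
bandwidth are grouped; each group of points is one sapling.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from ._geometry import min_enclosing_radius
from .containers import Raster


@dataclass
class SeedPoint:
    """A CHM local maximum: reference location of one sapling."""

    x: float
    y: float
    z: float  # CHM height at the seed, m
    sd: float = np.nan  # local stem density (mean distance to 4 nearest seeds), m
    radius: float = np.nan  # circumscribed-circle radius of the crown boundary, m
    bandwidth: float = np.nan  # h_loc, m


@dataclass
class SaplingRecord:
    """One delineated sapling with its phenotypes."""

    sapling_id: int
    x: float  # planar coordinates of the highest member point
    y: float
    height: float  # max member height, m
    crown_width: float  # mean of N-S and E-W extents, m
    n_points: int
    seed_bandwidth: float = np.nan


def detect_seeds(
    chm: Raster,
    min_distance: float = 1.5,
    min_height: float = 0.3,
    smooth_sigma: float = 0.1,
) -> list[SeedPoint]:
    """Strict CHM local maxima above a minimum height cut.

    ``min_distance`` is the exclusion window in meters (default half a
    typical planting spacing); ``min_height`` (default 0.3 m) suppresses
    residual grass/shrub returns; ``smooth_sigma`` (m) lightly smooths the
    CHM before peak picking so single crowns do not shed multiple maxima.
    Seed heights are read from the unsmoothed CHM.
    """
    if not np.isfinite(chm.data).any():
        return []
    grid = np.where(np.isfinite(chm.data), chm.data, 0.0)
    search = grid
    if smooth_sigma > 0:
        from scipy.ndimage import gaussian_filter

        search = gaussian_filter(grid, smooth_sigma / chm.resolution)
    md = max(1, int(round(min_distance / chm.resolution)))
    peaks = peak_local_max(
        search, min_distance=md, threshold_abs=min_height, exclude_border=False
    )
    seeds = []
    for r, c in peaks:
        if grid[r, c] < min_height:
            continue
        x, y = chm.cell_center(r, c)
        seeds.append(SeedPoint(float(x), float(y), float(grid[r, c])))
    return seeds


def local_density(
    seed_xy: np.ndarray, all_xy: np.ndarray, k: int = 4, default_spacing: float = 2.0
) -> float:
    """Mean planar distance from a seed to its k nearest other seeds."""
    all_xy = np.asarray(all_xy, dtype=float).reshape(-1, 2)
    others = all_xy[
        ~np.all(np.isclose(all_xy, np.asarray(seed_xy, dtype=float)), axis=1)
    ]
    if len(others) == 0:
        warnings.warn("single seed: using default spacing as stem density")
        return default_spacing
    kk = min(k, len(others))
    d, _ = cKDTree(others).query(np.asarray(seed_xy, dtype=float), k=kk)
    return float(np.mean(np.atleast_1d(d)))


def crown_boundary(
    chm: Raster, seed: SeedPoint, rise_tolerance: float = 0.03
) -> tuple[np.ndarray, float]:
    """Region-grow the crown around a seed and circumscribe its boundary.

    Growth proceeds over monotonically non-increasing CHM heights (within
    ``rise_tolerance``) and stops at rises or no-data.  Returns the boundary
    cell centers and the minimum enclosing circle radius.
    """
    grid = chm.data
    nrows, ncols = grid.shape
    r0, c0 = chm.world_to_cell(seed.x, seed.y)
    r0 = int(np.clip(r0, 0, nrows - 1))
    c0 = int(np.clip(c0, 0, ncols - 1))
    if not np.isfinite(grid[r0, c0]):
        warnings.warn("seed on no-data cell: one-cell crown")
        return (
            np.array([[seed.x, seed.y]]),
            float(chm.resolution * np.sqrt(2)),
        )
    region = np.zeros_like(grid, dtype=bool)
    region[r0, c0] = True
    q = deque([(r0, c0)])
    while q:
        r, c = q.popleft()
        zc = grid[r, c]
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if not (0 <= rr < nrows and 0 <= cc < ncols) or region[rr, cc]:
                continue
            zn = grid[rr, cc]
            if np.isfinite(zn) and zn <= zc + rise_tolerance:
                region[rr, cc] = True
                q.append((rr, cc))
    # boundary = region cells with a non-region 4-neighbor (or at the edge)
    padded = np.pad(region, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    boundary = region & ~interior
    rows, cols = np.nonzero(boundary)
    if len(rows) == 0:
        rows, cols = np.array([r0]), np.array([c0])
    bx, by = chm.cell_center(rows, cols)
    pts = np.column_stack([bx, by])
    if len(pts) == 1:
        return pts, float(chm.resolution * np.sqrt(2))
    return pts, min_enclosing_radius(pts)


def bandwidth(radius: float, sd: float, partial: float = 0.5) -> float:
    """Adaptive kernel bandwidth h = partial * radius / sd."""
    if partial <= 0:
        raise ValueError("the bandwidth control factor must be positive")
    if sd <= 0:
        raise ValueError("local stem density must be positive")
    if radius <= 0:
        raise ValueError("crown radius must be positive")
    return partial * radius / sd


def calibrate_seeds(
    chm: Raster,
    seeds: list[SeedPoint],
    partial: float = 0.5,
    k_density: int = 4,
    default_spacing: float = 2.0,
    min_bandwidth: float = 0.3,
    max_bandwidth: float = 1.0,
) -> list[SeedPoint]:
    """Fill sd, radius and bandwidth for every seed (in place, returned).

    ``min_bandwidth`` floors h at the smallest crown scale the scanner can
    resolve, so widely spaced plantings keep a workable kernel window;
    ``max_bandwidth`` caps h so an overgrown crown boundary cannot widen the
    kernel past neighboring saplings.
    """
    if not seeds:
        return seeds
    xy = np.array([(s.x, s.y) for s in seeds])
    for i, s in enumerate(seeds):
        s.sd = local_density(xy[i], xy, k=k_density, default_spacing=default_spacing)
        _, s.radius = crown_boundary(chm, s)
        h = bandwidth(s.radius, s.sd, partial)
        s.bandwidth = float(np.clip(h, min_bandwidth, max_bandwidth))
    return seeds


def mean_shift(
    points: np.ndarray,
    seeds: list[SeedPoint],
    tolerance: float = 1e-3,
    max_iterations: int = 100,
    merge_factor: float = 0.5,
    z_weight: float = 0.3,
) -> np.ndarray:
    """Cluster 3D points under per-point adaptive truncated-Gaussian kernels.

    Each point takes the bandwidth of its nearest seed (planar), iterates the
    kernel-weighted centroid update until the shift is below ``tolerance``
    or ``max_iterations`` is hit, then converged modes closer than
    ``merge_factor`` x local bandwidth are grouped.  ``z_weight`` scales the
    vertical axis of the feature space (1 = isotropic 3D, 0 = planar mode
    seeking; the default down-weights height so a conical crown collapses to
    one mode instead of fragmenting along the stem).  Returns labels
    (0..k-1; -1 = noise for points whose kernel window empties).
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n == 0:
        raise ValueError("empty point set")
    if not seeds:
        return np.full(n, -1, dtype=int)
    seed_xy = np.array([(s.x, s.y) for s in seeds])
    seed_h = np.array([s.bandwidth for s in seeds])
    if np.any(~np.isfinite(seed_h)):
        raise ValueError("seeds lack bandwidths; run calibrate_seeds first")
    _, nearest = cKDTree(seed_xy).query(points[:, :2])
    h = seed_h[nearest]

    feat = points.copy()
    feat[:, 2] *= z_weight
    data_tree = cKDTree(feat)
    modes = feat.copy()
    active = np.ones(n, dtype=bool)
    noise = np.zeros(n, dtype=bool)
    from itertools import chain

    for _ in range(max_iterations):
        idx = np.flatnonzero(active)
        if len(idx) == 0:
            break
        neighbor_lists = data_tree.query_ball_point(modes[idx], h[idx])
        lens = np.array([len(l) for l in neighbor_lists])
        empty = lens == 0
        if empty.any():
            noise[idx[empty]] = True
            active[idx[empty]] = False
            idx = idx[~empty]
            neighbor_lists = [l for l in neighbor_lists if l]
            lens = lens[~empty]
            if len(idx) == 0:
                break
        flat = np.fromiter(
            chain.from_iterable(neighbor_lists), dtype=np.int64, count=lens.sum()
        )
        starts = np.concatenate([[0], np.cumsum(lens)[:-1]])
        rep = np.repeat(np.arange(len(idx)), lens)
        diff = modes[idx][rep] - feat[flat]
        u = np.einsum("ij,ij->i", diff, diff) / h[idx][rep] ** 2
        w = np.exp(-0.5 * u)
        num = np.add.reduceat(w[:, None] * feat[flat], starts, axis=0)
        den = np.add.reduceat(w, starts)
        new = num / den[:, None]
        shift = np.linalg.norm(new - modes[idx], axis=1)
        modes[idx] = new
        active[idx[shift < tolerance]] = False

    # group converged modes within merge_factor * local bandwidth
    ok = np.flatnonzero(~noise)
    labels = np.full(n, -1, dtype=int)
    if len(ok) == 0:
        return labels
    mode_tree = cKDTree(modes[ok])
    pairs = mode_tree.query_pairs(r=float(merge_factor * h.max()), output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(modes[ok][pairs[:, 0]] - modes[ok][pairs[:, 1]], axis=1)
        lim = merge_factor * np.minimum(h[ok][pairs[:, 0]], h[ok][pairs[:, 1]])
        pairs = pairs[d <= lim]
    m = len(ok)
    if len(pairs):
        graph = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(m, m)
        )
        _, comp = connected_components(graph, directed=False)
    else:
        comp = np.arange(m)
    _, comp = np.unique(comp, return_inverse=True)

    # consolidate mode groups onto their reference seeds: groups whose mean
    # planar mode sits within the local bandwidth of a seed take that seed's
    # identity (fragments of one crown re-unite); orphan groups are noise
    seed_tree = cKDTree(seed_xy)
    group_label = np.full(comp.max() + 1, -1, dtype=int)
    for g in range(comp.max() + 1):
        members = ok[comp == g]
        mode_xy = modes[members][:, :2].mean(axis=0)
        d, j = seed_tree.query(mode_xy)
        if d <= max(seed_h[j], float(np.median(h[members]))):
            group_label[g] = j
    raw = group_label[comp]
    labels[ok] = raw
    # relabel used seeds to consecutive cluster ids
    used = np.unique(raw[raw >= 0])
    remap = {int(s): i for i, s in enumerate(used)}
    labels[ok] = np.array([remap.get(int(v), -1) for v in raw], dtype=int)
    return labels


def extract_phenotypes(points: np.ndarray, sapling_id: int = 0,
                       seed_bandwidth: float = np.nan) -> SaplingRecord:
    """Phenotypes of one cluster: top position/height, mean N-S / E-W extent."""
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        raise ValueError("empty cluster")
    top = int(np.argmax(points[:, 2]))
    width = 0.5 * (np.ptp(points[:, 0]) + np.ptp(points[:, 1]))
    return SaplingRecord(
        sapling_id=sapling_id,
        x=float(points[top, 0]),
        y=float(points[top, 1]),
        height=float(points[top, 2]),
        crown_width=float(width),
        n_points=len(points),
        seed_bandwidth=seed_bandwidth,
    )


def segment_saplings(
    points: np.ndarray,
    chm: Raster,
    partial: float = 0.5,
    min_distance: float = 1.5,
    seed_min_height: float = 0.3,
    tolerance: float = 1e-3,
    max_iterations: int = 100,
    min_cluster_points: int = 3,
    z_weight: float = 0.3,
) -> tuple[list[SaplingRecord], np.ndarray]:
    """Full sapling stage: seeds -> bandwidths -> mean shift -> phenotypes.

    Returns (records, per-point labels); clusters below
    ``min_cluster_points`` are folded into noise.
    """
    seeds = detect_seeds(chm, min_distance=min_distance, min_height=seed_min_height)
    if not seeds:
        return [], np.full(len(points), -1, dtype=int)
    calibrate_seeds(chm, seeds, partial=partial)
    labels = mean_shift(
        points, seeds, tolerance=tolerance, max_iterations=max_iterations,
        z_weight=z_weight,
    )
    records = []
    new_labels = np.full(len(points), -1, dtype=int)
    next_id = 0
    for lab in np.unique(labels):
        if lab < 0:
            continue
        mask = labels == lab
        if mask.sum() < min_cluster_points:
            continue
        rec = extract_phenotypes(points[mask], next_id)
        records.append(rec)
        new_labels[mask] = next_id
        next_id += 1
    return records, new_labels


def records_to_frame(records: list[SaplingRecord]) -> pd.DataFrame:
    """Sapling table (one row per detected sapling)."""
    return pd.DataFrame(
        [
            dict(
                sapling_id=r.sapling_id,
                x=r.x,
                y=r.y,
                height=r.height,
                crown_width=r.crown_width,
                n_points=r.n_points,
            )
            for r in records
        ],
        columns=["sapling_id", "x", "y", "height", "crown_width", "n_points"],
    )
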