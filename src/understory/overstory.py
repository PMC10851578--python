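"""Overstory stratification and Nyström spectral crown delineation.

The normalized cloud is split at a height threshold (default 5 m, sitting in
the gap between sapling tops at 3.5 m and mature-tree crowns above 10 m).
Crowns in the overstory stratum are delineated by spectral clustering on a
truncated Gaussian affinity; for large strata the affinity eigenbasis is
approximated with Nyström landmarks so the full n x n matrix is never formed.
The cluster count is seeded from local maxima of the overstory canopy height
model and can be overridden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import peak_local_max
from sklearn.cluster import KMeans

from ._geometry import MinRect, min_bounding_rectangle
from ._raster import points_to_max_grid
from .containers import PointCloud, Raster


@dataclass
class StratifiedCloud:
    """Index partition of nonground points at the height threshold."""

    cloud: PointCloud
    overstory_idx: np.ndarray  # z > threshold
    understory_idx: np.ndarray  # 0 < z <= threshold
    threshold: float


def stratify(cloud: PointCloud, threshold: float = 5.0) -> StratifiedCloud:
    """Partition normalized nonground points at the height threshold.

    A point exactly at the threshold belongs to the understory (the
    overstory is strictly *above* the threshold).  Ground and pseudo-ground
    points (height 0) fall in neither stratum.
    """
    z = cloud.z
    nonzero = z > 0
    over = np.flatnonzero(nonzero & (z > threshold))
    under = np.flatnonzero(nonzero & (z <= threshold))
    if len(over) == 0:
        warnings.warn("empty overstory stratum; overstory stages will be skipped")
    return StratifiedCloud(cloud, over, under, threshold)


def estimate_threshold(
    heights: np.ndarray, bin_width: float = 0.5, smooth_sigma: float = 1.0
) -> float:
    """Histogram-valley estimate of the stratification threshold.

    Smooths the height histogram and returns the height of the deepest valley
    between the two dominant modes.  Falls back to 5 m when the histogram is
    unimodal.
    """
    from scipy.ndimage import gaussian_filter1d

    h = np.asarray(heights, dtype=float)
    h = h[h > 0]
    if len(h) < 10:
        return 5.0
    bins = np.arange(0, h.max() + bin_width, bin_width)
    counts, edges = np.histogram(h, bins=bins)
    smoothed = gaussian_filter1d(counts.astype(float), smooth_sigma)
    # local maxima of the smoothed histogram
    peaks = [
        i
        for i in range(1, len(smoothed) - 1)
        if smoothed[i] >= smoothed[i - 1] and smoothed[i] > smoothed[i + 1]
    ]
    if len(peaks) < 2:
        return 5.0
    peaks.sort(key=lambda i: smoothed[i], reverse=True)
    i0, i1 = sorted(peaks[:2])
    if i1 - i0 < 2:
        return 5.0
    valley = i0 + int(np.argmin(smoothed[i0 : i1 + 1]))
    return float(0.5 * (edges[valley] + edges[valley + 1]))


@dataclass
class TreeSegment:
    """One delineated crown with its structural parameters."""

    segment_id: int
    indices: np.ndarray  # indices into the segmented stratum's cloud
    points: np.ndarray = field(repr=False)  # (n, 3) member coordinates
    stem: tuple[float, float] = (0.0, 0.0)  # x, y of the highest point
    height: float = 0.0  # max member height, m
    crown_width: float = 0.0  # mean of the MBR sides, m
    centroid: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mbr: MinRect | None = None
    candidate: bool = False

    @property
    def crown_radius(self) -> float:
        return self.crown_width / 2.0

    @property
    def n_points(self) -> int:
        return len(self.indices)


def make_segment(segment_id: int, indices: np.ndarray, points: np.ndarray) -> TreeSegment:
    """Compute the structural parameters of one segment."""
    indices = np.asarray(indices)
    points = np.asarray(points, dtype=float)
    top = int(np.argmax(points[:, 2]))
    mbr = min_bounding_rectangle(points[:, :2]) if len(points) >= 2 else None
    width = 0.5 * (mbr.long_side + mbr.short_side) if mbr else 0.0
    return TreeSegment(
        segment_id=segment_id,
        indices=indices,
        points=points,
        stem=(float(points[top, 0]), float(points[top, 1])),
        height=float(points[:, 2].max()),
        crown_width=width,
        centroid=tuple(points.mean(axis=0)),
        mbr=mbr,
    )


def segments_from_labels(
    points: np.ndarray, labels: np.ndarray, indices: np.ndarray | None = None
) -> list[TreeSegment]:
    """Group labeled points into TreeSegments (label -1 = unassigned, skipped)."""
    if indices is None:
        indices = np.arange(len(points))
    segs = []
    for sid in np.unique(labels):
        if sid < 0:
            continue
        m = labels == sid
        segs.append(make_segment(int(sid), indices[m], points[m]))
    return segs


def overstory_chm(
    stratified: StratifiedCloud, resolution: float = 0.5,
    bounds: tuple[float, float, float, float] | None = None,
) -> Raster:
    """Max-height CHM of the overstory stratum."""
    idx = stratified.overstory_idx
    return points_to_max_grid(
        stratified.cloud.xyz[idx][:, :2], stratified.cloud.z[idx], resolution, bounds
    )


def count_crowns_from_chm(
    chm: Raster, min_distance_m: float = 2.0, min_height: float = 5.0
) -> int:
    """Number of CHM local maxima: the spectral cluster count seed."""
    grid = np.where(np.isfinite(chm.data), chm.data, 0.0)
    md = max(1, int(round(min_distance_m / chm.resolution)))
    peaks = peak_local_max(
        grid, min_distance=md, threshold_abs=min_height, exclude_border=False
    )
    return max(1, len(peaks))


@dataclass(frozen=True)
class NscConfig:
    """Affinity and clustering parameters for crown delineation."""

    sigma_xy: float = 1.5  # horizontal Gaussian scale, m
    sigma_z: float = 6.0  # vertical scale (down-weighted), m
    cutoff: float = 5.0  # horizontal truncation radius, m
    n_landmarks: int = 500
    seed: int = 0
    chm_resolution: float = 0.5
    chm_min_distance: float = 2.0


def _affinity(a: np.ndarray, b: np.ndarray, cfg: NscConfig) -> np.ndarray:
    """Truncated anisotropic Gaussian affinity between point sets."""
    dxy2 = (
        (a[:, None, 0] - b[None, :, 0]) ** 2 + (a[:, None, 1] - b[None, :, 1]) ** 2
    )
    dz2 = (a[:, None, 2] - b[None, :, 2]) ** 2
    w = np.exp(-0.5 * (dxy2 / cfg.sigma_xy**2 + dz2 / cfg.sigma_z**2))
    w[dxy2 > cfg.cutoff**2] = 0.0
    return w


def full_affinity(points: np.ndarray, cfg: NscConfig | None = None) -> np.ndarray:
    """Dense affinity matrix (exact path; small strata only)."""
    cfg = cfg or NscConfig()
    return _affinity(points, points, cfg)


def nystrom_embedding(
    points: np.ndarray, k: int, cfg: NscConfig, rng: np.random.Generator
) -> np.ndarray:
    """Top-k eigenbasis of the normalized affinity via Nyström landmarks."""
    n = len(points)
    m = min(cfg.n_landmarks, n)
    landmarks = rng.choice(n, size=m, replace=False)
    C = _affinity(points, points[landmarks], cfg)  # n x m
    W = C[landmarks]  # m x m
    # rank-truncated pseudo-inverses: near-duplicate landmarks make W close
    # to singular and an unfiltered inverse destroys the embedding
    evals, evecs = np.linalg.eigh(W)
    keep = evals > 1e-6 * evals.max()
    Winv = (evecs[:, keep] / evals[keep]) @ evecs[:, keep].T
    # approximate degrees: d = C W^+ (C^T 1)
    d = np.maximum(C @ (Winv @ C.sum(axis=0)), 1e-10)
    Dc = C / np.sqrt(d)[:, None]
    # K_hat = Dc W^+ Dc^T ; eigenbasis via the m x m problem
    W_isqrt = (evecs[:, keep] / np.sqrt(evals[keep])) @ evecs[:, keep].T
    M = Dc @ W_isqrt  # n x m, K_hat = M M^T
    G = M.T @ M
    gvals, gvecs = np.linalg.eigh(G)
    order = np.argsort(gvals)[::-1][:k]
    U = M @ gvecs[:, order]
    U /= np.sqrt(np.maximum(gvals[order], 1e-12))[None, :]
    return U


def spectral_labels_from_embedding(
    U: np.ndarray, k: int, seed: int
) -> np.ndarray:
    """Row-normalize the spectral embedding and group with k-means++."""
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    V = U / np.maximum(norms, 1e-12)
    km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
    return km.fit_predict(V)


def nsc_segment(
    points: np.ndarray,
    k: int | None = None,
    config: NscConfig | None = None,
    exact: bool = False,
) -> list[TreeSegment]:
    """Delineate overstory crowns by (Nyström) spectral clustering.

    ``k=None`` seeds the cluster count from CHM local maxima of the stratum.
    ``exact=True`` forms the full affinity and decomposes it directly
    (reference path for small strata).
    """
    cfg = config or NscConfig()
    points = np.asarray(points, dtype=float)
    if len(points) == 0:
        raise ValueError("empty overstory stratum")
    if k is None:
        chm = points_to_max_grid(points[:, :2], points[:, 2], cfg.chm_resolution)
        grid = np.where(np.isfinite(chm.data), chm.data, 0.0)
        md = max(1, int(round(cfg.chm_min_distance / cfg.chm_resolution)))
        peaks = peak_local_max(
            grid, min_distance=md, threshold_abs=0.0, exclude_border=False
        )
        k = max(1, len(peaks))
    k = min(k, len(points))
    if k == 1:
        labels = np.zeros(len(points), dtype=int)
        return segments_from_labels(points, labels)

    rng = np.random.default_rng(cfg.seed)
    try:
        if exact or len(points) <= cfg.n_landmarks:
            A = full_affinity(points, cfg)
            d = np.maximum(A.sum(axis=1), 1e-10)
            L = A / np.sqrt(d)[:, None] / np.sqrt(d)[None, :]
            evals, evecs = np.linalg.eigh(L)
            U = evecs[:, np.argsort(evals)[::-1][:k]]
        else:
            U = nystrom_embedding(points, k, cfg, rng)
        labels = spectral_labels_from_embedding(U, k, cfg.seed)
    except np.linalg.LinAlgError:
        warnings.warn(
            "eigen-solver failed on degenerate affinity; "
            "falling back to distance-based clustering"
        )
        km = KMeans(n_clusters=k, n_init=10, random_state=cfg.seed)
        labels = km.fit_predict(points)
    # points isolated from every landmark can land in arbitrary clusters;
    # reattach each point to the majority label of its 5 nearest neighbors
    # only if it has zero affinity support (rare)
    return segments_from_labels(points, labels)


def assignment_agreement(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Best-matching fraction of identically assigned points (Hungarian)."""
    from scipy.optimize import linear_sum_assignment

    la = np.unique(labels_a)
    lb = np.unique(labels_b)
    conf = np.zeros((len(la), len(lb)))
    for i, a in enumerate(la):
        for j, b in enumerate(lb):
            conf[i, j] = np.sum((labels_a == a) & (labels_b == b))
    ri, ci = linear_sum_assignment(-conf)
    return float(conf[ri, ci].sum() / len(labels_a))
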