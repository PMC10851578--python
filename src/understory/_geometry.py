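"""2D geometry primitives used by the crown postprocessor.

Minimum bounding rectangles come from shapely's rotated-rectangle routine;
alpha shapes are built from a Delaunay triangulation by dropping triangles
with large circumradius; polyline simplification uses the classic
Douglas-Peucker recursion (endpoint-preserving).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, QhullError
from shapely.geometry import MultiPoint, Polygon
from shapely.ops import polygonize, unary_union


@dataclass(frozen=True)
class MinRect:
    """Minimum-area bounding rectangle of a 2D point set."""

    center: tuple[float, float]
    long_side: float
    short_side: float
    long_axis: tuple[float, float]  # unit vector of the long side
    short_axis: tuple[float, float]

    @property
    def aspect(self) -> float:
        """short/long ratio; 1 for a square footprint."""
        return self.short_side / self.long_side if self.long_side > 0 else 1.0


def min_bounding_rectangle(xy: np.ndarray) -> MinRect:
    """Minimum rotated rectangle of points (degenerate inputs get tiny sides)."""
    xy = np.asarray(xy, dtype=float)
    mp = MultiPoint(xy)
    rect = mp.minimum_rotated_rectangle
    if rect.geom_type != "Polygon":  # collinear or single point
        minx, miny, maxx, maxy = mp.bounds
        dx = max(maxx - minx, 1e-9)
        dy = max(maxy - miny, 1e-9)
        long_side, short_side = max(dx, dy), min(dx, dy)
        axis = (1.0, 0.0) if dx >= dy else (0.0, 1.0)
        return MinRect(
            ((minx + maxx) / 2, (miny + maxy) / 2),
            long_side,
            short_side,
            axis,
            (-axis[1], axis[0]),
        )
    coords = np.asarray(rect.exterior.coords)[:-1]
    e1 = coords[1] - coords[0]
    e2 = coords[2] - coords[1]
    l1, l2 = np.linalg.norm(e1), np.linalg.norm(e2)
    if l1 >= l2:
        long_side, short_side = l1, max(l2, 1e-9)
        la = e1 / max(l1, 1e-12)
    else:
        long_side, short_side = l2, max(l1, 1e-9)
        la = e2 / max(l2, 1e-12)
    center = coords.mean(axis=0)
    return MinRect(
        (float(center[0]), float(center[1])),
        float(long_side),
        float(short_side),
        (float(la[0]), float(la[1])),
        (float(-la[1]), float(la[0])),
    )


def alpha_shape(xy: np.ndarray, alpha_radius: float | None = None) -> Polygon:
    """Concave boundary of 2D points: keep Delaunay triangles whose
    circumradius is below ``alpha_radius``; fall back to the convex hull when
    the result is empty or degenerate.

    ``alpha_radius=None`` picks 3x the mean nearest-neighbor spacing with a
    floor of 1 m: crown silhouettes need sub-meter concavities resolved, but
    an alpha below the local sampling scale shatters the shape and forces the
    hull fallback.
    """
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 3:
        raise ValueError("alpha shape needs at least 3 points")
    hull_poly = MultiPoint(xy).convex_hull
    if hull_poly.geom_type != "Polygon":
        raise ValueError("degenerate (collinear) point set")
    try:
        tri = Delaunay(xy)
    except QhullError:
        return hull_poly
    a, b, c = (xy[tri.simplices[:, i]] for i in range(3))
    # circumradius = abc / (4 * area)
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    area = 0.5 * np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
        - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        circum = la * lb * lc / np.maximum(4 * area, 1e-12)
    if alpha_radius is None:
        from scipy.spatial import cKDTree

        d, _ = cKDTree(xy).query(xy, k=2)
        alpha_radius = max(3.0 * float(d[:, 1].mean()), 1.0)
    keep = circum < alpha_radius
    if not keep.any():
        warnings.warn("alpha too small; falling back to convex hull")
        return hull_poly
    polys = [Polygon(xy[s]) for s in tri.simplices[keep]]
    merged = unary_union(polys)
    if merged.geom_type == "MultiPolygon":
        merged = max(merged.geoms, key=lambda p: p.area)
    if merged.is_empty or merged.geom_type != "Polygon":
        warnings.warn("alpha shape degenerate; falling back to convex hull")
        return hull_poly
    # the boundary must contain all points; if triangles were dropped at the
    # rim, points can fall outside — then the hull is the honest answer
    if not merged.buffer(1e-9).contains(MultiPoint(xy)):
        hull_area = hull_poly.area
        if merged.area < 0.5 * hull_area:
            warnings.warn("alpha shape lost coverage; falling back to convex hull")
            return hull_poly
    return merged


def upper_envelope(boundary: Polygon, bin_width: float | None = None) -> np.ndarray:
    """Upper envelope of a closed boundary as (s, z) vertices.

    For each along-axis bin the maximum boundary height is taken (the
    exterior ring is densified first so long edges contribute), yielding an
    s-ordered polyline with vertex spacing equal to ``bin_width`` (default:
    the median adjacent-vertex spacing of the boundary).
    """
    coords = np.asarray(boundary.exterior.coords)
    if bin_width is None:
        seg = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        bin_width = max(float(np.median(seg)), 1e-6)
    dense = np.asarray(
        boundary.exterior.segmentize(bin_width / 2.0).coords
    )
    s = dense[:, 0]
    z = dense[:, 1]
    s0 = s.min()
    nbins = max(1, int(np.ceil((s.max() - s0) / bin_width)))
    idx = np.minimum(((s - s0) / bin_width).astype(int), nbins - 1)
    zmax = np.full(nbins, -np.inf)
    np.maximum.at(zmax, idx, z)
    filled = np.isfinite(zmax)
    centers = s0 + (np.arange(nbins) + 0.5) * bin_width
    return np.column_stack([centers[filled], zmax[filled]])


def douglas_peucker(points: np.ndarray, epsilon: float) -> np.ndarray:
    """Endpoint-preserving Douglas-Peucker simplification of a polyline."""
    pts = np.asarray(points, dtype=float)
    if len(pts) <= 2 or epsilon <= 0:
        return pts.copy()
    keep = np.zeros(len(pts), dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, len(pts) - 1)]
    while stack:
        i0, i1 = stack.pop()
        if i1 <= i0 + 1:
            continue
        seg = pts[i1] - pts[i0]
        seg_len = np.linalg.norm(seg)
        mid = pts[i0 + 1 : i1]
        if seg_len < 1e-12:
            d = np.linalg.norm(mid - pts[i0], axis=1)
        else:
            rel = mid - pts[i0]
            d = np.abs(seg[0] * rel[:, 1] - seg[1] * rel[:, 0]) / seg_len
        j = int(np.argmax(d))
        if d[j] > epsilon:
            k = i0 + 1 + j
            keep[k] = True
            stack.extend([(i0, k), (k, i1)])
    return pts[keep]


def convex_hull_2d(xy: np.ndarray) -> Polygon:
    """Convex hull polygon of 2D points (errors on degenerate sets)."""
    xy = np.asarray(xy, dtype=float)
    hull = MultiPoint(xy).convex_hull
    if hull.geom_type != "Polygon":
        raise ValueError("degenerate point set: convex hull is not a polygon")
    return hull


def min_enclosing_radius(xy: np.ndarray) -> float:
    """Radius of the minimum enclosing circle of 2D points."""
    import shapely

    return float(shapely.minimum_bounding_radius(MultiPoint(np.asarray(xy, float))))
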