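"""Postprocessing of spectral crown segmentation (candidate filtering,
forced facade splitting, backward allocation).

Spectral delineation leaves merged crowns (undersegmentation) and crown
fragments (oversegmentation).  The repair proceeds in three passes:

1. *Candidate filtering*: a segment is a candidate individual tree iff it
   simultaneously passes four rules — height above 5 m, minimum-bounding-
   rectangle aspect ratio strictly between 0.7 and 1.3, horizontal centroid
   inside the crown footprint hull, and point count above half the running
   mean count of accepted candidates.
2. *Forced splitting*: each suspect segment is projected onto the two
   vertical facades of its bounding rectangle; crown silhouettes are traced
   with an alpha shape, the upper envelope is simplified by Douglas-Peucker
   with tolerance five times the mean adjacent-vertex spacing, and envelope
   saddles (slope sign change from falling to rising) become cutting planes
   orthogonal to the facade.  Segments with no saddle in either facade join
   the residual point set.
3. *Backward allocation*: each residual point merges with the candidate
   whose planar distance is minimal and below that candidate's crown radius;
   otherwise a local point set (threshold = mean crown radius of the three
   nearest candidates) votes, and a strict majority (>50%) wins; otherwise
   the point is noise.  Candidate parameters are recomputed afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Point

from ._geometry import (
    alpha_shape,
    convex_hull_2d,
    douglas_peucker,
    upper_envelope,
)
from .overstory import TreeSegment, make_segment


@dataclass(frozen=True)
class CandidateRules:
    """The four candidate-tree acceptance rules."""

    min_height: float = 5.0
    aspect_low: float = 0.7
    aspect_high: float = 1.3
    num_mean_fraction: float = 0.5  # count must exceed num_mean * fraction


def aspect_ok(ratio: float, rules: CandidateRules | None = None) -> bool:
    """Strict MBR aspect test (short/long ratio)."""
    r = rules or CandidateRules()
    return r.aspect_low < ratio < r.aspect_high


def centroid_in_crown(segment: TreeSegment) -> bool:
    """Horizontal centroid inside the 2D convex hull of the footprint."""
    if len(segment.points) < 3:
        return False
    try:
        hull = convex_hull_2d(segment.points[:, :2])
    except ValueError:
        return False
    return bool(hull.covers(Point(segment.centroid[0], segment.centroid[1])))


def passes_rules(
    segment: TreeSegment, num_mean: float, rules: CandidateRules
) -> bool:
    if segment.height <= rules.min_height:
        return False
    if segment.mbr is None or not aspect_ok(segment.mbr.aspect, rules):
        return False
    if not centroid_in_crown(segment):
        return False
    if segment.n_points <= num_mean * rules.num_mean_fraction:
        return False
    return True


def bootstrap_num_mean(
    segments: list[TreeSegment], seed: int = 0, fraction: float = 0.1
) -> float:
    """Initial num_mean: median point count of a seeded random sample."""
    rng = np.random.default_rng(seed)
    n = max(1, int(round(fraction * len(segments))))
    pick = rng.choice(len(segments), size=min(n, len(segments)), replace=False)
    return float(np.median([segments[i].n_points for i in pick]))


def filter_candidates(
    segments: list[TreeSegment],
    seed: int = 0,
    rules: CandidateRules | None = None,
    num_mean: float | None = None,
) -> tuple[list[TreeSegment], list[TreeSegment], float]:
    """Route segments into candidates and suspects.

    Returns (candidates, suspects, final num_mean).  num_mean starts from a
    seeded bootstrap and is updated as a running mean over accepted
    candidates.
    """
    rules = rules or CandidateRules()
    if not segments:
        raise ValueError("no segments to filter")
    if num_mean is None:
        num_mean = bootstrap_num_mean(segments, seed)
    counts = [num_mean]
    candidates: list[TreeSegment] = []
    suspects: list[TreeSegment] = []
    for seg in segments:
        if passes_rules(seg, float(np.mean(counts)), rules):
            seg.candidate = True
            candidates.append(seg)
            counts.append(seg.n_points)
        else:
            seg.candidate = False
            suspects.append(seg)
    return candidates, suspects, float(np.mean(counts))


def facade_projection(segment: TreeSegment) -> tuple[np.ndarray, np.ndarray]:
    """Project member points onto the MBR's two vertical facades.

    Returns (long-facade, short-facade) point sets as (along-side, z) pairs.
    """
    if segment.mbr is None:
        raise ValueError("segment has no bounding rectangle")
    mbr = segment.mbr
    rel = segment.points[:, :2] - np.array(mbr.center)
    s_long = rel @ np.array(mbr.long_axis)
    s_short = rel @ np.array(mbr.short_axis)
    z = segment.points[:, 2]
    return np.column_stack([s_long, z]), np.column_stack([s_short, z])


def boundary_trace(projected: np.ndarray, alpha_radius: float | None = None):
    """Closed crown-silhouette boundary of a projected point set."""
    if len(projected) < 3:
        raise ValueError("need at least 3 projected points")
    return alpha_shape(projected, alpha_radius)


def simplify_and_find_inflections(
    boundary, dp_factor: float = 5.0, point_spacing: float | None = None
) -> list[float]:
    """Saddle positions of the simplified upper envelope.

    The envelope is simplified by Douglas-Peucker with tolerance
    ``dp_factor`` times the mean adjacent-point spacing (``point_spacing``
    when given, else the boundary's own vertex spacing); retained interior
    vertices where the discrete slope turns from falling to rising (local
    height minima — the saddle between two crown apices) are returned as
    along-facade positions.
    """
    coords = np.asarray(boundary.exterior.coords)
    spacing = point_spacing
    if spacing is None:
        spacing = float(np.linalg.norm(np.diff(coords, axis=0), axis=1).mean())
    # the envelope must resolve finer than the saddle scale even when the
    # boundary polygon is sparse
    span = float(np.ptp(coords[:, 0]))
    bin_width = min(spacing, span / 10.0) if span > 0 else spacing
    env = upper_envelope(boundary, bin_width=bin_width)
    if len(env) < 3:
        return []
    simp = douglas_peucker(env, dp_factor * spacing)
    out = []
    for i in range(1, len(simp) - 1):
        if simp[i, 1] < simp[i - 1, 1] and simp[i, 1] < simp[i + 1, 1]:
            out.append(float(simp[i, 0]))
    return out


def forced_split(
    segment: TreeSegment, dp_factor: float = 5.0, alpha_radius: float | None = None
) -> list[np.ndarray] | None:
    """Cut a suspect segment at envelope saddles.

    Returns member-index partitions (positions within the segment) cut by
    vertical planes through the saddles of the facade with more saddles, or
    ``None`` when no saddle exists in either facade (the whole segment then
    belongs in the residual set).
    """
    if segment.mbr is None or len(segment.points) < 4:
        return None
    proj_long, proj_short = facade_projection(segment)
    cuts = []
    for proj in (proj_long, proj_short):
        try:
            boundary = boundary_trace(proj, alpha_radius)
            d, _ = cKDTree(proj).query(proj, k=2)
            spacing = float(d[:, 1].mean())
            cuts.append(
                simplify_and_find_inflections(boundary, dp_factor, spacing)
            )
        except ValueError:
            cuts.append([])
    which = 0 if len(cuts[0]) >= len(cuts[1]) else 1
    if not cuts[which]:
        return None
    coords = (proj_long, proj_short)[which][:, 0]
    edges = np.concatenate([[-np.inf], np.sort(cuts[which]), [np.inf]])
    parts = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = np.flatnonzero((coords > lo) & (coords <= hi))
        if len(m):
            parts.append(m)
    return parts if len(parts) >= 2 else None


@dataclass
class NscpResult:
    """Outcome of the full postprocessing pass."""

    candidates: list[TreeSegment]
    noise_indices: np.ndarray  # stratum indices judged noise
    log: list[str] = field(default_factory=list)


def backward_allocate(
    residual_points: np.ndarray,
    candidates: list[TreeSegment],
    k_radius: int = 3,
) -> np.ndarray:
    """Assign each residual point to a candidate tree or to noise.

    Returns an array of candidate positions (index into ``candidates``) with
    -1 for noise.  Rule per point: direct merge when the nearest candidate
    centroid is closer than that candidate's crown radius; otherwise a
    majority vote (>50%) over candidate member points within the mean crown
    radius of the three nearest candidates; otherwise noise.
    """
    residual_points = np.asarray(residual_points, dtype=float)
    m = len(residual_points)
    out = np.full(m, -1, dtype=int)
    if not candidates or m == 0:
        return out
    cent = np.array([(c.centroid[0], c.centroid[1]) for c in candidates])
    radii = np.array([c.crown_radius for c in candidates])
    cent_tree = cKDTree(cent)
    member_xy = np.vstack([c.points[:, :2] for c in candidates])
    member_owner = np.concatenate(
        [np.full(len(c.points), i) for i, c in enumerate(candidates)]
    )
    member_tree = cKDTree(member_xy)
    kq = min(k_radius, len(candidates))
    d_all, nn_all = cent_tree.query(residual_points[:, :2], k=len(candidates))
    if len(candidates) == 1:
        d_all = d_all[:, None]
        nn_all = nn_all[:, None]
    for i in range(m):
        dists = d_all[i]
        order = nn_all[i]
        jmin = order[0]
        if dists[0] < radii[jmin]:
            out[i] = jmin
            continue
        thr = float(np.mean(radii[order[:kq]]))
        local = member_tree.query_ball_point(residual_points[i, :2], thr)
        if not local:
            continue
        owners = member_owner[local]
        vals, cnts = np.unique(owners, return_counts=True)
        top = int(np.argmax(cnts))
        if cnts[top] / len(owners) > 0.5:
            out[i] = int(vals[top])
    return out


def postprocess(
    segments: list[TreeSegment],
    seed: int = 0,
    rules: CandidateRules | None = None,
    dp_factor: float = 5.0,
    alpha_radius: float | None = None,
    max_split_depth: int = 3,
) -> NscpResult:
    """Full repair pass: filter, forced-split suspects, backward-allocate.

    Point conservation holds: every input point ends in exactly one candidate
    or in the noise set.
    """
    rules = rules or CandidateRules()
    candidates, suspects, num_mean = filter_candidates(segments, seed, rules)
    if not candidates and not suspects:
        raise ValueError("no segments to postprocess")
    log = [
        f"filter: {len(candidates)} candidates, {len(suspects)} suspects, "
        f"num_mean={num_mean:.1f}"
    ]
    if not candidates:
        raise ValueError("no candidate trees at all; aborting postprocessing")

    residual_idx: list[np.ndarray] = []
    residual_pts: list[np.ndarray] = []
    counts = [num_mean]

    queue = [(seg, 0) for seg in suspects]
    while queue:
        seg, depth = queue.pop()
        if depth > 0 and passes_rules(seg, float(np.mean(counts)), rules):
            seg.candidate = True
            candidates.append(seg)
            counts.append(seg.n_points)
            log.append(f"split-accept: segment of {seg.n_points} points")
            continue
        parts = (
            forced_split(seg, dp_factor, alpha_radius)
            if depth < max_split_depth
            else None
        )
        if parts is None:
            residual_idx.append(seg.indices)
            residual_pts.append(seg.points)
            log.append(f"residual: segment of {seg.n_points} points")
            continue
        log.append(f"split: segment of {seg.n_points} points -> {len(parts)} parts")
        for p in parts:
            queue.append(
                (make_segment(-1, seg.indices[p], seg.points[p]), depth + 1)
            )

    if residual_idx:
        res_idx = np.concatenate(residual_idx)
        res_pts = np.vstack(residual_pts)
        assign = backward_allocate(res_pts, candidates)
        new_candidates = []
        for i, c in enumerate(candidates):
            mask = assign == i
            if mask.any():
                idx = np.concatenate([c.indices, res_idx[mask]])
                pts = np.vstack([c.points, res_pts[mask]])
                new_candidates.append(make_segment(i, idx, pts))
            else:
                new_candidates.append(make_segment(i, c.indices, c.points))
        noise = res_idx[assign < 0]
        log.append(
            f"backward allocation: {int((assign >= 0).sum())} merged, "
            f"{len(noise)} noise"
        )
        candidates = new_candidates
    else:
        noise = np.empty(0, dtype=int)
        candidates = [
            make_segment(i, c.indices, c.points) for i, c in enumerate(candidates)
        ]
    for c in candidates:
        c.candidate = True
    return NscpResult(candidates, noise, log)
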