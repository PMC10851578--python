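"""Candidate filtering, forced facade splitting and backward allocation."""

import numpy as np
import pytest
from shapely.geometry import Polygon

from understory.nscp import (
    CandidateRules,
    aspect_ok,
    backward_allocate,
    boundary_trace,
    bootstrap_num_mean,
    facade_projection,
    filter_candidates,
    forced_split,
    passes_rules,
    postprocess,
    simplify_and_find_inflections,
)
from understory.overstory import make_segment
from understory.synthetic import sample_tree


def _crown_segment(specs, density=60.0, seed=0, above=5.0):
    rng = np.random.default_rng(seed)
    pts = np.vstack([
        sample_tree("cone", (x, y), h, r, density, rng) for x, y, h, r in specs
    ])
    pts = pts[pts[:, 2] > above]
    return make_segment(0, np.arange(len(pts)), pts)


def test_all_rules_pass_for_clean_crown():
    seg = _crown_segment([(0, 0, 16, 2.0)])
    assert passes_rules(seg, num_mean=seg.n_points, rules=CandidateRules())


def test_aspect_boundaries_are_strict():
    assert not aspect_ok(1.3)
    assert not aspect_ok(0.7)
    assert aspect_ok(0.95)


def test_low_count_segment_rejected():
    seg = _crown_segment([(0, 0, 16, 2.0)])
    assert not passes_rules(seg, num_mean=4 * seg.n_points, rules=CandidateRules())


def test_merged_double_crown_routed_to_suspects():
    """Two crowns in one segment give an elongated MBR (aspect < 0.7)."""
    merged = _crown_segment([(0, 0, 16, 2.0), (4.5, 0, 17, 2.0)])
    single = _crown_segment([(10, 10, 16, 2.0)], seed=1)
    assert merged.mbr.aspect < 0.7
    candidates, suspects, _ = filter_candidates([single, merged], seed=0)
    assert merged in suspects
    assert single in candidates


def test_filter_requires_segments():
    with pytest.raises(ValueError):
        filter_candidates([], seed=0)


def test_bootstrap_num_mean_is_seeded():
    segs = [_crown_segment([(0, 0, 14 + i, 1.8)], seed=i) for i in range(5)]
    assert bootstrap_num_mean(segs, seed=3) == bootstrap_num_mean(segs, seed=3)


def test_facade_projection_axis_aligned():
    rng = np.random.default_rng(0)
    pts = np.column_stack([
        rng.uniform(0, 8, 300), rng.uniform(0, 2, 300), rng.uniform(6, 15, 300)
    ])
    seg = make_segment(0, np.arange(300), pts)
    proj_long, proj_short = facade_projection(seg)
    # long side is x: the long projection's first axis spans the x extent
    assert np.ptp(proj_long[:, 0]) == pytest.approx(np.ptp(pts[:, 0]), rel=0.02)
    assert np.ptp(proj_short[:, 0]) == pytest.approx(np.ptp(pts[:, 1]), rel=0.05)
    assert np.array_equal(proj_long[:, 1], pts[:, 2])
    assert len(proj_long) == len(proj_short) == 300


def test_facade_extent_equals_mbr_sides_under_rotation():
    rng = np.random.default_rng(1)
    base = np.column_stack([
        rng.uniform(0, 6, 400), rng.uniform(0, 3, 400), rng.uniform(6, 12, 400)
    ])
    theta = np.deg2rad(30)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    rotated = base.copy()
    rotated[:, :2] = base[:, :2] @ rot.T
    for pts in (base, rotated):
        seg = make_segment(0, np.arange(len(pts)), pts)
        proj_long, proj_short = facade_projection(seg)
        assert np.ptp(proj_long[:, 0]) == pytest.approx(seg.mbr.long_side, rel=0.01)
        assert np.ptp(proj_short[:, 0]) == pytest.approx(seg.mbr.short_side, rel=0.01)


def test_boundary_square_corners():
    square = np.array([[0, 0], [1, 0], [1, 1], [0, 1.0]])
    poly = boundary_trace(square, alpha_radius=5.0)
    assert poly.area == pytest.approx(1.0)


def test_boundary_equals_hull_for_large_alpha(rng):
    pts = rng.uniform(0, 4, (200, 2))
    from shapely.geometry import MultiPoint

    poly = boundary_trace(pts, alpha_radius=100.0)
    hull = MultiPoint(pts).convex_hull
    assert poly.area == pytest.approx(hull.area, rel=1e-3)


def test_bimodal_silhouette_has_concave_notch():
    """A two-lobed crown silhouette must trace a boundary with less area
    than its convex hull (the saddle notch)."""
    seg = _crown_segment([(0, 0, 16, 2.0), (4.5, 0, 16, 2.0)], density=80.0)
    proj_long, _ = facade_projection(seg)
    poly = boundary_trace(proj_long)
    from shapely.geometry import MultiPoint

    hull = MultiPoint(proj_long).convex_hull
    assert poly.area < 0.97 * hull.area


def test_monotone_envelope_has_no_inflection():
    tri = Polygon([(0, 0), (5, 10), (10, 0)])
    assert simplify_and_find_inflections(tri) == []


def test_w_shaped_envelope_inflection_position():
    w = Polygon([(0, 0), (1.5, 8), (3, 4), (4.5, 8), (6, 0)])
    infl = simplify_and_find_inflections(w, dp_factor=0.1)
    assert len(infl) == 1
    assert infl[0] == pytest.approx(3.0, abs=0.5)


def test_forced_split_none_without_inflection():
    seg = _crown_segment([(0, 0, 16, 2.0)])
    assert forced_split(seg) is None


def test_forced_split_partitions_merged_pair():
    seg = _crown_segment([(0, 0, 18, 2.0), (3.5, 0, 16, 1.8)])
    parts = forced_split(seg)
    assert parts is not None and len(parts) == 2
    joined = np.sort(np.concatenate(parts))
    assert np.array_equal(joined, np.arange(seg.n_points))


def test_forced_split_recovers_truth_stems():
    rng = np.random.default_rng(5)
    a = sample_tree("cone", (0, 0), 18, 2.0, 70, rng)
    b = sample_tree("cone", (3.5, 0), 16, 1.8, 70, rng)
    pts = np.vstack([a, b])
    keep = pts[:, 2] > 5
    seg = make_segment(0, np.arange(keep.sum()), pts[keep])
    parts = forced_split(seg)
    assert parts is not None
    subs = [make_segment(i, p, seg.points[p]) for i, p in enumerate(parts)]
    stems = sorted(s.stem[0] for s in subs)
    assert stems[0] == pytest.approx(0.0, abs=0.5)
    assert stems[1] == pytest.approx(3.5, abs=0.5)
    num_mean = np.mean([s.n_points for s in subs])
    assert all(passes_rules(s, num_mean, CandidateRules()) for s in subs)


def _toy_candidates():
    """Four compact candidate trees on a 10 m square."""
    segs = []
    rng = np.random.default_rng(2)
    for i, (x, y) in enumerate([(0, 0), (10, 0), (0, 10), (10, 10)]):
        pts = np.column_stack([
            x + rng.normal(0, 0.8, 120), y + rng.normal(0, 0.8, 120),
            rng.uniform(8, 15, 120),
        ])
        segs.append(make_segment(i, np.arange(120), pts))
    return segs


def test_backward_allocation_three_rules():
    cands = _toy_candidates()
    residual = np.array([
        [0.5, 0.0, 9.0],     # P1: within crown radius of tree 0 -> merge
        [2.5, 0.0, 9.0],     # P2: outside radii, local set dominated by tree 0
        [5.0, 5.0, 9.0],     # P3: empty local set -> noise
    ])
    assign = backward_allocate(residual, cands)
    assert assign[0] == 0
    assert assign[1] == 0
    assert assign[2] == -1


def test_backward_allocation_matches_bruteforce(rng):
    cands = _toy_candidates()
    residual = np.column_stack([
        rng.uniform(-2, 12, 60), rng.uniform(-2, 12, 60), rng.uniform(8, 15, 60)
    ])
    assign = backward_allocate(residual, cands)
    cent = np.array([(c.centroid[0], c.centroid[1]) for c in cands])
    radii = np.array([c.crown_radius for c in cands])
    for i, p in enumerate(residual):
        d = np.hypot(cent[:, 0] - p[0], cent[:, 1] - p[1])
        j = int(np.argmin(d))
        if d[j] < radii[j]:
            assert assign[i] == j
            continue
        thr = radii[np.argsort(d)[:3]].mean()
        votes = {}
        for k, c in enumerate(cands):
            dd = np.hypot(c.points[:, 0] - p[0], c.points[:, 1] - p[1])
            votes[k] = int((dd < thr).sum())
        total = sum(votes.values())
        if total == 0:
            assert assign[i] == -1
        else:
            best = max(votes, key=votes.get)
            if votes[best] / total > 0.5:
                assert assign[i] == best
            else:
                assert assign[i] == -1


def test_backward_allocation_no_candidates():
    residual = np.random.default_rng(0).uniform(0, 5, (10, 3))
    assert (backward_allocate(residual, []) == -1).all()


def test_postprocess_conserves_points():
    clean = [_crown_segment([(i * 8.0, 0, 16, 2.0)], seed=i) for i in range(4)]
    merged = _crown_segment([(0, 20, 18, 2.0), (3.5, 20, 16, 1.8)], seed=9)
    total = sum(s.n_points for s in clean) + merged.n_points
    result = postprocess(clean + [merged], seed=0)
    allocated = sum(c.n_points for c in result.candidates)
    assert allocated + len(result.noise_indices) == total


def test_postprocess_reentrant_on_clean_result():
    clean = [_crown_segment([(i * 8.0, 0, 16, 2.0)], seed=i) for i in range(4)]
    result = postprocess(clean, seed=0)
    again = postprocess(result.candidates, seed=0)
    assert len(again.candidates) == len(result.candidates)
    first = {frozenset(c.indices.tolist()) for c in result.candidates}
    second = {frozenset(c.indices.tolist()) for c in again.candidates}
    assert first == second
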