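"""Seed detection, adaptive bandwidths and mean-shift sapling delineation."""

import numpy as np
import pytest

from understory.containers import Raster
from understory.saplings import (
    SeedPoint,
    bandwidth,
    calibrate_seeds,
    crown_boundary,
    detect_seeds,
    extract_phenotypes,
    local_density,
    mean_shift,
    segment_saplings,
)


def _bump_chm(centers, radius=0.5, height=2.0, res=0.05, extent=10.0):
    """CHM with radially symmetric conical bumps (no-data in gaps)."""
    n = int(extent / res)
    grid = np.full((n, n), np.nan)
    xs = (np.arange(n) + 0.5) * res
    X, Y = np.meshgrid(xs, xs)
    for cx, cy in centers:
        d = np.hypot(X - cx, Y - cy)
        inside = d <= radius
        vals = height * (1 - d / radius)
        grid[inside] = np.fmax(
            np.where(np.isnan(grid[inside]), -np.inf, grid[inside]), vals[inside]
        )
    return Raster(grid, (0.0, 0.0), res)


def test_single_bump_single_seed():
    chm = _bump_chm([(5.0, 5.0)])
    seeds = detect_seeds(chm)
    assert len(seeds) == 1
    assert seeds[0].x == pytest.approx(5.0, abs=0.1)
    assert seeds[0].y == pytest.approx(5.0, abs=0.1)


def test_flat_chm_no_seeds():
    chm = Raster(np.ones((50, 50)) * 0.1, (0, 0), 0.05)
    assert detect_seeds(chm) == []  # below the 0.3 m grass cut
    chm_nodata = Raster(np.full((50, 50), np.nan), (0, 0), 0.05)
    assert detect_seeds(chm_nodata) == []


def test_seed_count_matches_truth_in_gaps(open_stand):
    from understory.extraction import build_chm
    from understory.ground import normalize

    norm = normalize(open_stand.cloud)
    pts = norm.xyz[norm.z > 0]
    chm = build_chm(pts, resolution=0.05)
    seeds = detect_seeds(chm)
    n_truth = (open_stand.inventory["layer"] == "sapling").sum()
    assert abs(len(seeds) - n_truth) <= 0.1 * n_truth


def test_local_density_four_neighbors():
    seeds = np.array([[0, 0], [2, 0], [-2, 0], [0, 2], [0, -2.0]])
    assert local_density(seeds[0], seeds, k=4) == pytest.approx(2.0)


def test_local_density_grid_interior():
    xs = np.arange(0, 10, 2.0)
    grid = np.array([(x, y) for x in xs for y in xs])
    center = np.array([4.0, 4.0])
    assert local_density(center, grid, k=4) == pytest.approx(2.0)


def test_local_density_matches_bruteforce(rng):
    seeds = rng.uniform(0, 20, (30, 2))
    for i in range(5):
        d = np.hypot(*(seeds - seeds[i]).T)
        expected = np.sort(d[d > 1e-12])[:4].mean()
        assert local_density(seeds[i], seeds, k=4) == pytest.approx(expected)


def test_single_seed_falls_back_with_warning():
    with pytest.warns(UserWarning):
        sd = local_density(np.array([0.0, 0.0]), np.array([[0.0, 0.0]]))
    assert sd == 2.0


def test_crown_boundary_radius_symmetric_bump():
    chm = _bump_chm([(5.0, 5.0)], radius=0.5)
    seed = detect_seeds(chm)[0]
    _, radius = crown_boundary(chm, seed)
    assert radius == pytest.approx(0.5, abs=2 * chm.resolution + 0.05)


def test_adjacent_bumps_stop_at_saddle():
    chm = _bump_chm([(4.0, 5.0), (5.4, 5.0)], radius=0.8)
    seeds = sorted(detect_seeds(chm, min_distance=0.5), key=lambda s: s.x)
    assert len(seeds) == 2
    for s in seeds:
        _, radius = crown_boundary(chm, s)
        assert radius <= 1.0  # bounded by the shared saddle, not 2 crowns


def test_bandwidth_formula():
    assert bandwidth(1.0, 2.0, partial=0.5) == pytest.approx(0.25)
    assert bandwidth(2.0, 2.0, partial=0.5) == pytest.approx(2 * 0.25)
    with pytest.raises(ValueError):
        bandwidth(1.0, 2.0, partial=0.0)
    with pytest.raises(ValueError):
        bandwidth(1.0, 0.0)


def _seed(x, y, h=0.5):
    return SeedPoint(x, y, 2.0, sd=2.0, radius=0.5, bandwidth=h)


def test_mean_shift_fixed_point_at_point_mass():
    pts = np.tile([[1.0, 2.0, 0.5]], (10, 1))
    labels = mean_shift(pts, [_seed(1.0, 2.0)])
    assert (labels == 0).all()


def test_mean_shift_two_separated_blobs(rng):
    a = rng.normal(0, 0.05, (40, 3)) + [0, 0, 1]
    b = rng.normal(0, 0.05, (40, 3)) + [5, 0, 1]
    pts = np.vstack([a, b])
    labels = mean_shift(pts, [_seed(0, 0), _seed(5, 0)])
    assert len(np.unique(labels[labels >= 0])) == 2
    assert len(np.unique(labels[:40])) == 1
    assert len(np.unique(labels[40:])) == 1


def test_mean_shift_modes_near_truth_stems(rng):
    stems = [(0.0, 0.0), (3.0, 0.0), (0.0, 3.0), (3.0, 3.0)]
    pts = np.vstack([
        np.column_stack([
            rng.normal(sx, 0.2, 60), rng.normal(sy, 0.2, 60),
            rng.uniform(0.2, 1.5, 60),
        ])
        for sx, sy in stems
    ])
    seeds = [_seed(sx, sy, h=0.4) for sx, sy in stems]
    labels = mean_shift(pts, seeds)
    assert len(np.unique(labels[labels >= 0])) == 4
    for i, (sx, sy) in enumerate(stems):
        members = pts[labels == labels[i * 60]]
        assert np.hypot(members[:, 0].mean() - sx, members[:, 1].mean() - sy) < 0.2


def test_mean_shift_cluster_count_not_increasing_in_bandwidth(rng):
    pts = np.column_stack([
        rng.normal(0, 0.3, 80), rng.normal(0, 0.3, 80), rng.uniform(0, 1, 80)
    ])
    n1 = len(np.unique(mean_shift(pts, [_seed(0, 0, 0.3)])))
    n2 = len(np.unique(mean_shift(pts, [_seed(0, 0, 0.6)])))
    assert n2 <= n1


def test_every_point_clustered_or_noise(rng):
    pts = np.column_stack([
        rng.uniform(0, 6, 200), rng.uniform(0, 6, 200), rng.uniform(0, 2, 200)
    ])
    labels = mean_shift(pts, [_seed(2, 2), _seed(4, 4)])
    assert len(labels) == len(pts)
    assert (labels >= -1).all()


def test_mean_shift_requires_bandwidths():
    with pytest.raises(ValueError):
        mean_shift(np.zeros((3, 3)), [SeedPoint(0, 0, 1.0)])
    with pytest.raises(ValueError):
        mean_shift(np.empty((0, 3)), [_seed(0, 0)])


def test_extract_phenotypes_extents():
    pts = np.array([
        [0.0, 0.0, 1.0], [2.0, 0.0, 1.2], [1.0, 1.0, 2.5], [1.0, -0.0, 0.8]
    ])
    rec = extract_phenotypes(pts)
    assert rec.crown_width == pytest.approx(0.5 * (2.0 + 1.0))
    assert rec.height == 2.5
    assert (rec.x, rec.y) == (1.0, 1.0)


def test_extract_phenotypes_single_point():
    rec = extract_phenotypes(np.array([[1.0, 2.0, 0.7]]))
    assert rec.crown_width == 0.0
    assert rec.height == pytest.approx(0.7)
    with pytest.raises(ValueError):
        extract_phenotypes(np.empty((0, 3)))


def test_phenotype_height_tracks_truth_minus_leader(open_stand):
    """Detected sapling heights sit a leader-shoot offset below truth."""
    from understory import run_on_stand

    res = run_on_stand(open_stand)
    det = res.sapling_table
    inv = open_stand.inventory
    ref = inv[inv["layer"] == "sapling"].reset_index(drop=True)
    from understory.evaluate import match

    pairs = match(ref[["x", "y", "height"]], det)
    dh = (
        det.loc[pairs["det_index"], "height"].to_numpy()
        - ref.loc[pairs["ref_index"], "height"].to_numpy()
    )
    offset = open_stand.config.leader_shoot
    assert np.median(np.abs(dh + offset)) <= 0.1


def test_calibrate_seeds_fills_bandwidths():
    chm = _bump_chm([(3.0, 3.0), (6.0, 3.0), (3.0, 6.0), (6.0, 6.0), (5.0, 8.0)])
    seeds = detect_seeds(chm, min_distance=0.5)
    calibrate_seeds(chm, seeds, partial=0.5)
    for s in seeds:
        assert np.isfinite(s.bandwidth) and s.bandwidth > 0
        assert s.bandwidth >= 0.3  # floored


def test_segment_saplings_empty_chm():
    chm = Raster(np.full((20, 20), np.nan), (0, 0), 0.05)
    records, labels = segment_saplings(np.zeros((5, 3)), chm)
    assert records == []
    assert (labels == -1).all()
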