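"""Matching, accuracy rates, regression statistics and canopy closure."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from understory.containers import Raster
from understory.evaluate import (
    MatchConfig,
    canopy_closure,
    commission_rate,
    evaluate_detection,
    match,
    position_error,
    rates,
    regression_stats,
    resample_max,
)


def _frame(rows):
    return pd.DataFrame(rows, columns=["x", "y", "height"])


def test_match_within_both_thresholds():
    ref = _frame([(0.0, 0.0, 2.0)])
    det = _frame([(0.5, 0.0, 2.3)])
    assert len(match(ref, det)) == 1


def test_match_distance_rule():
    ref = _frame([(0.0, 0.0, 2.0)])
    det = _frame([(1.2, 0.0, 2.0)])
    assert len(match(ref, det)) == 0


def test_match_height_rule():
    ref = _frame([(0.0, 0.0, 2.0)])
    det = _frame([(0.5, 0.0, 4.0)])
    assert len(match(ref, det)) == 0


def test_match_picks_minimum_height_difference():
    ref = _frame([(0.0, 0.0, 2.0)])
    det = _frame([(0.5, 0.0, 3.0), (0.4, 0.1, 2.1)])
    pairs = match(ref, det)
    assert list(pairs["det_index"]) == [1]


def test_match_is_one_to_one():
    ref = _frame([(0.0, 0.0, 2.0), (0.3, 0.0, 2.1)])
    det = _frame([(0.1, 0.0, 2.05)])
    pairs = match(ref, det)
    assert len(pairs) == 1


def _bruteforce_match(ref, det, cfg):
    """Enumerate all one-to-one assignments; maximize count, minimize sum|dh|."""
    feasible = {}
    for i, r in ref.iterrows():
        for j, d in det.iterrows():
            if (
                np.hypot(r.x - d.x, r.y - d.y) <= cfg.radius
                and abs(r.height - d.height) <= cfg.height_tolerance
            ):
                feasible[(i, j)] = abs(r.height - d.height)
    best = (0, 0.0, frozenset())
    ref_ids = list(ref.index)

    def assignments(pos, used, pairs):
        nonlocal best
        if pos == len(ref_ids):
            n = len(pairs)
            cost = sum(feasible[p] for p in pairs)
            if n > best[0] or (n == best[0] and cost < best[1]):
                best = (n, cost, frozenset(pairs))
            return
        i = ref_ids[pos]
        assignments(pos + 1, used, pairs)
        for j in det.index:
            if j not in used and (i, j) in feasible:
                assignments(pos + 1, used | {j}, pairs + [(i, j)])

    assignments(0, set(), [])
    return best


def test_match_equals_exhaustive_assignment(rng):
    cfg = MatchConfig()
    for trial in range(5):
        ref = _frame(
            np.column_stack([
                rng.uniform(0, 6, 7), rng.uniform(0, 6, 7), rng.uniform(1, 3, 7)
            ])
        )
        det = _frame(
            np.column_stack([
                rng.uniform(0, 6, 8), rng.uniform(0, 6, 8), rng.uniform(1, 3, 8)
            ])
        )
        pairs = match(ref, det, cfg)
        n_best, cost_best, _ = _bruteforce_match(ref, det, cfg)
        assert len(pairs) == n_best
        assert pairs["dh"].sum() == pytest.approx(cost_best, abs=1e-9)


def test_rates_perfect():
    assert rates(100, 100, 100) == pytest.approx((100.0, 100.0, 0.0))


def test_rates_arithmetic():
    r_det, r_mat, r_com = rates(10, 8, 7)
    assert (r_det, r_mat) == (80.0, 70.0)
    assert r_com == pytest.approx(12.5)


def test_rates_zero_detections_has_no_commission():
    r_det, r_mat, r_com = rates(10, 0, 0)
    assert r_det == 0.0 and np.isnan(r_com)


def test_rates_input_validation():
    with pytest.raises(ValueError):
        rates(0, 5, 2)
    with pytest.raises(ValueError):
        rates(10, 5, 7)


def test_commission_identity_on_reported_overall_rates():
    # overall detection 121.03% and matching 82.08% imply commission 32.18%
    assert round(commission_rate(121.03, 82.08), 2) == 32.18


@settings(max_examples=50, deadline=None)
@given(
    n_ref=st.integers(1, 200),
    n_det=st.integers(1, 200),
    frac=st.floats(0, 1),
)
def test_commission_identity_property(n_ref, n_det, frac):
    n_mat = int(frac * min(n_ref, n_det))
    r_det, r_mat, r_com = rates(n_ref, n_det, n_mat)
    assert r_com == pytest.approx(100.0 * (1 - r_mat / r_det), abs=1e-9)


def test_regression_exact_and_bias():
    ref = np.array([1.0, 2.0, 3.0, 4.0])
    stats = regression_stats(ref, ref)
    assert stats["r_squared"] == pytest.approx(1.0)
    assert stats["rmse"] == pytest.approx(0.0)
    stats = regression_stats(ref, ref + 0.5)
    assert stats["r_squared"] == pytest.approx(1.0)
    assert stats["rmse"] == pytest.approx(0.5)


def test_regression_rmse_matches_noise_sigma(rng):
    ref = rng.uniform(1, 3, 3000)
    det = ref + rng.normal(0, 0.2, 3000)
    stats = regression_stats(ref, det)
    assert stats["rmse"] == pytest.approx(0.2, rel=0.1)


def test_regression_constant_reference():
    stats = regression_stats([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
    assert np.isnan(stats["r_squared"])


def test_closure_half_and_zero():
    chm = Raster(np.array([[6.0, 6.0], [2.0, 2.0]]), (0, 0), 1.0)
    assert canopy_closure(chm) == pytest.approx(0.5)
    low = Raster(np.full((4, 4), 2.0), (0, 0), 1.0)
    assert canopy_closure(low) == 0.0


def test_closure_monotone_in_height_cut():
    rng = np.random.default_rng(0)
    chm = Raster(rng.uniform(0, 20, (40, 40)), (0, 0), 0.5)
    cuts = [8.0, 5.0, 2.0]
    closures = [canopy_closure(chm, height_cut=c) for c in cuts]
    assert closures[0] <= closures[1] <= closures[2]


def test_closure_max_resampling():
    data = np.array([[6.0, 1.0], [1.0, 1.0]])
    chm = Raster(data, (0, 0), 1.0)
    # max rule: the 2 m cell keeps the 6 m crown pixel
    assert canopy_closure(chm, scale=2.0) == pytest.approx(1.0)
    r = resample_max(chm, 2.0)
    assert r.shape == (1, 1) and r.data[0, 0] == 6.0


def test_closure_all_nodata_raises():
    with pytest.raises(ValueError):
        canopy_closure(Raster(np.full((3, 3), np.nan), (0, 0), 1.0))


def test_stand_closure_measured_from_chm(closed_stand, closed_stand_normalized):
    from understory.extraction import build_chm
    from understory.overstory import stratify

    norm = closed_stand_normalized
    pts = norm.xyz  # include ground cells so gaps count as open area
    ex, ey = closed_stand.config.extent_m
    chm = build_chm(pts[norm.z >= 0], resolution=0.5, bounds=(0, 0, ex, ey),
                    fill_radius=0.0)
    measured = canopy_closure(chm)
    assert abs(measured - closed_stand.closure) <= 0.1


def test_position_error_cases():
    ref = _frame([(0.0, 0.0, 2.0)])
    det = _frame([(0.3, 0.4, 2.0)])
    pairs = match(ref, det)
    pe = position_error(ref, det, pairs)
    assert pe["mean"] == pytest.approx(0.5)
    same = position_error(ref, ref, match(ref, ref))
    assert same["mean"] == 0.0


def test_evaluate_detection_report(rng):
    ref = _frame(
        np.column_stack([
            rng.uniform(0, 20, 30), rng.uniform(0, 20, 30), rng.uniform(1, 3, 30)
        ])
    )
    det = ref.copy()
    det["x"] += rng.normal(0, 0.1, 30)
    det["height"] += rng.normal(0, 0.05, 30)
    rep = evaluate_detection(ref, det)
    assert rep.n_mat == 30
    assert rep.r_det == pytest.approx(100.0)
    assert rep.r_com == pytest.approx(0.0, abs=1e-9)
    assert rep.height_stats["rmse"] < 0.1
    assert "detection rate" in rep.summary()
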