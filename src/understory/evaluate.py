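"""Detection scoring: reference matching, rate metrics, regressions, closure.

Detected trees are matched one-to-one to reference stems: a detected tree is
eligible for a reference when it lies within the horizontal radius (default
1 m) and its height differs by at most the height tolerance (default 1.5 m);
among eligible pairings the assignment maximizes the number of matches and,
among those, minimizes the total height difference.  Rates follow the
standard detection / matching / commission definitions:

    R_det = N_det / N_ref
    R_mat = N_mat / N_ref
    R_com = 1 - R_mat / R_det

Canopy closure is the fraction of CHM area above the 5 m height cut,
computed after max-rule resampling to an evaluation scale (0.5, 1 or 2 m).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import linregress

from .containers import Raster

_BIG = 1e9  # infeasible-pair cost; dominates any feasible total


@dataclass(frozen=True)
class MatchConfig:
    """Matching thresholds: horizontal radius and height tolerance (m)."""

    radius: float = 1.0
    height_tolerance: float = 1.5

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.height_tolerance <= 0:
            raise ValueError("matching thresholds must be positive")


def match(
    reference: pd.DataFrame,
    detected: pd.DataFrame,
    config: MatchConfig | None = None,
) -> pd.DataFrame:
    """One-to-one reference/detected matching.

    Both frames need columns ``x, y, height``.  Returns a frame with
    ``ref_index, det_index, dh, distance`` (absolute height difference and
    planar distance per matched pair).
    """
    cfg = config or MatchConfig()
    cols = ["ref_index", "det_index", "dh", "distance"]
    if len(reference) == 0 or len(detected) == 0:
        return pd.DataFrame(columns=cols)
    rx = reference[["x", "y"]].to_numpy(float)
    rh = reference["height"].to_numpy(float)
    dx = detected[["x", "y"]].to_numpy(float)
    dh = detected["height"].to_numpy(float)
    dist = np.hypot(rx[:, None, 0] - dx[None, :, 0], rx[:, None, 1] - dx[None, :, 1])
    delta = np.abs(rh[:, None] - dh[None, :])
    feasible = (dist <= cfg.radius) & (delta <= cfg.height_tolerance)
    if not feasible.any():
        return pd.DataFrame(columns=cols)
    cost = np.where(feasible, delta, _BIG)
    ri, ci = linear_sum_assignment(cost)
    keep = feasible[ri, ci]
    ri, ci = ri[keep], ci[keep]
    return pd.DataFrame(
        {
            "ref_index": reference.index.to_numpy()[ri],
            "det_index": detected.index.to_numpy()[ci],
            "dh": delta[ri, ci],
            "distance": dist[ri, ci],
        }
    )


def rates(n_ref: int, n_det: int, n_mat: int) -> tuple[float, float, float]:
    """Detection, matching and commission rates in percent.

    Commission is computed through the identity R_com = 1 - R_mat / R_det
    and is NaN when nothing was detected.
    """
    if n_ref <= 0:
        raise ValueError("reference count must be positive")
    if not (0 <= n_mat <= min(n_ref, n_det)):
        raise ValueError("matched count must satisfy 0 <= N_mat <= min(N_ref, N_det)")
    r_det = 100.0 * n_det / n_ref
    r_mat = 100.0 * n_mat / n_ref
    r_com = commission_rate(r_det, r_mat) if n_det > 0 else np.nan
    return r_det, r_mat, r_com


def commission_rate(detection_rate: float, matching_rate: float) -> float:
    """Commission rate (%) from detection and matching rates (%)."""
    if detection_rate <= 0:
        raise ValueError("detection rate must be positive")
    return 100.0 * (1.0 - matching_rate / detection_rate)


def regression_stats(reference, detected) -> dict:
    """OLS fit of detected on reference values: R^2, RMSE, slope, intercept.

    RMSE is of the raw differences (detected - reference), not fit residuals.
    R^2 is NaN for constant reference values.
    """
    ref = np.asarray(reference, dtype=float)
    det = np.asarray(detected, dtype=float)
    if len(ref) < 3 or len(ref) != len(det):
        raise ValueError("need at least 3 (reference, detected) pairs")
    rmse = float(np.sqrt(np.mean((det - ref) ** 2)))
    if np.ptp(ref) < 1e-12:
        return dict(r_squared=np.nan, rmse=rmse, slope=np.nan, intercept=np.nan)
    res = linregress(ref, det)
    return dict(
        r_squared=float(res.rvalue**2),
        rmse=rmse,
        slope=float(res.slope),
        intercept=float(res.intercept),
    )


def resample_max(raster: Raster, scale: float) -> Raster:
    """Max-rule resampling to a coarser cell size (occupancy-preserving)."""
    if scale < raster.resolution:
        raise ValueError("target scale must be >= source resolution")
    block = max(1, int(round(scale / raster.resolution)))
    nrows, ncols = raster.shape
    pr = (-nrows) % block
    pc = (-ncols) % block
    data = np.pad(raster.data, ((0, pr), (0, pc)), constant_values=np.nan)
    view = data.reshape(data.shape[0] // block, block, data.shape[1] // block, block)
    with np.errstate(all="ignore"):
        out = np.nanmax(view, axis=(1, 3))
    return Raster(out, raster.origin, raster.resolution * block)


def canopy_closure(
    chm: Raster, height_cut: float = 5.0, scale: float | None = None
) -> float:
    """Fraction of valid CHM cells whose height exceeds the cut."""
    r = resample_max(chm, scale) if scale and scale > chm.resolution else chm
    valid = r.valid_mask()
    if not valid.any():
        raise ValueError("all-no-data CHM")
    return float((r.data[valid] > height_cut).mean())


def position_error(
    reference: pd.DataFrame, detected: pd.DataFrame, pairs: pd.DataFrame
) -> dict:
    """Planar stem-position errors of matched pairs: values, mean, std, max."""
    if len(pairs) == 0:
        return dict(errors=np.empty(0), mean=np.nan, std=np.nan, max=np.nan)
    rx = reference.loc[pairs["ref_index"], ["x", "y"]].to_numpy(float)
    dx = detected.loc[pairs["det_index"], ["x", "y"]].to_numpy(float)
    e = np.hypot(*(rx - dx).T)
    return dict(
        errors=e, mean=float(e.mean()), std=float(e.std()), max=float(e.max())
    )


@dataclass
class EvalReport:
    """Full accuracy report for one detection run."""

    n_ref: int
    n_det: int
    n_mat: int
    r_det: float
    r_mat: float
    r_com: float
    pairs: pd.DataFrame = field(repr=False)
    height_stats: dict | None = None
    width_stats: dict | None = None
    position: dict | None = None

    def summary(self) -> str:
        lines = [
            f"references: {self.n_ref}  detected: {self.n_det}  matched: {self.n_mat}",
            f"detection rate:  {self.r_det:.2f}%",
            f"matching rate:   {self.r_mat:.2f}%",
            f"commission rate: {self.r_com:.2f}%"
            if np.isfinite(self.r_com)
            else "commission rate: n/a",
        ]
        if self.height_stats:
            lines.append(
                f"height:  R2={self.height_stats['r_squared']:.3f} "
                f"RMSE={self.height_stats['rmse']:.3f} m"
            )
        if self.width_stats:
            lines.append(
                f"crown width: R2={self.width_stats['r_squared']:.3f} "
                f"RMSE={self.width_stats['rmse']:.3f} m"
            )
        if self.position:
            lines.append(
                f"position error: mean={self.position['mean']:.3f} m "
                f"max={self.position['max']:.3f} m"
            )
        return "\n".join(lines)


def evaluate_detection(
    reference: pd.DataFrame,
    detected: pd.DataFrame,
    config: MatchConfig | None = None,
) -> EvalReport:
    """Match and score a detection run against a reference inventory."""
    pairs = match(reference, detected, config)
    n_ref, n_det, n_mat = len(reference), len(detected), len(pairs)
    r_det, r_mat, r_com = rates(n_ref, n_det, n_mat)
    height_stats = width_stats = None
    if n_mat >= 3:
        rh = reference.loc[pairs["ref_index"], "height"].to_numpy(float)
        dh = detected.loc[pairs["det_index"], "height"].to_numpy(float)
        height_stats = regression_stats(rh, dh)
        if "crown_width" in detected.columns and (
            "crown_width" in reference.columns or "crown_radius" in reference.columns
        ):
            rw_col = (
                reference["crown_width"]
                if "crown_width" in reference.columns
                else 2.0 * reference["crown_radius"]
            )
            rw = rw_col.loc[pairs["ref_index"]].to_numpy(float)
            dw = detected.loc[pairs["det_index"], "crown_width"].to_numpy(float)
            width_stats = regression_stats(rw, dw)
    pos = position_error(reference, detected, pairs)
    return EvalReport(
        n_ref, n_det, n_mat, r_det, r_mat, r_com, pairs, height_stats, width_stats, pos
    )
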