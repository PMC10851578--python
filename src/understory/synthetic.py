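"""Synthetic two-layer stand generator.

Emulates the study system: a planted conifer overstory (heights well above
10 m) with canopy gaps, understory saplings (heights below 3.5 m) planted on
a near-regular grid, shrub/grass clutter in a 0-0.5 m band, and gently
undulating terrain.  Every point carries a truth label and every tree a truth
inventory record, so each pipeline stage can be scored against known answers
without external data.

Crown point sampling is uniform in the crown solid (cone or ellipsoid),
which thins naturally toward the apex.  Saplings carry a terminal
leader-shoot offset: the topmost ``leader_shoot`` meters of the recorded
tree height are supported by no points, mimicking the airborne scanner's
inability to sample the current-year vertical shoot.  An optional occlusion
model removes understory/ground points beneath crowns with probability
proportional to the overlying crown cover, which reproduces the qualitative
closure-versus-matching-rate effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .containers import (
    CLASS_UNCLASSIFIED,
    LAYER_CLUTTER,
    LAYER_GROUND,
    LAYER_OVERSTORY,
    LAYER_SAPLING,
    PointCloud,
    Raster,
)


@dataclass(frozen=True)
class StandConfig:
    """Stand layout and sampling parameters.

    Defaults describe the reference stand: ~50 x 50 m plots, larch-like
    overstory (12-22 m) over spruce-like saplings (1-3.5 m) planted with
    near-equal spacing, 243 pts/m^2 scanning density.
    """

    extent_m: tuple[float, float] = (50.0, 50.0)
    overstory_density: float | None = None  # stems/ha; None -> from closure target
    overstory_height_range: tuple[float, float] = (15.0, 20.0)  # same-aged plantation
    sapling_grid_spacing: float = 3.0
    sapling_height_range: tuple[float, float] = (1.0, 3.5)
    canopy_closure_target: float = 0.5
    clutter_density: float = 1.0  # shrub/grass points per m^2
    terrain_relief: float = 4.0  # max peak-to-trough relief, m
    point_density: float = 243.0  # pts/m^2 within crown footprints
    rng_seed: int = 0
    # secondary knobs (defaults are part of the study conditions)
    leader_shoot: float = 0.1  # sapling height not carried by points, m
    occlusion: bool = True
    occlusion_strength: float = 0.5
    ground_point_fraction: float = 0.25  # ground density = fraction * point_density
    dbh_slope: float = 0.013  # DBH = slope*height + intercept + N(0, sigma)
    dbh_intercept: float = 0.05
    dbh_sigma: float = 0.02
    overstory_crown_model: str = "cone"
    sapling_crown_model: str = "cone"

    def validate(self) -> None:
        if self.extent_m[0] <= 0 or self.extent_m[1] <= 0:
            raise ValueError("extent must be positive")
        if self.sapling_grid_spacing <= 0:
            raise ValueError("sapling grid spacing must be positive")
        if self.point_density <= 0:
            raise ValueError("point density must be positive")
        if self.clutter_density < 0:
            raise ValueError("clutter density must be non-negative")
        if not (0.0 <= self.canopy_closure_target < 1.0):
            raise ValueError("canopy closure target must be in [0, 1)")
        if self.overstory_height_range[0] <= 10.0:
            raise ValueError("overstory heights must exceed 10 m")
        if self.sapling_height_range[1] > 3.5:
            raise ValueError("sapling heights must not exceed 3.5 m")
        if self.sapling_height_range[0] <= 0:
            raise ValueError("sapling heights must be positive")
        if self.overstory_density is not None and self.overstory_density < 0:
            raise ValueError("overstory density must be non-negative")
        if self.terrain_relief < 0:
            raise ValueError("terrain relief must be non-negative")


class Terrain:
    """Smooth ground-elevation surface: a single long sinusoid.

    Peak-to-trough relief equals ``relief``; the maximum slope is bounded by
    ``pi * relief / wavelength`` with wavelength = the longer extent side.
    """

    def __init__(self, extent: tuple[float, float], relief: float, seed: int):
        rng = np.random.default_rng(seed)
        theta = rng.uniform(0, 2 * np.pi)
        self.direction = np.array([np.cos(theta), np.sin(theta)])
        self.phase = rng.uniform(0, 2 * np.pi)
        self.wavelength = max(extent)
        self.amplitude = relief / 2.0

    def __call__(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        s = x * self.direction[0] + y * self.direction[1]
        return self.amplitude * np.sin(2 * np.pi * s / self.wavelength + self.phase)


def generate_terrain(config: StandConfig) -> Terrain:
    """Build the deterministic ground surface for a stand configuration."""
    config.validate()
    return Terrain(config.extent_m, config.terrain_relief, config.rng_seed)


def sample_tree(
    crown_model: str,
    stem_xy: tuple[float, float],
    height: float,
    crown_radius: float,
    point_density: float,
    rng: np.random.Generator,
    ground_z: float = 0.0,
    crown_base_frac: float = 0.35,
    trunk_points_per_m: float = 10.0,
    top_offset: float = 0.0,
) -> np.ndarray:
    """Sample one tree's points: crown solid + trunk line + exact apex.

    ``top_offset`` lowers the highest sampled point below the nominal tree
    height (the leader-shoot effect); with offset 0 one point sits exactly at
    ``ground_z + height``.
    """
    if height <= 0 or crown_radius <= 0 or point_density <= 0:
        raise ValueError("height, crown radius and point density must be positive")
    if crown_model not in ("cone", "ellipsoid"):
        raise ValueError(f"unknown crown model: {crown_model}")
    x0, y0 = stem_xy
    top = ground_z + height - top_offset
    base = ground_z + crown_base_frac * height
    if top <= base:
        base = ground_z
    n = rng.poisson(point_density * np.pi * crown_radius**2)
    if crown_model == "cone":
        # uniform in a solid cone, apex up: P(t) ~ (1-t)^2
        t = 1.0 - (1.0 - rng.uniform(size=n)) ** (1.0 / 3.0)
        r_at = crown_radius * (1.0 - t)
        rho = np.sqrt(rng.uniform(size=n)) * r_at
        phi = rng.uniform(0, 2 * np.pi, size=n)
        z = base + t * (top - base)
        pts = np.column_stack([x0 + rho * np.cos(phi), y0 + rho * np.sin(phi), z])
    else:
        # uniform in an ellipsoid with semi-axes (r, r, (top-base)/2)
        g = rng.normal(size=(n, 3))
        g /= np.maximum(np.linalg.norm(g, axis=1, keepdims=True), 1e-12)
        g *= rng.uniform(size=(n, 1)) ** (1.0 / 3.0)
        c = 0.5 * (top - base)
        pts = np.column_stack(
            [
                x0 + crown_radius * g[:, 0],
                y0 + crown_radius * g[:, 1],
                base + c + c * g[:, 2],
            ]
        )
    # trunk returns below the crown base
    trunk_len = max(0.0, base - ground_z)
    m = rng.poisson(trunk_points_per_m * trunk_len)
    if m:
        tz = rng.uniform(ground_z, base, size=m)
        jig = rng.normal(0, 0.03, size=(m, 2))
        trunk = np.column_stack([x0 + jig[:, 0], y0 + jig[:, 1], tz])
        pts = np.vstack([pts, trunk])
    # top whorl: conifers carry a dense branch whorl right below the crown
    # top, so the top is supported by several returns (the leader shoot
    # above it is what the scanner misses, handled via top_offset)
    wn = rng.poisson(6.0)
    if wn:
        wr = rng.uniform(0, 0.1, size=wn)
        wphi = rng.uniform(0, 2 * np.pi, size=wn)
        wz = top - rng.uniform(0, 0.15, size=wn)
        whorl = np.column_stack(
            [x0 + wr * np.cos(wphi), y0 + wr * np.sin(wphi), wz]
        )
        pts = np.vstack([pts, whorl])
    # guarantee the crown top is sampled
    pts = np.vstack([pts, [x0, y0, top]])
    return pts


@dataclass
class StandResult:
    """Generated stand: labeled cloud, truth inventory, achieved closure."""

    cloud: PointCloud
    inventory: pd.DataFrame
    closure: float
    config: StandConfig
    terrain: Terrain = field(repr=False, default=None)  # type: ignore[assignment]


# mean crown radius used when deriving stem density from a closure target
_R_CROWN_COEF = 0.12


def _overstory_count(config: StandConfig, area: float) -> int:
    if config.overstory_density is not None:
        return int(round(config.overstory_density * area / 1e4))
    c = config.canopy_closure_target
    if c <= 0:
        return 0
    h_mean = 0.5 * sum(config.overstory_height_range)
    r_mean = _R_CROWN_COEF * h_mean
    # gridded plantation: near-disjoint crowns, coverage ~ n*pi*r^2/area
    return int(round(c * area / (np.pi * r_mean**2)))


def generate_stand(config: StandConfig) -> StandResult:
    """Generate the labeled point cloud and truth inventory for one stand."""
    config.validate()
    root = np.random.SeedSequence(config.rng_seed)
    ss_terrain, ss_over, ss_sap, ss_ground, ss_clutter, ss_occl = root.spawn(6)
    terrain = Terrain(
        config.extent_m, config.terrain_relief, config.rng_seed
    )
    ex, ey = config.extent_m
    area = ex * ey

    records = []
    clouds_xyz: list[np.ndarray] = []
    clouds_layer: list[np.ndarray] = []
    clouds_id: list[np.ndarray] = []
    tree_id = 0

    # ---- overstory: jittered planting grid (rows and columns) ------------
    n_over = _overstory_count(config, area)
    grid_sites: list[tuple[float, float]] = []
    if n_over > 0:
        s_over = float(np.sqrt(area / n_over))
        for gy in np.arange(s_over / 2, ey, s_over):
            for gx in np.arange(s_over / 2, ex, s_over):
                grid_sites.append((gx, gy))
    n_over = len(grid_sites)
    over_children = ss_over.spawn(max(n_over, 1))
    stems = []
    for i in range(n_over):
        rng_i = np.random.default_rng(over_children[i])
        gx, gy = grid_sites[i]
        x = float(np.clip(gx + rng_i.normal(0, 0.15 * s_over), 0, ex))
        y = float(np.clip(gy + rng_i.normal(0, 0.15 * s_over), 0, ey))
        h = rng_i.uniform(*config.overstory_height_range)
        r = float(
            np.clip(_R_CROWN_COEF * h + rng_i.normal(0, 0.15), 0.8, 4.0)
        )
        dbh = max(
            0.05,
            config.dbh_slope * h
            + config.dbh_intercept
            + rng_i.normal(0, config.dbh_sigma),
        )
        gz = float(terrain(x, y))
        pts = sample_tree(
            config.overstory_crown_model,
            (x, y),
            h,
            r,
            config.point_density,
            rng_i,
            ground_z=gz,
            crown_base_frac=0.35,
            trunk_points_per_m=20.0,
        )
        clouds_xyz.append(pts)
        clouds_layer.append(np.full(len(pts), LAYER_OVERSTORY, dtype=np.int16))
        clouds_id.append(np.full(len(pts), tree_id, dtype=np.int32))
        stems.append((x, y, r))
        records.append(
            dict(
                layer="overstory",
                tree_id=tree_id,
                x=x,
                y=y,
                height=h,
                crown_radius=r,
                dbh=dbh,
            )
        )
        tree_id += 1

    stem_xy = np.array([(s[0], s[1]) for s in stems]) if stems else np.empty((0, 2))
    stem_r = np.array([s[2] for s in stems]) if stems else np.empty(0)

    # ---- saplings on a jittered grid ------------------------------------
    rng_sap = np.random.default_rng(ss_sap)
    s = config.sapling_grid_spacing
    xs = np.arange(s / 2, ex, s)
    ys = np.arange(s / 2, ey, s)
    stem_tree = cKDTree(stem_xy) if len(stem_xy) else None
    for gy in ys:
        for gx in xs:
            jx = gx + rng_sap.normal(0, 0.1 * s)
            jy = gy + rng_sap.normal(0, 0.1 * s)
            h = rng_sap.uniform(*config.sapling_height_range)
            r = 0.2 * h + 0.05
            keep = True
            if stem_tree is not None:
                d, _ = stem_tree.query([jx, jy])
                if d < 0.6:  # stem collision with a mature tree
                    keep = False
            if not keep or not (0 <= jx <= ex and 0 <= jy <= ey):
                # still consume the tree's point draw for stream stability
                continue
            gz = float(terrain(jx, jy))
            pts = sample_tree(
                config.sapling_crown_model,
                (jx, jy),
                h,
                r,
                config.point_density,
                rng_sap,
                ground_z=gz,
                crown_base_frac=0.05,
                trunk_points_per_m=3.0,
                top_offset=config.leader_shoot,
            )
            clouds_xyz.append(pts)
            clouds_layer.append(np.full(len(pts), LAYER_SAPLING, dtype=np.int16))
            clouds_id.append(np.full(len(pts), tree_id, dtype=np.int32))
            records.append(
                dict(
                    layer="sapling",
                    tree_id=tree_id,
                    x=jx,
                    y=jy,
                    height=h,
                    crown_radius=r,
                    dbh=np.nan,
                )
            )
            tree_id += 1

    # ---- ground returns ---------------------------------------------------
    rng_ground = np.random.default_rng(ss_ground)
    n_ground = rng_ground.poisson(config.ground_point_fraction * config.point_density * area)
    gx = rng_ground.uniform(0, ex, n_ground)
    gy = rng_ground.uniform(0, ey, n_ground)
    gpts = np.column_stack([gx, gy, terrain(gx, gy)])
    clouds_xyz.append(gpts)
    clouds_layer.append(np.full(n_ground, LAYER_GROUND, dtype=np.int16))
    clouds_id.append(np.full(n_ground, -1, dtype=np.int32))

    # ---- shrub/grass clutter (0-0.5 m band) ------------------------------
    rng_clut = np.random.default_rng(ss_clutter)
    n_clut = rng_clut.poisson(config.clutter_density * area)
    cx = rng_clut.uniform(0, ex, n_clut)
    cy = rng_clut.uniform(0, ey, n_clut)
    cz = terrain(cx, cy) + rng_clut.uniform(0.0, 0.5, n_clut)
    clouds_xyz.append(np.column_stack([cx, cy, cz]))
    clouds_layer.append(np.full(n_clut, LAYER_CLUTTER, dtype=np.int16))
    clouds_id.append(np.full(n_clut, -1, dtype=np.int32))

    xyz = np.concatenate(clouds_xyz) if clouds_xyz else np.empty((0, 3))
    layer = np.concatenate(clouds_layer) if clouds_layer else np.empty(0, np.int16)
    tid = np.concatenate(clouds_id) if clouds_id else np.empty(0, np.int32)

    # ---- occlusion: thin non-overstory points beneath crowns --------------
    if config.occlusion and len(stem_xy) and len(xyz):
        rng_occl = np.random.default_rng(ss_occl)
        under = layer != LAYER_OVERSTORY
        idx_under = np.flatnonzero(under)
        cover = np.zeros(len(idx_under))
        tree = cKDTree(stem_xy)
        rmax = float(stem_r.max())
        neighbors = tree.query_ball_point(xyz[idx_under, :2], rmax)
        for j, nbrs in enumerate(neighbors):
            for t in nbrs:
                d = np.hypot(
                    xyz[idx_under[j], 0] - stem_xy[t, 0],
                    xyz[idx_under[j], 1] - stem_xy[t, 1],
                )
                if d < stem_r[t]:
                    cover[j] += 1.0 - d / stem_r[t]
        p_remove = np.minimum(0.85, config.occlusion_strength * cover)
        drop = rng_occl.uniform(size=len(idx_under)) < p_remove
        keep_mask = np.ones(len(xyz), dtype=bool)
        keep_mask[idx_under[drop]] = False
        xyz, layer, tid = xyz[keep_mask], layer[keep_mask], tid[keep_mask]

    cloud = PointCloud(
        xyz,
        classification=np.full(len(xyz), CLASS_UNCLASSIFIED, dtype=np.int16),
        truth_id=tid,
        truth_layer=layer,
    )
    inventory = pd.DataFrame.from_records(
        records,
        columns=["layer", "tree_id", "x", "y", "height", "crown_radius", "dbh"],
    )

    closure = achieved_closure(cloud, terrain, config)
    if abs(closure - config.canopy_closure_target) > 0.1:
        warnings.warn(
            f"achieved canopy closure {closure:.2f} deviates from target "
            f"{config.canopy_closure_target:.2f}",
            stacklevel=2,
        )
    return StandResult(cloud, inventory, closure, config, terrain)


def achieved_closure(
    cloud: PointCloud, terrain: Terrain, config: StandConfig, scale: float = 0.5
) -> float:
    """Fraction of plot cells whose overstory occupancy exceeds 5 m height."""
    ex, ey = config.extent_m
    ncols = max(1, int(np.ceil(ex / scale)))
    nrows = max(1, int(np.ceil(ey / scale)))
    grid = np.zeros((nrows, ncols))
    if len(cloud):
        hz = cloud.z - terrain(cloud.x, cloud.y)
        sel = hz > 5.0
        if sel.any():
            col = np.clip((cloud.x[sel] / scale).astype(int), 0, ncols - 1)
            row = np.clip((cloud.y[sel] / scale).astype(int), 0, nrows - 1)
            np.maximum.at(grid, (row, col), hz[sel])
    return float((grid > 5.0).mean())


def overstory_chm(result: StandResult, resolution: float = 0.5) -> Raster:
    """Truth overstory CHM (normalized by the generating terrain)."""
    cfg = result.config
    ex, ey = cfg.extent_m
    ncols = max(1, int(np.ceil(ex / resolution)))
    nrows = max(1, int(np.ceil(ey / resolution)))
    grid = np.zeros((nrows, ncols))
    cloud = result.cloud
    hz = cloud.z - result.terrain(cloud.x, cloud.y)
    sel = cloud.truth_layer == LAYER_OVERSTORY
    if sel.any():
        col = np.clip((cloud.x[sel] / resolution).astype(int), 0, ncols - 1)
        row = np.clip((cloud.y[sel] / resolution).astype(int), 0, nrows - 1)
        np.maximum.at(grid, (row, col), hz[sel])
    return Raster(grid, (0.0, 0.0), resolution)


def with_seed(config: StandConfig, seed: int) -> StandConfig:
    """Config copy with a different seed (convenience for replicate runs)."""
    return replace(config, rng_seed=int(seed))
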