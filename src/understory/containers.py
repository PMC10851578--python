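"""In-memory contracts shared by every pipeline stage.

A :class:`PointCloud` is a column-oriented bag of point records in a
projected CRS (meters).  All distances in the package are planar or 3D
Euclidean on these coordinates.  A :class:`Raster` is a single-band height
grid (the canopy height model) with a lower-left origin and cell-center
sample semantics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Point classification vocabulary.  Ground is refined into true ground
# (per-cell lowest classified ground return) and pseudo ground (grass/shrub
# returns forced to height 0 during normalization).
CLASS_UNCLASSIFIED = 1
CLASS_GROUND = 2
CLASS_NOISE = 7
CLASS_TRUE_GROUND = 20
CLASS_PSEUDO_GROUND = 21

CLASS_NAMES = {
    CLASS_UNCLASSIFIED: "unclassified",
    CLASS_GROUND: "ground",
    CLASS_NOISE: "noise",
    CLASS_TRUE_GROUND: "true_ground",
    CLASS_PSEUDO_GROUND: "pseudo_ground",
}

GROUND_CLASSES = (CLASS_GROUND, CLASS_TRUE_GROUND, CLASS_PSEUDO_GROUND)

# Truth-layer codes attached by the synthetic generator.
LAYER_NONE = -1
LAYER_GROUND = 0
LAYER_OVERSTORY = 1
LAYER_SAPLING = 2
LAYER_CLUTTER = 3

LAYER_NAMES = {
    LAYER_NONE: "none",
    LAYER_GROUND: "ground",
    LAYER_OVERSTORY: "overstory",
    LAYER_SAPLING: "sapling",
    LAYER_CLUTTER: "clutter",
}


@dataclass
class PointCloud:
    """Point records: coordinates plus classification, segment and truth ids.

    Parameters
    ----------
    xyz
        ``(n, 3)`` float array of x, y, z in meters (projected CRS).
    classification
        Per-point class code from the fixed vocabulary above.
    segment
        Per-point segment id; ``-1`` means unassigned.
    truth_id
        Ground-truth tree id from the simulator; ``-1`` if unknown.
    truth_layer
        Ground-truth layer code; ``LAYER_NONE`` if unknown.
    """

    xyz: np.ndarray
    classification: np.ndarray = field(default=None)  # type: ignore[assignment]
    segment: np.ndarray = field(default=None)  # type: ignore[assignment]
    truth_id: np.ndarray = field(default=None)  # type: ignore[assignment]
    truth_layer: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64).reshape(-1, 3)
        n = len(self.xyz)
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("point coordinates must be finite")
        if self.classification is None:
            self.classification = np.full(n, CLASS_UNCLASSIFIED, dtype=np.int16)
        else:
            self.classification = np.asarray(self.classification, dtype=np.int16)
        if self.segment is None:
            self.segment = np.full(n, -1, dtype=np.int32)
        else:
            self.segment = np.asarray(self.segment, dtype=np.int32)
        if self.truth_id is None:
            self.truth_id = np.full(n, -1, dtype=np.int32)
        else:
            self.truth_id = np.asarray(self.truth_id, dtype=np.int32)
        if self.truth_layer is None:
            self.truth_layer = np.full(n, LAYER_NONE, dtype=np.int16)
        else:
            self.truth_layer = np.asarray(self.truth_layer, dtype=np.int16)
        for arr, name in (
            (self.classification, "classification"),
            (self.segment, "segment"),
            (self.truth_id, "truth_id"),
            (self.truth_layer, "truth_layer"),
        ):
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != point count {n}")
        bad = ~np.isin(self.classification, list(CLASS_NAMES))
        if bad.any():
            raise ValueError(
                f"unknown class codes: {sorted(set(self.classification[bad].tolist()))}"
            )

    def __len__(self) -> int:
        return len(self.xyz)

    @property
    def x(self) -> np.ndarray:
        return self.xyz[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xyz[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    def copy(self) -> "PointCloud":
        return PointCloud(
            self.xyz.copy(),
            self.classification.copy(),
            self.segment.copy(),
            self.truth_id.copy(),
            self.truth_layer.copy(),
        )

    def subset(self, mask_or_idx) -> "PointCloud":
        """Row subset (boolean mask or index array)."""
        return PointCloud(
            self.xyz[mask_or_idx],
            self.classification[mask_or_idx],
            self.segment[mask_or_idx],
            self.truth_id[mask_or_idx],
            self.truth_layer[mask_or_idx],
        )

    def is_ground(self) -> np.ndarray:
        return np.isin(self.classification, GROUND_CLASSES)


def concat(clouds) -> PointCloud:
    clouds = list(clouds)
    if not clouds:
        return PointCloud(np.empty((0, 3)))
    return PointCloud(
        np.concatenate([c.xyz for c in clouds]),
        np.concatenate([c.classification for c in clouds]),
        np.concatenate([c.segment for c in clouds]),
        np.concatenate([c.truth_id for c in clouds]),
        np.concatenate([c.truth_layer for c in clouds]),
    )


@dataclass
class Raster:
    """Single-band height grid.

    ``data[row, col]`` with row 0 at the *bottom*: the cell center of
    ``data[i, j]`` sits at ``(origin_x + (j + 0.5) * res, origin_y + (i + 0.5) * res)``.
    No-data cells are NaN in memory and written as an explicit sentinel on disk.
    """

    data: np.ndarray
    origin: tuple[float, float]
    resolution: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("raster grid must be 2D")
        if not self.resolution > 0:
            raise ValueError("resolution must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.data)

    def world_to_cell(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map world coordinates to (row, col); no bounds check."""
        col = np.floor((np.asarray(x) - self.origin[0]) / self.resolution).astype(int)
        row = np.floor((np.asarray(y) - self.origin[1]) / self.resolution).astype(int)
        return row, col

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        x = self.origin[0] + (np.asarray(col) + 0.5) * self.resolution
        y = self.origin[1] + (np.asarray(row) + 0.5) * self.resolution
        return x, y

    def copy(self) -> "Raster":
        return Raster(self.data.copy(), self.origin, self.resolution)
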