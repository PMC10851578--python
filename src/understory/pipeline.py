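"""End-to-end orchestration of the two-layer segmentation workflow.

Stage order: fine normalization -> stratification at the height threshold ->
spectral crown delineation (NSC) -> postprocessing repair (NSCP) -> mature
trunk-buffer removal -> isolated-point removal -> sapling CHM -> adaptive
mean shift -> phenotypes -> (optional) evaluation against a reference
inventory.  Every stage's output can be persisted; a manifest records the
configuration, seed and per-stage point counts so any stage can be rerun
standalone.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import PointCloud
from .evaluate import EvalReport, MatchConfig, evaluate_detection
from .extraction import DbhModel, build_chm, extract_sapling_points, fit_dbh_model
from .ground import NormalizationConfig, normalize
from .io import write_inventory, write_points, write_raster
from .nscp import CandidateRules, postprocess
from .overstory import NscConfig, TreeSegment, nsc_segment, stratify
from .saplings import records_to_frame, segment_saplings

log = logging.getLogger("understory")


@dataclass(frozen=True)
class RunConfig:
    """All stage parameters with their standard defaults."""

    delta: float = 0.5  # true-ground grid step, m
    stratification_threshold: float = 5.0  # overstory/understory cut, m
    nsc_landmarks: int = 500
    nsc_sigma_xy: float = 1.5
    nsc_sigma_z: float = 6.0
    nsc_cutoff: float = 5.0
    aspect_low: float = 0.7
    aspect_high: float = 1.3
    dp_factor: float = 5.0  # Douglas-Peucker tolerance multiplier
    buffer_factor: float = 1.5  # trunk buffer radius = factor * DBH
    noise_cell: float = 0.3  # isolated-point voxel size, m
    chm_resolution: float = 0.05  # sapling CHM cell, m
    partial: float = 0.5  # adaptive bandwidth control factor
    seed_min_height: float = 0.3  # CHM seed height cut, m
    seed_min_distance: float = 1.5  # CHM seed exclusion window, m
    match_radius: float = 1.0
    match_height_tolerance: float = 1.5
    closure_scales: tuple[float, ...] = (0.5, 1.0, 2.0)
    rng_seed: int = 0

    def stage_seed(self, offset: int) -> int:
        """Per-stage seed derived from the global seed by fixed offsets."""
        return (self.rng_seed + offset) % (2**31 - 1)


@dataclass
class PipelineResult:
    """All pipeline artifacts in memory."""

    normalized: PointCloud
    mature_trees: list[TreeSegment]
    mature_table: pd.DataFrame
    sapling_table: pd.DataFrame
    sapling_labels: np.ndarray
    chm: "object"
    dbh_model: DbhModel | None
    report: EvalReport | None
    counts: dict = field(default_factory=dict)
    nscp_log: list[str] = field(default_factory=list)


def mature_tree_table(segments: list[TreeSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                tree_id=s.segment_id,
                x=s.stem[0],
                y=s.stem[1],
                height=s.height,
                crown_width=s.crown_width,
                n_points=s.n_points,
            )
            for s in segments
        ],
        columns=["tree_id", "x", "y", "height", "crown_width", "n_points"],
    )


def run_pipeline(
    cloud: PointCloud,
    config: RunConfig | None = None,
    dbh_pairs: pd.DataFrame | None = None,
    reference: pd.DataFrame | None = None,
    output_dir: str | Path | None = None,
    skip_normalization: bool = False,
) -> PipelineResult:
    """Run the full workflow on a raw point cloud.

    ``dbh_pairs`` (columns ``height, dbh``) fits the trunk-buffer model; when
    absent the trunk-removal step is skipped with a warning.  ``reference``
    (columns ``x, y, height``) triggers the evaluation stage.
    """
    cfg = config or RunConfig()
    counts: dict[str, int] = {"input": len(cloud)}
    out = Path(output_dir) if output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    # 1. fine normalization
    if skip_normalization:
        norm = cloud
    else:
        norm = normalize(cloud, NormalizationConfig(delta=cfg.delta))
    counts["normalized"] = len(norm)
    log.info("normalized %d points", len(norm))
    if out:
        write_points(norm, out / "normalized.csv")

    # 2. stratify
    strat = stratify(norm, cfg.stratification_threshold)
    counts["overstory"] = len(strat.overstory_idx)
    counts["understory"] = len(strat.understory_idx)
    log.info(
        "stratified: %d overstory, %d understory points",
        counts["overstory"],
        counts["understory"],
    )

    # 3-4. NSC + NSCP on the overstory stratum
    mature: list[TreeSegment] = []
    nscp_log: list[str] = []
    if counts["overstory"] > 0:
        over_pts = norm.xyz[strat.overstory_idx]
        nsc_cfg = NscConfig(
            sigma_xy=cfg.nsc_sigma_xy,
            sigma_z=cfg.nsc_sigma_z,
            cutoff=cfg.nsc_cutoff,
            n_landmarks=cfg.nsc_landmarks,
            seed=cfg.stage_seed(1),
        )
        segments = nsc_segment(over_pts, config=nsc_cfg)
        counts["nsc_segments"] = len(segments)
        log.info("NSC: %d segments", len(segments))
        rules = CandidateRules(
            min_height=cfg.stratification_threshold,
            aspect_low=cfg.aspect_low,
            aspect_high=cfg.aspect_high,
        )
        result = postprocess(
            segments, seed=cfg.stage_seed(2), rules=rules, dp_factor=cfg.dp_factor
        )
        mature = result.candidates
        nscp_log = result.log
        counts["mature_trees"] = len(mature)
        counts["overstory_noise"] = len(result.noise_indices)
        log.info("NSCP: %d candidate trees", len(mature))
    else:
        warnings.warn("empty overstory stratum; skipping overstory stages")
    mtable = mature_tree_table(mature)
    if out:
        write_inventory(mtable, out / "mature_trees.csv")

    # 5. DBH model + trunk removal, 6. denoise
    under_pts = norm.xyz[strat.understory_idx]
    model = None
    if dbh_pairs is not None and len(dbh_pairs) >= 2:
        model = fit_dbh_model(dbh_pairs["height"], dbh_pairs["dbh"])
    elif len(mature):
        warnings.warn("no DBH field pairs given; trunk buffers skipped")
    stem_xy = mtable[["x", "y"]].to_numpy() if len(mtable) else np.empty((0, 2))
    stem_h = mtable["height"].to_numpy() if len(mtable) else np.empty(0)
    keep, stats = extract_sapling_points(
        under_pts,
        stem_xy,
        stem_h,
        model,
        buffer_factor=cfg.buffer_factor,
        noise_cell=cfg.noise_cell,
    )
    counts.update({f"extraction_{k}": v for k, v in stats.items()})
    sap_pts = under_pts[keep]
    log.info(
        "understory extraction: %d kept (%d trunk, %d isolated removed)",
        stats["kept"],
        stats["trunk_removed"],
        stats["isolated_removed"],
    )

    # 7. sapling CHM
    bounds = None
    if len(norm):
        bounds = (norm.x.min(), norm.y.min(), norm.x.max(), norm.y.max())
    chm = build_chm(sap_pts, resolution=cfg.chm_resolution, bounds=bounds)
    if out:
        write_raster(chm, out / "sapling_chm.asc")

    # 8-9. adaptive mean shift + phenotypes
    if len(sap_pts):
        records, labels = segment_saplings(
            sap_pts,
            chm,
            partial=cfg.partial,
            min_distance=cfg.seed_min_distance,
            seed_min_height=cfg.seed_min_height,
        )
    else:
        records, labels = [], np.empty(0, dtype=int)
    stable = records_to_frame(records)
    counts["saplings"] = len(stable)
    log.info("mean shift: %d saplings", len(stable))
    if out:
        write_inventory(stable, out / "saplings.csv")

    # 10. evaluation
    report = None
    if reference is not None and len(reference) and len(stable):
        report = evaluate_detection(
            reference.reset_index(drop=True),
            stable,
            MatchConfig(cfg.match_radius, cfg.match_height_tolerance),
        )
        log.info("evaluation: %s", report.summary().replace("\n", " | "))
        if out:
            (out / "evaluation.txt").write_text(report.summary() + "\n")

    if out:
        manifest = dict(
            version=__version__,
            config=asdict(cfg),
            counts=counts,
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(
        normalized=norm,
        mature_trees=mature,
        mature_table=mtable,
        sapling_table=stable,
        sapling_labels=labels,
        chm=chm,
        dbh_model=model,
        report=report,
        counts=counts,
        nscp_log=nscp_log,
    )


def run_on_stand(stand, config: RunConfig | None = None,
                 output_dir=None) -> PipelineResult:
    """Convenience: run the pipeline on a synthetic stand against its truth.

    DBH pairs come from the stand's overstory inventory (up to 100 sampled
    trees, mirroring a field campaign); the reference is the sapling truth.
    """
    cfg = config or RunConfig()
    inv = stand.inventory
    over = inv[inv["layer"] == "overstory"]
    sap = inv[inv["layer"] == "sapling"]
    pairs = None
    if len(over) >= 2:
        n = min(100, len(over))
        pairs = over.sample(n, random_state=cfg.stage_seed(3))[["height", "dbh"]]
    ref = sap[["x", "y", "height", "crown_radius"]].reset_index(drop=True)
    return run_pipeline(
        stand.cloud,
        cfg,
        dbh_pairs=pairs,
        reference=ref,
        output_dir=output_dir,
    )
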