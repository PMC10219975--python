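"""Experiment configuration, YAML I/O and the end-to-end pipeline.

An imaging session is described by one YAML file (phantom, optics, stage,
tiles, sections, segmentation, seed) — mirroring how real sessions are
parameterized — and ``run_pipeline`` executes the full chain into a run
directory: acquisition, preprocessing, stitching, quantification and the
statistics report, all addressable from a manifest and reproducible from
the seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__, preprocess, quantify, stitch
from .acquisition import (
    SectionSchedule,
    StageConfig,
    TilePlan,
    plan_tiles,
    run_virtual_acquisition,
    schedule_sections,
)
from .optics import OpticalConfig
from .phantom import (
    RegionModel,
    generate_tissue_phantom,
    habenula_region_pair,
    region_label_image,
)

__all__ = ["ExperimentConfig", "load_config", "save_config", "run_pipeline"]

logger = logging.getLogger("duvtomo")


@dataclass
class ExperimentConfig:
    """Complete description of one virtual imaging session.

    All lengths are µm unless a key says mm.  The seed drives every
    stochastic stage through named substreams.
    """

    seed: int
    box_um: tuple[float, float, float] = (400.0, 200.0, 500.0)
    regions: list[dict] = field(default_factory=list)  # RegionModel kwargs
    optics: dict = field(default_factory=dict)  # OpticalConfig overrides
    stage: dict = field(default_factory=dict)  # StageConfig overrides
    overlap_fraction: float = 0.20
    section_thickness_um: float = 50.0
    segmentation: dict = field(default_factory=dict)  # SegmentationParams overrides
    flat_field: bool = True
    sigma_log: float = 0.3

    _KNOWN = {
        "seed",
        "box_um",
        "regions",
        "optics",
        "stage",
        "overlap_fraction",
        "section_thickness_um",
        "segmentation",
        "flat_field",
        "sigma_log",
    }

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if not (0.0 <= self.overlap_fraction <= 0.9):
            raise ValueError("overlap_fraction must lie in [0, 0.9]")
        if self.section_thickness_um <= 0:
            raise ValueError("section_thickness_um must be > 0")
        self.box_um = tuple(float(v) for v in self.box_um)
        if len(self.box_um) != 3 or any(v <= 0 for v in self.box_um):
            raise ValueError("box_um must be three positive extents")

    def region_models(self) -> list[RegionModel]:
        if not self.regions:
            return habenula_region_pair(self.box_um)
        out = []
        for kw in self.regions:
            kw = dict(kw)
            kw["bounds"] = tuple(tuple(float(v) for v in b) for b in kw["bounds"])
            if "dye_profile" in kw:
                kw["dye_profile"] = tuple(kw["dye_profile"])
            out.append(RegionModel(**kw))
        return out

    def optical_config(self) -> OpticalConfig:
        kw = dict(self.optics)
        for key in ("psf_sigma_um", "fov_px"):
            if key in kw:
                kw[key] = tuple(kw[key])
        return OpticalConfig(**kw)

    def stage_config(self) -> StageConfig:
        kw = dict(self.stage)
        if "travel_limits_mm" in kw:
            kw["travel_limits_mm"] = tuple(kw["travel_limits_mm"])
        return StageConfig(**kw)

    def segmentation_params(self) -> quantify.SegmentationParams:
        return quantify.SegmentationParams(**self.segmentation)

    def to_dict(self) -> dict:
        def plain(v):
            if isinstance(v, (list, tuple)):
                return [plain(x) for x in v]
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            return v

        return plain(dataclasses.asdict(self))


def load_config(path: str | Path) -> ExperimentConfig:
    """Load and validate an experiment YAML; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    unknown = set(raw) - ExperimentConfig._KNOWN
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ValueError("missing required key: seed")
    cfg = ExperimentConfig(**raw)
    defaults = sorted(ExperimentConfig._KNOWN - set(raw))
    if defaults:
        logger.info("config %s: defaults used for %s", path, defaults)
    return cfg


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def run_pipeline(config: ExperimentConfig, out_dir: str | Path) -> Path:
    """Execute the full virtual experiment into ``out_dir``.

    Stages: phantom generation, tile/section planning, virtual acquisition
    (tiles written as TIFF), optional flat-field estimation and correction,
    per-section stitching, segmentation on the red channel, region
    assignment, per-section counts/densities and — when exactly two regions
    are present — a paired t-test of their densities across sections.
    Deterministic given the config seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    manifest: dict[str, object] = {"version": __version__, "seed": config.seed}
    stage = "config"
    try:
        save_config(config, out / "experiment.yaml")
        logger.info("run started: seed=%s", config.seed)

        stage = "phantom"
        root = np.random.SeedSequence(config.seed)
        sub = {
            name: int(ss.generate_state(1)[0] % (2**31))
            for name, ss in zip(
                ("phantom", "acquisition"), root.spawn(2)
            )
        }
        regions = config.region_models()
        phantom = generate_tissue_phantom(
            config.box_um, regions, seed=sub["phantom"], sigma_log=config.sigma_log
        )
        logger.info("phantom: %d cells in %d regions", len(phantom.cells), len(regions))

        stage = "planning"
        optics_cfg = config.optical_config()
        plan = plan_tiles(
            (config.box_um[0] / 1000.0, config.box_um[1] / 1000.0),
            (optics_cfg.fov_um[0] / 1000.0, optics_cfg.fov_um[1] / 1000.0),
            config.overlap_fraction,
        )
        schedule = schedule_sections(
            config.box_um[2],
            config.section_thickness_um,
            attenuation_depth_um=optics_cfg.attenuation_depth_um,
        )
        logger.info(
            "plan: %dx%d tiles, %d sections", plan.grid[0], plan.grid[1], schedule.n_sections
        )

        stage = "acquisition"
        tiles_dir = out / "tiles"
        series = run_virtual_acquisition(
            phantom, optics_cfg, plan, schedule, seed=sub["acquisition"], out_dir=tiles_dir
        )
        manifest["tiles_manifest"] = "tiles/manifest.csv"

        stage = "preprocess"
        field_model = None
        if config.flat_field and len(series.images) >= 10:
            field_model = preprocess.estimate_flat_field(
                [im.rgb.astype(float) for im in series.images]
            )
            logger.info("flat field estimated from %d tiles", len(series.images))

        stage = "stitch"
        px = optics_cfg.pixel_size_um
        atlas_shape = (
            int(round(config.box_um[1] / px)),
            int(round(config.box_um[0] / px)),
        )
        atlas = region_label_image(phantom, px, atlas_shape)
        mosaics_dir = out / "mosaics"
        mosaics_dir.mkdir(exist_ok=True)

        stage = "quantify"
        params = config.segmentation_params()
        all_cells = []
        for k in range(schedule.n_sections):
            tiles = {}
            for im in series.section(k):
                img = im.rgb.astype(float)
                if field_model is not None:
                    img = preprocess.flat_field_correct(img, field_model)
                tiles[im.tile_index] = img
            if len(tiles) > 1:
                mosaic, placement = stitch.stitch_section(tiles, plan, px)
            else:
                mosaic = next(iter(tiles.values()))
            tifffile.imwrite(
                mosaics_dir / f"section_{k:04d}.tif",
                np.clip(mosaic, 0, optics_cfg.max_value).astype(
                    np.uint8 if optics_cfg.bit_depth == 8 else np.uint16
                ),
            )
            _, cells = quantify.segment_cells(mosaic, pixel_size_um=px, params=params)
            cells = quantify.assign_regions(cells, atlas, pixel_size_um=px)
            cells["section_index"] = k
            all_cells.append(cells)
        cell_table = pd.concat(all_cells, ignore_index=True)
        cell_table.to_csv(out / "cells.csv", index=False)
        manifest["cells"] = "cells.csv"
        logger.info("segmented %d cells over %d sections", len(cell_table), schedule.n_sections)

        area_mm2 = {
            r.region_id: (r.bounds[0][1] - r.bounds[0][0])
            * (r.bounds[1][1] - r.bounds[1][0])
            * 1e-6
            for r in regions
        }
        counts = quantify.count_and_density(cell_table, area_mm2)
        counts.to_csv(out / "region_counts.csv", index=False)
        manifest["region_counts"] = "region_counts.csv"

        stage = "statistics"
        if len(regions) == 2:
            ids = [r.region_id for r in regions]
            pivot = (
                counts.pivot_table(
                    index="section_index", columns="region_id", values="density_per_mm2"
                )
                .reindex(range(schedule.n_sections))
                .fillna(0.0)
            )
            if all(i in pivot.columns for i in ids):
                t, df, p = quantify.paired_t(
                    pivot[ids[0]].to_numpy(), pivot[ids[1]].to_numpy()
                )
                report = {
                    "paired_t": {"t": t, "df": df, "p": p},
                    "regions": ids,
                    "mean_density_per_mm2": {
                        str(i): float(pivot[i].mean()) for i in ids
                    },
                }
                with open(out / "stats.json", "w") as fh:
                    json.dump(report, fh, indent=2)
                manifest["stats"] = "stats.json"
                logger.info("paired t: t=%.3f df=%d p=%.2e", t, df, p)

        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        logger.info("run complete")
        return out
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
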