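"""Virtual acquisition planning and orchestration.

Covers the stage arithmetic of the motorized three-axis translator
(stepper-driven micrometer actuators), tile-grid planning with overlap,
serial-section scheduling, and the serpentine acquisition loop that renders
every tile of every block face.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .optics import BlockFaceImage, OpticalConfig, render_block_face

__all__ = [
    "StageConfig",
    "TilePlan",
    "SectionSchedule",
    "SectionSeries",
    "stage_resolution",
    "distance_to_steps",
    "plan_tiles",
    "schedule_sections",
    "run_virtual_acquisition",
]


@dataclass(frozen=True)
class StageConfig:
    """Stepper-driven linear translator: 0.9° steps on a 500 µm/rev micrometer."""

    step_angle_deg: float = 0.9
    pitch_um_per_rev: float = 500.0
    travel_limits_mm: tuple[float, float, float] = (25.0, 50.0, 25.0)  # (x, y, z)

    @property
    def resolution_um(self) -> float:
        return stage_resolution(self.step_angle_deg, self.pitch_um_per_rev)


def stage_resolution(step_angle_deg: float, pitch_um_per_rev: float) -> float:
    """Linear resolution (µm per step) of a stepper-driven micrometer.

    resolution = pitch x step_angle / 360, computed in exact rational
    arithmetic when the inputs are exactly representable (0.9°, 500 µm/rev
    -> exactly 1.25 µm).
    """
    if step_angle_deg <= 0 or pitch_um_per_rev <= 0:
        raise ValueError("step angle and pitch must be > 0")
    try:
        res = (
            Fraction(str(step_angle_deg)) * Fraction(str(pitch_um_per_rev)) / 360
        )
        return float(res)
    except ValueError:  # non-decimal float repr; fall back to float math
        return pitch_um_per_rev * step_angle_deg / 360.0


def distance_to_steps(
    distance_um: float,
    resolution_um: float,
    travel_limit_um: float | None = None,
) -> tuple[int, float]:
    """Quantize a commanded move to whole motor steps.

    Returns (steps, residual µm) with steps = round-half-even of
    distance/resolution, so |residual| <= resolution/2.
    """
    if resolution_um <= 0:
        raise ValueError("resolution must be > 0")
    if travel_limit_um is not None and abs(distance_um) > travel_limit_um:
        raise ValueError(
            f"commanded move {distance_um} µm exceeds axis travel {travel_limit_um} µm"
        )
    steps = int(np.rint(distance_um / resolution_um))
    residual = distance_um - steps * resolution_um
    return steps, residual


@dataclass(frozen=True)
class TilePlan:
    """Tile grid covering a lateral extent with fractional overlap."""

    fov_mm: tuple[float, float] = (1.3, 1.0)
    overlap_fraction: float = 0.20
    grid: tuple[int, int] = (1, 1)  # (n_x, n_y)
    origins_mm: tuple[tuple[float, float], ...] = ((0.0, 0.0),)  # row-major (x, y)

    @property
    def n_tiles(self) -> int:
        return self.grid[0] * self.grid[1]

    def serpentine_order(self) -> list[tuple[int, int]]:
        """Tile visit order (row, col): left-to-right, then right-to-left."""
        n_x, n_y = self.grid
        order = []
        for r in range(n_y):
            cols = range(n_x) if r % 2 == 0 else range(n_x - 1, -1, -1)
            order.extend((r, c) for c in cols)
        return order

    def origin_mm(self, row: int, col: int) -> tuple[float, float]:
        return self.origins_mm[row * self.grid[0] + col]


def _axis_origins(extent: float, fov: float, stride: float) -> np.ndarray:
    if extent <= fov:
        return np.array([0.0])
    n = int(np.ceil((extent - fov) / stride)) + 1
    origins = np.arange(n) * stride
    # shift-to-fit: the last tile ends exactly at the extent instead of
    # protruding beyond the tissue
    origins[-1] = extent - fov
    return origins


def plan_tiles(
    extent_mm: tuple[float, float],
    fov_mm: tuple[float, float] = (1.3, 1.0),
    overlap_fraction: float = 0.20,
) -> TilePlan:
    """Plan the tile grid covering ``extent_mm`` with the given overlap.

    Stride is fov x (1 - overlap); tile counts use ceil with the last tile
    clipped to end at the extent, so the union of tiles always covers the
    requested area and adjacent tiles share at least the nominal overlap.
    """
    if any(e <= 0 for e in extent_mm) or any(f <= 0 for f in fov_mm):
        raise ValueError("extent and fov must be > 0")
    if not (0.0 <= overlap_fraction <= 0.9):
        raise ValueError("overlap fraction must lie in [0, 0.9]")
    ox = _axis_origins(extent_mm[0], fov_mm[0], fov_mm[0] * (1 - overlap_fraction))
    oy = _axis_origins(extent_mm[1], fov_mm[1], fov_mm[1] * (1 - overlap_fraction))
    origins = tuple((float(x), float(y)) for y in oy for x in ox)
    return TilePlan(
        fov_mm=tuple(fov_mm),
        overlap_fraction=overlap_fraction,
        grid=(len(ox), len(oy)),
        origins_mm=origins,
    )


@dataclass(frozen=True)
class SectionSchedule:
    """Serial-section schedule: block-face z positions at fixed thickness."""

    section_thickness_um: float
    n_sections: int
    face_z_um: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.section_thickness_um <= 0:
            raise ValueError("section thickness must be > 0")
        dz = np.diff(self.face_z_um)
        if len(dz) and not np.all(dz > 0):
            raise ValueError("face z positions must be strictly increasing")


def schedule_sections(
    z_extent_um: float,
    thickness_um: float,
    attenuation_depth_um: float | None = None,
) -> SectionSchedule:
    """Face positions 0, t, 2t, ... down a block of depth ``z_extent_um``.

    Warns when the thickness does not exceed the optical attenuation depth:
    consecutive faces would then re-image overlapping material, breaking the
    premise that each cell is seen in at most one section.
    """
    if z_extent_um <= 0 or thickness_um <= 0:
        raise ValueError("extent and thickness must be > 0")
    if thickness_um > z_extent_um:
        warnings.warn(
            "section thickness exceeds the block depth; single face", stacklevel=2
        )
        return SectionSchedule(thickness_um, 1, (0.0,))
    if attenuation_depth_um is not None and thickness_um <= attenuation_depth_um:
        warnings.warn(
            f"section thickness {thickness_um} µm <= attenuation depth "
            f"{attenuation_depth_um} µm: consecutive faces re-image material",
            stacklevel=2,
        )
    n = int(np.floor(z_extent_um / thickness_um))
    faces = tuple(float(k * thickness_um) for k in range(n))
    return SectionSchedule(thickness_um, n, faces)


@dataclass
class SectionSeries:
    """Ordered collection of block-face tiles over sections, plus manifest."""

    images: list[BlockFaceImage] = field(default_factory=list)
    manifest: pd.DataFrame = field(default_factory=pd.DataFrame)
    tile_plan: TilePlan | None = None
    schedule: SectionSchedule | None = None

    def section(self, index: int) -> list[BlockFaceImage]:
        return [im for im in self.images if im.section_index == index]


def run_virtual_acquisition(
    phantom,
    config: OpticalConfig,
    tile_plan: TilePlan,
    schedule: SectionSchedule,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SectionSeries:
    """Render every tile of every block face in serpentine order.

    Per-tile noise streams are spawned deterministically from ``seed`` so the
    whole acquisition is reproducible.  When ``out_dir`` is given, each tile
    is written as an 8/16-bit RGB TIFF and the manifest CSV alongside.
    """
    _, _, bz = phantom.bounding_box
    faces = [z for z in schedule.face_z_um if z < bz]
    if len(faces) < len(schedule.face_z_um):
        warnings.warn(
            "phantom shallower than the section schedule; truncating", stacklevel=2
        )
    root = np.random.SeedSequence(seed)
    images: list[BlockFaceImage] = []
    rows = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    order = tile_plan.serpentine_order()
    streams = iter(root.spawn(len(faces) * len(order)))
    for k, fz in enumerate(faces):
        for (r, c) in order:
            ox_mm, oy_mm = tile_plan.origin_mm(r, c)
            tile_seed = int(next(streams).generate_state(1)[0] % (2**31))
            img = render_block_face(
                phantom,
                face_z_um=fz,
                config=config,
                tile_origin_um=(ox_mm * 1000.0, oy_mm * 1000.0),
                seed=tile_seed,
                section_index=k,
                tile_index=(r, c),
            )
            images.append(img)
            fname = f"s{k:04d}_r{r:02d}_c{c:02d}.tif"
            if out is not None:
                tifffile.imwrite(
                    out / fname,
                    img.rgb,
                    metadata={
                        "face_z_um": fz,
                        "tile_origin_um": list(img.tile_origin_um),
                        "section_index": k,
                    },
                )
            rows.append(
                {
                    "section_index": k,
                    "tile_row": r,
                    "tile_col": c,
                    "origin_x_mm": ox_mm,
                    "origin_y_mm": oy_mm,
                    "face_z_um": fz,
                    "file": fname,
                }
            )
    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return SectionSeries(images=images, manifest=manifest, tile_plan=tile_plan, schedule=schedule)
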