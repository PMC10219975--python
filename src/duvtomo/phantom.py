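"""Ground-truth 3D scenes for the virtual block-face microscope.

A phantom is a bounding box (µm) containing point-like emitters: cells with a
nuclear and a perikaryal (Nissl-like) compartment, and optionally fluorescent
calibration beads.  Regions of differing nominal cell density stand in for
anatomical structures (e.g. a medial/lateral habenula pair); a rasterized
region-label volume stands in for an anatomical atlas.

Coordinates are right-handed, in µm, 0-based; ``z = 0`` is the current block
face and increases into the block.  Rasters are indexed ``(row=y, col=x)``
with half-open pixel intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CellSpec",
    "RegionModel",
    "Bead",
    "TissuePhantom",
    "generate_tissue_phantom",
    "generate_bead_phantom",
    "voxelize_labels",
    "region_label_image",
    "ground_truth_section_table",
    "habenula_region_pair",
]

# intensity heterogeneity across and within cells: lognormal jitter on the
# per-cell dye amplitudes
DEFAULT_SIGMA_LOG = 0.3


@dataclass(frozen=True)
class CellSpec:
    """One cell: nuclear sphere inside a somatic (Nissl-rim) sphere."""

    center: tuple[float, float, float]  # (x, y, z) µm; z = depth below face
    nucleus_radius: float  # µm
    soma_radius: float  # µm, >= nucleus_radius
    dye_amplitudes: tuple[float, ...]  # per-dye emission strength, a.u.
    region_id: int = 0

    def __post_init__(self) -> None:
        if not (self.soma_radius >= self.nucleus_radius > 0):
            raise ValueError(
                "require soma_radius >= nucleus_radius > 0, got "
                f"{self.soma_radius} / {self.nucleus_radius}"
            )
        if any(a < 0 for a in self.dye_amplitudes):
            raise ValueError("dye amplitudes must be >= 0")


@dataclass(frozen=True)
class Bead:
    """Uniform fluorescent microsphere (calibration target)."""

    center: tuple[float, float, float]
    diameter: float = 4.0  # µm
    amplitude: float = 1.0


@dataclass(frozen=True)
class RegionModel:
    """Axis-aligned sub-volume with a nominal cell density.

    ``bounds`` is ``((x0, x1), (y0, y1), (z0, z1))`` in µm within the phantom
    bounding box.  ``nominal_density`` is cells per mm³.  ``dye_profile`` gives
    the mean amplitude per dye.
    """

    region_id: int
    nominal_density: float  # cells / mm^3
    bounds: tuple[tuple[float, float], tuple[float, float], tuple[float, float]]
    dye_profile: tuple[float, ...] = (1.0,)
    nucleus_radius: float = 3.0  # µm
    soma_radius: float = 5.0  # µm

    def __post_init__(self) -> None:
        if self.nominal_density < 0:
            raise ValueError("density must be >= 0")
        if self.region_id <= 0:
            raise ValueError("region_id must be a positive integer (0 = background)")
        for lo, hi in self.bounds:
            if not hi > lo:
                raise ValueError(f"zero/negative region extent: ({lo}, {hi})")

    @property
    def volume_mm3(self) -> float:
        v_um3 = 1.0
        for lo, hi in self.bounds:
            v_um3 *= hi - lo
        return v_um3 * 1e-9

    def overlaps(self, other: "RegionModel") -> bool:
        for (a0, a1), (b0, b1) in zip(self.bounds, other.bounds):
            if a1 <= b0 or b1 <= a0:
                return False
        return True


@dataclass
class TissuePhantom:
    """Ground-truth scene: bounding box, cells, beads, region geometry."""

    bounding_box: tuple[float, float, float]  # (x, y, z) extents, µm
    cells: list[CellSpec] = field(default_factory=list)
    beads: list[Bead] = field(default_factory=list)
    regions: list[RegionModel] = field(default_factory=list)
    n_dyes: int = 1
    seed: int | None = None

    def __post_init__(self) -> None:
        bx, by, bz = self.bounding_box
        if not (bx > 0 and by > 0 and bz > 0):
            raise ValueError("bounding box extents must be > 0")
        for c in self.cells:
            if not all(0 <= p <= b for p, b in zip(c.center, self.bounding_box)):
                raise ValueError(f"cell at {c.center} outside bounding box")
        for b in self.beads:
            if not all(0 <= p <= e for p, e in zip(b.center, self.bounding_box)):
                raise ValueError(f"bead at {b.center} outside bounding box")

    def cells_in_region(self, region_id: int) -> list[CellSpec]:
        return [c for c in self.cells if c.region_id == region_id]


def habenula_region_pair(
    box: tuple[float, float, float] = (800.0, 400.0, 500.0),
    density_high: float = 30_000.0,
    density_low: float = 15_000.0,
    n_dyes: int = 1,
) -> list[RegionModel]:
    """Default two-region fixture with a 2:1 density contrast.

    Emulates the medial/lateral habenula pair: a denser medial-like region and
    a sparser lateral-like region, side by side along x, each filling half the
    box.  Absolute densities are package defaults (not measured values),
    chosen so that the cells visible on a block face occupy ~12% of the
    frame — dense enough that cells touch, sparse enough to segment.
    """
    bx, by, bz = box
    profile = tuple(1.0 for _ in range(n_dyes))
    return [
        RegionModel(1, density_high, ((0.0, bx / 2), (0.0, by), (0.0, bz)), profile),
        RegionModel(2, density_low, ((bx / 2, bx), (0.0, by), (0.0, bz)), profile),
    ]


def generate_tissue_phantom(
    box: tuple[float, float, float],
    regions: list[RegionModel],
    seed: int,
    sigma_log: float = DEFAULT_SIGMA_LOG,
) -> TissuePhantom:
    """Draw a random tissue phantom.

    Per region the cell count is Poisson(density x volume), positions are
    uniform within the region, and per-cell dye amplitudes are the region's
    ``dye_profile`` with multiplicative lognormal jitter (sigma of log =
    ``sigma_log``).  Cells may touch — overlap is not prevented, as in real
    tissue.  Deterministic for a fixed seed.
    """
    for i, r in enumerate(regions):
        for s in regions[i + 1:]:
            if r.overlaps(s):
                raise ValueError(
                    f"regions {r.region_id} and {s.region_id} overlap"
                )
        for (lo, hi), ext in zip(r.bounds, box):
            if lo < 0 or hi > ext:
                raise ValueError(f"region {r.region_id} exceeds bounding box")

    rng = np.random.default_rng(seed)
    n_dyes = max((len(r.dye_profile) for r in regions), default=1)
    cells: list[CellSpec] = []
    for r in regions:
        n = rng.poisson(r.nominal_density * r.volume_mm3)
        lows = np.array([b[0] for b in r.bounds])
        highs = np.array([b[1] for b in r.bounds])
        pos = rng.uniform(lows, highs, size=(n, 3))
        jitter = rng.lognormal(mean=0.0, sigma=sigma_log, size=(n, len(r.dye_profile)))
        amps = np.asarray(r.dye_profile) * jitter
        for k in range(n):
            a = np.zeros(n_dyes)
            a[: len(r.dye_profile)] = amps[k]
            cells.append(
                CellSpec(
                    center=tuple(pos[k]),
                    nucleus_radius=r.nucleus_radius,
                    soma_radius=r.soma_radius,
                    dye_amplitudes=tuple(a),
                    region_id=r.region_id,
                )
            )
    return TissuePhantom(
        bounding_box=box, cells=cells, regions=list(regions), n_dyes=n_dyes, seed=seed
    )


def generate_bead_phantom(
    n_beads: int,
    box: tuple[float, float, float],
    diameter_um: float = 4.0,
    min_separation: float | None = None,
    amplitude: float = 1.0,
    seed: int = 0,
    max_tries: int = 10_000,
) -> TissuePhantom:
    """Place ``n_beads`` fluorescent microspheres at random, well separated.

    Default diameter 4 µm (TetraSpeck-like calibration beads in agarose).
    Rejection sampling enforces pairwise separation >= ``min_separation``
    (default 4x the diameter); raises if the box cannot host the requested
    beads within a bounded number of tries.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    if min_separation is None:
        min_separation = 4.0 * diameter_um
    if min_separation <= diameter_um:
        raise ValueError("min_separation must exceed the bead diameter")
    rng = np.random.default_rng(seed)
    margin = diameter_um / 2
    lo = np.full(3, margin)
    hi = np.asarray(box) - margin
    if np.any(hi <= lo):
        raise ValueError("box too small for the bead diameter")
    placed: list[np.ndarray] = []
    tries = 0
    while len(placed) < n_beads:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_beads} beads at separation "
                f"{min_separation} µm in box {box} after {max_tries} tries"
            )
        tries += 1
        p = rng.uniform(lo, hi)
        if all(np.linalg.norm(p - q) >= min_separation for q in placed):
            placed.append(p)
    beads = [Bead(center=tuple(p), diameter=diameter_um, amplitude=amplitude) for p in placed]
    return TissuePhantom(bounding_box=box, beads=beads, seed=seed)


def voxelize_labels(phantom: TissuePhantom, spacing_um: float) -> np.ndarray:
    """Rasterize region geometry to a (z, y, x) integer label volume.

    Each voxel carries the region_id of its center point; background is 0.
    """
    if spacing_um <= 0:
        raise ValueError("spacing must be > 0")
    bx, by, bz = phantom.bounding_box
    for r in phantom.regions:
        min_ext = min(hi - lo for lo, hi in r.bounds)
        if spacing_um > min_ext:
            warnings.warn(
                f"voxel spacing {spacing_um} µm exceeds the smallest extent of "
                f"region {r.region_id}; it may vanish from the raster",
                stacklevel=2,
            )
    nx = max(1, int(round(bx / spacing_um)))
    ny = max(1, int(round(by / spacing_um)))
    nz = max(1, int(round(bz / spacing_um)))
    labels = np.zeros((nz, ny, nx), dtype=np.int32)
    xc = (np.arange(nx) + 0.5) * spacing_um
    yc = (np.arange(ny) + 0.5) * spacing_um
    zc = (np.arange(nz) + 0.5) * spacing_um
    for r in phantom.regions:
        (x0, x1), (y0, y1), (z0, z1) = r.bounds
        ix = (xc >= x0) & (xc < x1)
        iy = (yc >= y0) & (yc < y1)
        iz = (zc >= z0) & (zc < z1)
        labels[np.ix_(iz, iy, ix)] = r.region_id
    return labels


def region_label_image(
    phantom: TissuePhantom, pixel_size_um: float, shape: tuple[int, int]
) -> np.ndarray:
    """2D (y, x) region-label image on a given pixel grid (atlas per section)."""
    ny, nx = shape
    xc = (np.arange(nx) + 0.5) * pixel_size_um
    yc = (np.arange(ny) + 0.5) * pixel_size_um
    labels = np.zeros((ny, nx), dtype=np.int32)
    for r in phantom.regions:
        (x0, x1), (y0, y1), _ = r.bounds
        ix = (xc >= x0) & (xc < x1)
        iy = (yc >= y0) & (yc < y1)
        labels[np.ix_(iy, ix)] = r.region_id
    return labels


def ground_truth_section_table(
    phantom: TissuePhantom,
    face_z_um: np.ndarray | list[float],
    d_um: float,
    visibility_cutoff: float = float(np.exp(-1)),
) -> pd.DataFrame:
    """Expected per-section visibility of every cell.

    A cell is expected-visible in section ``k`` iff its depth below that block
    face lies in ``[0, z*)`` where ``exp(-z*/d) = visibility_cutoff`` — i.e.
    down to the depth at which surface-excitation attenuation reduces its
    signal below the cutoff.  With section thickness > z* each cell appears in
    at most one section.
    """
    if d_um <= 0:
        raise ValueError("d_um must be > 0")
    if not (0 < visibility_cutoff < 1):
        raise ValueError("visibility_cutoff must lie in (0, 1)")
    faces = np.atleast_1d(np.asarray(face_z_um, dtype=float))
    if faces.size == 0:
        raise ValueError("face_z_um must be non-empty")
    if faces.size > 1 and np.any(np.diff(faces) <= 0):
        raise ValueError("face positions must be strictly increasing")
    z_star = -d_um * np.log(visibility_cutoff)
    rows = []
    for idx, c in enumerate(phantom.cells):
        for k, fz in enumerate(faces):
            depth = c.center[2] - fz
            if 0 <= depth < z_star:
                rows.append(
                    {
                        "cell_index": idx,
                        "section_index": k,
                        "depth_um": depth,
                        "x_um": c.center[0],
                        "y_um": c.center[1],
                        "region_id": c.region_id,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["cell_index", "section_index", "depth_um", "x_um", "y_um", "region_id"],
    )
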