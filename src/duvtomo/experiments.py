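"""Reference simulation experiments: parameter recovery on synthetic data.

The instrument-characterization measurements (bead FWHM, 1/e sectioning
depth, depth correlation, regional density contrast) are ordinarily made on
real tissue; here the package validates itself by closing the loop on
synthetic scenes instead: generate a phantom with known parameters, image it
with the forward model, run the analysis, and compare the recovered values
with the ground truth.  These experiment functions define the canonical
study conditions and are shared by the test suite and the acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import calibrate, quantify, stitch
from .acquisition import plan_tiles, schedule_sections, run_virtual_acquisition
from .optics import OpticalConfig, render_block_face, render_reference_stack
from .phantom import (
    Bead,
    CellSpec,
    TissuePhantom,
    generate_tissue_phantom,
    habenula_region_pair,
    region_label_image,
)

__all__ = [
    "fixture_optical_config",
    "sectioning_depth_recovery",
    "bead_fwhm_recovery",
    "depth_correlation_experiment",
    "habenula_contrast_experiment",
    "welch_type_i_error",
]


def fixture_optical_config(**overrides) -> OpticalConfig:
    """Small-field configuration used by the recovery experiments.

    Same optics as the reference setup (d = 20 µm, sigma = 1.5/1.5/13 µm)
    but a 1 µm pixel grid over a few hundred µm so a study runs in seconds.
    Noise at a realistic 8-bit level: shot noise at ~30 detected photons per
    grey level near saturation plus ~1 grey level of read noise.
    """
    defaults = dict(
        pixel_size_um=1.0,
        fov_px=(400, 200),
        illumination_ramp=0.15,
        vignette=0.05,
        photon_scale=0.5,
        read_noise=1.0,
        offset=2.0,
        gain=3.0,
    )
    defaults.update(overrides)
    return OpticalConfig(**defaults)


def _scatter_cells(
    n_cells: int,
    box: tuple[float, float, float],
    depth_range: tuple[float, float],
    rng: np.random.Generator,
    sigma_log: float = 0.3,
    nucleus_radius: float = 3.0,
    soma_radius: float = 5.0,
) -> TissuePhantom:
    xy = rng.uniform(
        [soma_radius, soma_radius], [box[0] - soma_radius, box[1] - soma_radius], size=(n_cells, 2)
    )
    z = rng.uniform(*depth_range, size=n_cells)
    amps = rng.lognormal(0.0, sigma_log, size=n_cells)
    cells = [
        CellSpec(
            center=(xy[i, 0], xy[i, 1], z[i]),
            nucleus_radius=nucleus_radius,
            soma_radius=soma_radius,
            dye_amplitudes=(amps[i],),
        )
        for i in range(n_cells)
    ]
    return TissuePhantom(bounding_box=box, cells=cells, n_dyes=1)


def sectioning_depth_recovery(
    d_um: float,
    seed: int,
    n_cells: int = 500,
    sigma_log: float = 0.3,
    config: OpticalConfig | None = None,
) -> calibrate.AttenuationFit:
    """One recovery run of the 1/e optical-sectioning-thickness estimate.

    ``n_cells`` whole cells with lognormal amplitude jitter are scattered
    over depths [R, R + 2d] (R = soma radius); the block face is rendered
    with attenuation depth ``d_um``; each cell's median intensity is
    measured in a small disk at its known lateral position and regressed
    against its ground-truth depth (the synthetic stand-in for depths
    located in a confocal stack).
    """
    rng = np.random.default_rng(seed)
    if config is None:
        config = fixture_optical_config(
            attenuation_depth_um=d_um, fov_px=(512, 512), gain=25.0
        )
    else:
        config = config.with_(attenuation_depth_um=d_um)
    box = (config.fov_um[0], config.fov_um[1], 5 * d_um + 50)
    # whole cells only: a cell cut by the blade loses part of its volume and
    # no longer follows I(z) = I0 exp(-z/d), biasing the fit
    soma_r = 5.0
    phantom = _scatter_cells(
        n_cells, box, (soma_r, soma_r + 2.0 * d_um), rng, sigma_log
    )
    img = render_block_face(
        phantom, 0.0, config, seed=int(rng.integers(2**31))
    ).rgb[:, :, 0].astype(float)
    img = img - np.median(img)  # remove camera offset/background pedestal

    px = config.pixel_size_um
    rad_px = int(round(phantom.cells[0].nucleus_radius / px))
    yy, xx = np.mgrid[-rad_px : rad_px + 1, -rad_px : rad_px + 1]
    disk = yy**2 + xx**2 <= rad_px**2
    rows = []
    for c in phantom.cells:
        cx = int(c.center[0] / px)
        cy = int(c.center[1] / px)
        if (
            rad_px <= cx < img.shape[1] - rad_px
            and rad_px <= cy < img.shape[0] - rad_px
        ):
            patch = img[cy - rad_px : cy + rad_px + 1, cx - rad_px : cx + rad_px + 1]
            rows.append(
                {"depth_um": c.center[2], "intensity": float(np.median(patch[disk]))}
            )
    table = pd.DataFrame(rows)
    return calibrate.estimate_sectioning_thickness(table, bin_width_um=2.0)


def bead_fwhm_recovery(
    seed: int = 0,
    n_beads: int = 10,
    diameter_um: float = 4.0,
    psf_sigma_um: tuple[float, float, float] = (1.5, 1.5, 13.0),
    z_spacing_um: float = 2.0,
    noise: float = 0.5,
) -> tuple[dict[str, calibrate.GaussianFit], dict[str, float]]:
    """Recover per-axis FWHM from a simulated bead z-stack.

    Ten 4 µm beads in a clear (agarose-like) volume are imaged as a z-stack
    with the given PSF; beads are detected, profiles averaged and Gaussian
    fit.  Returns the fits and the ground-truth FWHM of the bead-convolved
    profile per axis, computed by dense numerical evaluation of the
    noiseless forward model (the independent truth the fits are judged
    against).
    """
    rng = np.random.default_rng(seed)
    sx, sy, sz = psf_sigma_um
    box = (200.0, 200.0, 160.0)
    # jittered lateral grid, z clear of the stack limits: well separated yet random
    cols = int(np.ceil(np.sqrt(n_beads)))
    rows = int(np.ceil(n_beads / cols))
    beads = []
    for i in range(n_beads):
        gx = (i % cols + 0.5) * box[0] / cols + rng.uniform(-8, 8)
        gy = (i // cols + 0.5) * box[1] / rows + rng.uniform(-8, 8)
        gz = rng.uniform(60.0, 100.0)
        beads.append(Bead(center=(gx, gy, gz), diameter=diameter_um, amplitude=1.0))
    phantom = TissuePhantom(bounding_box=box, beads=beads, n_dyes=1)
    config = OpticalConfig(
        psf_sigma_um=psf_sigma_um,
        pixel_size_um=1.0,
        fov_px=(200, 200),
        illumination_ramp=0.0,
        vignette=0.0,
        gain=200.0,
    )
    zs = np.arange(0.0, box[2], z_spacing_um)
    stack = render_reference_stack(phantom, config, zs)[:, :, :, 0]
    if noise > 0:
        stack = stack + rng.normal(0.0, noise, size=stack.shape)
    centroids = calibrate.detect_beads(stack, min_separation=8.0)
    fits = calibrate.profile_psf(
        stack, centroids, spacing_um=(z_spacing_um, 1.0, 1.0), half_width=30
    )

    r = diameter_um / 2.0

    def lateral_truth(sigma: float) -> float:
        # profile through the centre of a sphere ⊗ Gaussian, evaluated densely
        x = np.linspace(-6 * sigma - r, 6 * sigma + r, 4001)
        u = np.linspace(-r, r, 2001)
        chord = 2.0 * np.sqrt(np.clip(r * r - u * u, 0, None))
        prof = np.array(
            [np.trapezoid(chord * np.exp(-0.5 * ((xi - u) / sigma) ** 2), u) for xi in x]
        )
        return _fwhm_numeric(x, prof)

    def axial_truth(sigma: float) -> float:
        # axial response: disk area at depth u, sectioned by the axial Gaussian
        z = np.linspace(-6 * sigma - r, 6 * sigma + r, 4001)
        u = np.linspace(-r, r, 2001)
        area = np.pi * np.clip(r * r - u * u, 0, None)
        prof = np.array(
            [np.trapezoid(area * np.exp(-0.5 * ((zi - u) / sigma) ** 2), u) for zi in z]
        )
        return _fwhm_numeric(z, prof)

    truth = {
        "x": lateral_truth(sx),
        "y": lateral_truth(sy),
        "z": axial_truth(sz),
    }
    return fits, truth


def _fwhm_numeric(x: np.ndarray, y: np.ndarray) -> float:
    half = y.max() / 2.0
    above = y >= half
    i0 = int(np.argmax(above))
    i1 = len(y) - 1 - int(np.argmax(above[::-1]))

    def cross(i, j):
        return x[i] + (half - y[i]) * (x[j] - x[i]) / (y[j] - y[i])

    left = cross(i0 - 1, i0) if i0 > 0 else x[0]
    right = cross(i1 + 1, i1) if i1 < len(y) - 1 else x[-1]
    return float(right - left)


def depth_correlation_experiment(
    d_um: float = 20.0,
    seed: int = 0,
    n_cells: int = 400,
    z_spacing_um: float = 2.0,
    max_depth_um: float = 40.0,
    confocal_sigma_z_um: float = 2.0,
) -> calibrate.DepthCorrelationProfile:
    """Block-face image vs reference z-stack similarity as a function of depth.

    A noiseless render of a cell field is compared against the co-registered
    confocal-surrogate stack (tight axial sectioning,
    ``confocal_sigma_z_um``).  The profile peaks at the shallowest slices —
    within one cell radius of the face, where the blade has cut into the
    cells — and falls off beyond the attenuation depth.  The whole frame
    enters the correlation: the synthetic background is clean, so no
    foreground mask is needed.
    """
    rng = np.random.default_rng(seed)
    config = fixture_optical_config(
        attenuation_depth_um=d_um,
        fov_px=(256, 256),
        illumination_ramp=0.0,
        vignette=0.0,
        photon_scale=0.0,
        read_noise=0.0,
        offset=0.0,
    )
    # block face below the top of the box: the microtome has cut through the
    # shallowest cells, whose remnant caps dominate the surface image
    face_z = 6.0
    box = (256.0, 256.0, face_z + max_depth_um + 30.0)
    phantom = _scatter_cells(n_cells, box, (0.0, face_z + max_depth_um), rng)
    surface = render_block_face(phantom, face_z, config, quantize=False).rgb
    depths = np.arange(0.0, max_depth_um + z_spacing_um, z_spacing_um)
    confocal = config.with_(
        psf_sigma_um=(config.psf_sigma_um[0], config.psf_sigma_um[1], confocal_sigma_z_um)
    )
    stack = render_reference_stack(
        phantom, confocal, face_z + depths, surface_z_um=face_z
    )
    return calibrate.correlation_vs_depth(
        surface, stack, depths, foreground_quantile=0.0
    )


@dataclass
class ContrastResult:
    """Outcome of the two-region density-contrast study."""

    counts: pd.DataFrame  # per (section, region): count, area, density
    density_ratio: float  # mean over sections of dense/sparse density
    t: float
    df: int
    p: float
    true_ratio: float
    per_section_truth: pd.DataFrame


def habenula_contrast_experiment(
    seed: int = 0,
    n_sections: int = 10,
    thickness_um: float = 50.0,
    density_high: float = 30_000.0,
    density_low: float = 15_000.0,
    box_xy_um: tuple[float, float] = (800.0, 400.0),
) -> ContrastResult:
    """End-to-end recovery of a 2:1 regional density contrast.

    A two-region phantom (dense medial-like vs sparse lateral-like block) is
    serially sectioned and imaged, tiles are stitched, cells segmented on
    the red channel, assigned to regions by the synthetic atlas, and the
    per-section densities compared with a paired t-test across sections —
    the full chain from virtual acquisition to statistics.

    The default densities keep the imaged cell occupancy near 12% of the
    frame (density x imaged depth x blurred cell footprint), where touching
    somas are still separable by the watershed; the 0.16 mm² regions give
    section counts large enough that Poisson fluctuations stay well inside
    the contrast.
    """
    rng = np.random.default_rng(seed)
    box = (box_xy_um[0], box_xy_um[1], n_sections * thickness_um)
    regions = habenula_region_pair(box, density_high, density_low)
    phantom = generate_tissue_phantom(box, regions, seed=int(rng.integers(2**31)))

    config = fixture_optical_config(fov_px=(240, 200), pixel_size_um=1.0)
    plan = plan_tiles(
        (box[0] / 1000.0, box[1] / 1000.0),
        (config.fov_um[0] / 1000.0, config.fov_um[1] / 1000.0),
        overlap_fraction=0.20,
    )
    schedule = schedule_sections(box[2], thickness_um)
    series = run_virtual_acquisition(
        phantom, config, plan, schedule, seed=int(rng.integers(2**31))
    )

    px = config.pixel_size_um
    atlas = region_label_image(
        phantom, px, (int(round(box[1] / px)), int(round(box[0] / px)))
    )
    area_mm2 = {
        r.region_id: (r.bounds[0][1] - r.bounds[0][0])
        * (r.bounds[1][1] - r.bounds[1][0])
        * 1e-6
        for r in regions
    }
    params = quantify.SegmentationParams(min_area_um2=15.0, max_area_um2=500.0)
    all_cells = []
    for k in range(schedule.n_sections):
        tiles = {im.tile_index: im.rgb for im in series.section(k)}
        if len(tiles) > 1:
            mosaic, _ = stitch.stitch_section(tiles, plan, px)
        else:
            mosaic = np.asarray(next(iter(tiles.values())), dtype=float)
        _, cells = quantify.segment_cells(mosaic, pixel_size_um=px, params=params)
        cells = quantify.assign_regions(cells, atlas, pixel_size_um=px)
        cells["section_index"] = k
        all_cells.append(cells)
    cell_table = pd.concat(all_cells, ignore_index=True)
    counts = quantify.count_and_density(cell_table, area_mm2)

    dense = (
        counts[counts["region_id"] == 1]
        .set_index("section_index")["density_per_mm2"]
        .reindex(range(n_sections), fill_value=0.0)
    )
    sparse = (
        counts[counts["region_id"] == 2]
        .set_index("section_index")["density_per_mm2"]
        .reindex(range(n_sections), fill_value=0.0)
    )
    t, df, p = quantify.paired_t(dense.to_numpy(), sparse.to_numpy())
    ratio = float(dense.mean() / sparse.mean())

    truth_rows = []
    for k, fz in enumerate(schedule.face_z_um):
        for r in regions:
            n_vis = sum(
                1
                for c in phantom.cells
                if c.region_id == r.region_id and 0 <= c.center[2] - fz < 20.0
            )
            truth_rows.append(
                {"section_index": k, "region_id": r.region_id, "visible_cells": n_vis}
            )
    return ContrastResult(
        counts=counts,
        density_ratio=ratio,
        t=t,
        df=df,
        p=p,
        true_ratio=density_high / density_low,
        per_section_truth=pd.DataFrame(truth_rows),
    )


def welch_type_i_error(
    n_replicates: int = 1000,
    n_per_group: int = 10,
    n_groups: int = 3,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Empirical type-I error of the Welch ANOVA under the null.

    All groups are drawn from the same normal distribution; the rejection
    rate at ``alpha`` should match ``alpha``.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        groups = [rng.normal(size=n_per_group) for _ in range(n_groups)]
        _, _, _, p = quantify.welch_anova(*groups)
        if p < alpha:
            rejections += 1
    return rejections / n_replicates
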