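"""Forward model of the DUV surface-excitation microscope.

Deep-UV light (~280 nm) is absorbed within the first tens of microns of
tissue, so only emitters near the freshly cut block face fluoresce: the
excitation follows Beer–Lambert decay ``exp(-z/d)`` with 1/e depth ``d``
(default 20 µm).  A cell is rendered as a nuclear sphere plus a Nissl-like
spherical shell between the nucleus and the soma radius; the contribution of a
sphere at a pixel is the closed-form integral of ``exp(-z/d)`` along the
sphere's depth chord, so depth attenuation is exact rather than discretized.

The module also renders reference z-stacks that emulate a confocal
microscope: each slice sections the volume with an axial Gaussian (no
Beer–Lambert attenuation), on the same lateral pixel grid, so block-face and
reference images are co-registered by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.special import erf

__all__ = [
    "OpticalConfig",
    "BlockFaceImage",
    "depth_weight",
    "render_block_face",
    "render_reference_stack",
    "apply_mixing",
    "mixing_matrix_from_peaks",
    "default_optical_config",
    "EMISSION_PEAKS_NM",
]

# emission maxima of the default dye set: Hoechst 33258, propidium iodide,
# Alexa Fluor 594 (nm)
EMISSION_PEAKS_NM = {"hoechst": 496.0, "pi": 659.0, "af594": 613.0}

# PI first: the Nissl-like counterstain used for cell counting (red channel)
DEFAULT_DYE_ORDER = ("pi", "hoechst", "af594")

# idealized camera passbands (nm): R, G, B
_PASSBANDS = ((580.0, 700.0), (480.0, 580.0), (400.0, 480.0))


def mixing_matrix_from_peaks(
    peaks_nm: tuple[float, ...], emission_sigma_nm: float = 30.0
) -> np.ndarray:
    """Build a (3, n_dyes) dye -> RGB mixing matrix from emission peaks.

    Each dye's emission spectrum is modelled as a Gaussian around its peak;
    rows integrate that spectrum over idealized R/G/B passbands and each
    column is normalized so its strongest channel is 1.
    """
    m = np.zeros((3, len(peaks_nm)))
    s = emission_sigma_nm * np.sqrt(2.0)
    for j, peak in enumerate(peaks_nm):
        for i, (lo, hi) in enumerate(_PASSBANDS):
            m[i, j] = 0.5 * (erf((hi - peak) / s) - erf((lo - peak) / s))
    col_max = m.max(axis=0)
    col_max[col_max == 0] = 1.0
    return m / col_max


@dataclass(frozen=True)
class OpticalConfig:
    """Forward-model parameters of one imaging configuration.

    ``attenuation_depth_um`` is the Beer–Lambert 1/e depth of the DUV
    excitation (20 µm for the reference setup).  ``psf_sigma_um`` holds the
    lateral and axial Gaussian PSF sigmas.  ``illumination_ramp`` is the
    fractional gain variation across the field from the oblique (60°) side
    illumination; ``vignette`` the radial fall-off at the field corners.
    ``exposure_ms`` and ``power_mw`` are metadata only — no radiometric model
    is attempted.
    """

    attenuation_depth_um: float = 20.0
    psf_sigma_um: tuple[float, float, float] = (1.5, 1.5, 13.0)  # (x, y, z)
    pixel_size_um: float = 1.3  # FOV 1.3 mm over a 1000 px sensor row
    fov_px: tuple[int, int] = (1000, 769)  # (width, height) ~ 1.3 x 1.0 mm
    illumination_ramp: float = 0.15
    illumination_angle_deg: float = 60.0
    vignette: float = 0.05
    mixing_matrix: np.ndarray | None = None  # None: built from dye emission peaks
    photon_scale: float = 0.0  # photons per intensity unit; 0 = no shot noise
    read_noise: float = 0.0  # Gaussian read noise sigma, intensity units
    offset: float = 0.0  # camera black level, intensity units
    bit_depth: int = 8
    gain: float = 1.0  # intensity units per unit emission
    exposure_ms: float = 30.0
    power_mw: float = 8.13

    def __post_init__(self) -> None:
        if self.attenuation_depth_um <= 0:
            raise ValueError("attenuation depth must be > 0")
        if any(s <= 0 for s in self.psf_sigma_um):
            raise ValueError("PSF sigmas must be > 0")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be > 0")
        if self.mixing_matrix is not None and np.any(np.asarray(self.mixing_matrix) < 0):
            raise ValueError("mixing matrix entries must be >= 0")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit depth must be 8 or 16")

    @property
    def max_value(self) -> int:
        return (1 << self.bit_depth) - 1

    @property
    def fov_um(self) -> tuple[float, float]:
        return (self.fov_px[0] * self.pixel_size_um, self.fov_px[1] * self.pixel_size_um)

    def with_(self, **kwargs) -> "OpticalConfig":
        return replace(self, **kwargs)

    def mixing_for(self, n_dyes: int) -> np.ndarray:
        """The (3, n_dyes) mixing matrix, built from the default dye set
        (PI, Hoechst, AF594, cycled) when none was supplied explicitly."""
        if self.mixing_matrix is not None:
            m = np.asarray(self.mixing_matrix, dtype=float)
            if m.shape != (3, n_dyes):
                raise ValueError(
                    f"mixing matrix shape {m.shape} incompatible with {n_dyes} dyes"
                )
            return m
        peaks = tuple(
            EMISSION_PEAKS_NM[DEFAULT_DYE_ORDER[j % len(DEFAULT_DYE_ORDER)]]
            for j in range(n_dyes)
        )
        return mixing_matrix_from_peaks(peaks)


def default_optical_config(**overrides) -> OpticalConfig:
    """Reference 10x configuration (d = 20 µm, ~1.3 x 1.0 mm FOV)."""
    return OpticalConfig(**overrides)


@dataclass
class BlockFaceImage:
    """One acquired block-face tile: RGB raster plus placement metadata."""

    rgb: np.ndarray  # (height, width, 3), quantized
    tile_origin_um: tuple[float, float]
    face_z_um: float
    section_index: int = 0
    tile_index: tuple[int, int] = (0, 0)  # (row, col) in the tile grid
    channels: tuple[str, ...] = ("R", "G", "B")


def depth_weight(z_um: np.ndarray | float, d_um: float) -> np.ndarray | float:
    """Beer–Lambert excitation weight ``exp(-z/d)`` at depth z below the face."""
    if d_um <= 0:
        raise ValueError("attenuation depth must be > 0")
    z = np.asarray(z_um, dtype=float)
    if np.any(z < 0):
        raise ValueError("depth below the block face must be >= 0")
    w = np.exp(-z / d_um)
    return float(w) if np.isscalar(z_um) else w


def _chord_bounds(r2: np.ndarray, zc: float, radius: float):
    """Entry/exit depths of vertical chords through a sphere.

    ``r2`` is the squared lateral distance from the sphere axis; returns
    (z1, z2) arrays with z1=z2 outside the silhouette.
    """
    h2 = radius * radius - r2
    h = np.sqrt(np.clip(h2, 0.0, None))
    return zc - h, zc + h


def _attenuated_chord(r2: np.ndarray, zc: float, radius: float, d: float) -> np.ndarray:
    """∫ exp(-z/d) dz along each chord, clipped to z >= 0 (above-face part absent)."""
    z1, z2 = _chord_bounds(r2, zc, radius)
    z1 = np.clip(z1, 0.0, None)
    z2 = np.clip(z2, 0.0, None)
    return d * (np.exp(-z1 / d) - np.exp(-z2 / d))


def _sectioned_chord(
    r2: np.ndarray,
    zc: float,
    radius: float,
    z_plane: float,
    sigma_z: float,
    surface_z: float | None = None,
) -> np.ndarray:
    """∫ exp(-(z - z_plane)^2 / 2σz^2) dz along each chord (axial sectioning)."""
    z1, z2 = _chord_bounds(r2, zc, radius)
    if surface_z is not None:  # material above the cut face has been removed
        z1 = np.clip(z1, surface_z, None)
        z2 = np.clip(z2, surface_z, None)
    s = sigma_z * np.sqrt(2.0)
    return (
        sigma_z
        * np.sqrt(np.pi / 2.0)
        * (erf((z2 - z_plane) / s) - erf((z1 - z_plane) / s))
    )


def _render_dye_fields(
    phantom,
    config: OpticalConfig,
    tile_origin_um: tuple[float, float],
    weight_fn,
) -> np.ndarray:
    """Accumulate per-dye emission images (n_dyes, h, w) before PSF/noise.

    ``weight_fn(r2_patch, zc_rel, radius)`` returns the depth-integrated
    emission of a sphere of given radius centred at relative depth ``zc_rel``
    for squared lateral offsets ``r2_patch``.
    """
    w_px, h_px = config.fov_px
    px = config.pixel_size_um
    ox, oy = tile_origin_um
    n_dyes = getattr(phantom, "n_dyes", 1)
    fields = np.zeros((max(n_dyes, 1), h_px, w_px), dtype=np.float64)

    def paint(center, radii_amps):
        # radii_amps: list of (outer_radius, inner_radius, per-dye amplitude array)
        cx = (center[0] - ox) / px - 0.5
        cy = (center[1] - oy) / px - 0.5
        r_max = max(r for r, _, _ in radii_amps)
        rad_px = int(np.ceil(r_max / px)) + 1
        x0, x1 = int(np.floor(cx)) - rad_px, int(np.floor(cx)) + rad_px + 1
        y0, y1 = int(np.floor(cy)) - rad_px, int(np.floor(cy)) + rad_px + 1
        x0, x1 = max(x0, 0), min(x1, w_px)
        y0, y1 = max(y0, 0), min(y1, h_px)
        if x0 >= x1 or y0 >= y1:
            return
        xs = (np.arange(x0, x1) - cx) * px
        ys = (np.arange(y0, y1) - cy) * px
        r2 = ys[:, None] ** 2 + xs[None, :] ** 2
        for r_out, r_in, amps in radii_amps:
            prof = weight_fn(r2, center[2], r_out)
            if r_in > 0:
                prof = prof - weight_fn(r2, center[2], r_in)
            for j, a in enumerate(amps):
                if a > 0:
                    fields[j, y0:y1, x0:x1] += a * prof

    for c in getattr(phantom, "cells", []):
        amps = np.asarray(c.dye_amplitudes, dtype=float)
        # nucleus: filled sphere; Nissl rim: shell between nucleus and soma
        paint(
            c.center,
            [
                (c.nucleus_radius, 0.0, amps),
                (c.soma_radius, c.nucleus_radius, 0.5 * amps),
            ],
        )
    for b in getattr(phantom, "beads", []):
        amps = np.full(max(n_dyes, 1), b.amplitude)
        paint(b.center, [(b.diameter / 2.0, 0.0, amps)])
    return fields


def _illumination_field(config: OpticalConfig) -> np.ndarray:
    """Multiplicative shading: linear ramp along x (oblique side light) + vignette."""
    w_px, h_px = config.fov_px
    x = np.linspace(-0.5, 0.5, w_px)
    y = np.linspace(-0.5, 0.5, h_px)
    ramp = 1.0 + 2.0 * config.illumination_ramp * x[None, :]
    r2 = (x[None, :] ** 2 + y[:, None] ** 2) / 0.5
    vign = 1.0 - config.vignette * r2
    return ramp * vign


def apply_mixing(dye_images: np.ndarray, mixing_matrix: np.ndarray) -> np.ndarray:
    """Map per-dye emission images to RGB: (n_dyes, h, w) -> (h, w, 3)."""
    dye_images = np.asarray(dye_images, dtype=float)
    m = np.asarray(mixing_matrix, dtype=float)
    if dye_images.ndim != 3:
        raise ValueError("dye_images must be (n_dyes, height, width)")
    if m.shape != (3, dye_images.shape[0]):
        raise ValueError(
            f"mixing matrix shape {m.shape} incompatible with {dye_images.shape[0]} dyes"
        )
    return np.einsum("cd,dhw->hwc", m, dye_images)


def _finalize(
    signal_rgb: np.ndarray, config: OpticalConfig, rng: np.random.Generator | None
) -> np.ndarray:
    """Shading, noise, offset and quantization (clip, round half even)."""
    img = signal_rgb * config.gain * _illumination_field(config)[:, :, None]
    if rng is not None and config.photon_scale > 0:
        img = rng.poisson(np.clip(img, 0, None) * config.photon_scale) / config.photon_scale
    img = img + config.offset
    if rng is not None and config.read_noise > 0:
        img = img + rng.normal(0.0, config.read_noise, size=img.shape)
    img = np.clip(img, 0, config.max_value)
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    return np.rint(img).astype(dtype)


def render_block_face(
    phantom,
    face_z_um: float,
    config: OpticalConfig,
    tile_origin_um: tuple[float, float] = (0.0, 0.0),
    seed: int | None = None,
    section_index: int = 0,
    tile_index: tuple[int, int] = (0, 0),
    quantize: bool = True,
) -> BlockFaceImage:
    """Render the block-face image of the tile at ``tile_origin_um``.

    Only emitters near the face contribute: each sphere's emission is the
    exact Beer–Lambert chord integral at its depth below ``face_z_um``,
    blurred by the lateral PSF, shaded by the illumination field, mixed to
    RGB, noised (if configured and seeded) and quantized.  With
    ``quantize=False`` the noiseless float RGB image is returned; shading and
    offset still apply but no noise or rounding is introduced.
    """
    bx, by, _ = phantom.bounding_box
    fx, fy = config.fov_um
    ox, oy = tile_origin_um
    if ox >= bx or oy >= by or ox + fx <= 0 or oy + fy <= 0:
        warnings.warn("tile lies fully outside the phantom; background only", stacklevel=2)

    d = config.attenuation_depth_um

    # shift emitters so depth is measured from the current face; emitters
    # above the face were cut away and do not exist
    class _Shifted:
        bounding_box = phantom.bounding_box
        n_dyes = getattr(phantom, "n_dyes", 1)
        cells = [
            type(c)(
                center=(c.center[0], c.center[1], c.center[2] - face_z_um),
                nucleus_radius=c.nucleus_radius,
                soma_radius=c.soma_radius,
                dye_amplitudes=c.dye_amplitudes,
                region_id=c.region_id,
            )
            for c in getattr(phantom, "cells", [])
            if c.center[2] - face_z_um > -c.soma_radius
        ]
        beads = [
            type(b)(
                center=(b.center[0], b.center[1], b.center[2] - face_z_um),
                diameter=b.diameter,
                amplitude=b.amplitude,
            )
            for b in getattr(phantom, "beads", [])
            if b.center[2] - face_z_um > -b.diameter / 2
        ]

    fields = _render_dye_fields(
        _Shifted,
        config,
        tile_origin_um,
        lambda r2, zc, radius: _attenuated_chord(r2, zc, radius, d),
    )
    sx, sy, _ = config.psf_sigma_um
    px = config.pixel_size_um
    for j in range(fields.shape[0]):
        fields[j] = ndimage.gaussian_filter(fields[j], sigma=(sy / px, sx / px))
    rgb = apply_mixing(fields, config.mixing_for(fields.shape[0]))
    if not quantize:
        rgb = rgb * config.gain * _illumination_field(config)[:, :, None] + config.offset
    else:
        rng = np.random.default_rng(seed) if seed is not None else None
        rgb = _finalize(rgb, config, rng)
    return BlockFaceImage(
        rgb=rgb,
        tile_origin_um=tile_origin_um,
        face_z_um=face_z_um,
        section_index=section_index,
        tile_index=tile_index,
    )


def render_reference_stack(
    phantom,
    config: OpticalConfig,
    z_positions_um: np.ndarray | list[float],
    tile_origin_um: tuple[float, float] = (0.0, 0.0),
    seed: int | None = None,
    quantize: bool = False,
    surface_z_um: float | None = None,
) -> np.ndarray:
    """Render a confocal-surrogate z-stack: (n_slices, h, w, 3).

    Each slice images the plane at its z position with Gaussian axial
    sectioning (sigma = axial PSF) and NO surface-excitation attenuation, on
    the same lateral grid and PSF as the block-face render, so the stack is
    co-registered with the block-face image.  Default slice spacing in
    workflows is 2 µm.
    """
    z_positions = np.asarray(z_positions_um, dtype=float)
    if z_positions.size == 0:
        raise ValueError("z_positions must be non-empty")
    if z_positions.size > 1 and np.any(np.diff(z_positions) <= 0):
        raise ValueError("z_positions must be strictly ascending")
    sx, sy, sz = config.psf_sigma_um
    px = config.pixel_size_um
    rng = np.random.default_rng(seed) if seed is not None else None
    slices = []
    for z in z_positions:
        fields = _render_dye_fields(
            phantom,
            config,
            tile_origin_um,
            lambda r2, zc, radius, _z=z: _sectioned_chord(
                r2, zc, radius, _z, sz, surface_z=surface_z_um
            ),
        )
        for j in range(fields.shape[0]):
            fields[j] = ndimage.gaussian_filter(fields[j], sigma=(sy / px, sx / px))
        rgb = apply_mixing(fields, config.mixing_for(fields.shape[0]))
        if quantize:
            slices.append(_finalize(rgb, config, rng))
        else:
            slices.append(rgb * config.gain + config.offset)
    return np.stack(slices)
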