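"""Per-image corrections preceding stitching and quantification.

Flat-field (shading) correction undoes the multiplicative illumination
pattern of the oblique side light; colour correction is either diagonal
white balance or full linear unmixing against the dye mixing matrix;
extended depth of focus fuses an optional focal stack; 8-bit frames are
promoted to 16 bit losslessly before counting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "FlatFieldModel",
    "flat_field_correct",
    "estimate_flat_field",
    "color_correct",
    "extended_depth_of_focus",
    "to_16bit",
]

_EPS = 1e-6


@dataclass
class FlatFieldModel:
    """Smooth multiplicative gain raster, normalized to mean 1 per channel."""

    gain: np.ndarray  # (h, w) or (h, w, c), > 0, mean 1

    def __post_init__(self) -> None:
        g = np.asarray(self.gain, dtype=float)
        if np.any(g <= 0):
            raise ValueError("flat-field gains must be > 0")
        axes = (0, 1)
        self.gain = g / g.mean(axis=axes, keepdims=True)


def flat_field_correct(image: np.ndarray, field: np.ndarray | FlatFieldModel) -> np.ndarray:
    """Divide out a shading field, preserving the global mean.

    corrected = image / field x mean(field).  Zero or negative field pixels
    are floored to a small epsilon with a warning.
    """
    gain = field.gain if isinstance(field, FlatFieldModel) else np.asarray(field, dtype=float)
    img = np.asarray(image, dtype=float)
    if gain.ndim == 2 and img.ndim == 3:
        gain = gain[:, :, None]
    if gain.shape != img.shape and gain.shape != img.shape[:2] + (1,):
        raise ValueError(f"field shape {gain.shape} does not match image {img.shape}")
    if np.any(gain <= 0):
        warnings.warn("non-positive flat-field pixels floored to epsilon", stacklevel=2)
        gain = np.clip(gain, _EPS, None)
    return img / gain * gain.mean()


def estimate_flat_field(
    tiles: list[np.ndarray] | np.ndarray,
    smooth_frac: float = 0.05,
    min_tiles: int = 10,
) -> FlatFieldModel:
    """Estimate the shading field from a collection of tiles.

    Per-pixel median across tiles (sparse scene content cancels out),
    Gaussian-smoothed with sigma = ``smooth_frac`` of the field width, then
    normalized to mean 1.  Requires at least ``min_tiles`` tiles; with fewer,
    supply an explicit reference instead.
    """
    tiles = np.asarray(tiles, dtype=float)
    if tiles.ndim < 3 or tiles.shape[0] < min_tiles:
        raise ValueError(
            f"need >= {min_tiles} tiles to estimate a flat field; "
            "provide an explicit reference image otherwise"
        )
    med = np.median(tiles, axis=0)
    sigma = smooth_frac * med.shape[1]
    if med.ndim == 3:
        smooth = np.stack(
            [ndimage.gaussian_filter(med[..., c], sigma) for c in range(med.shape[2])],
            axis=-1,
        )
    else:
        smooth = ndimage.gaussian_filter(med, sigma)
    smooth = np.clip(smooth, _EPS, None)
    return FlatFieldModel(gain=smooth)


def color_correct(
    rgb: np.ndarray,
    gains: np.ndarray | tuple[float, float, float] | None = None,
    matrix: np.ndarray | None = None,
) -> np.ndarray:
    """Linear per-pixel colour correction.

    With ``gains`` (default, white balance) each channel is scaled; with a
    3x3 ``matrix`` the pixels are mapped through it — passing the inverse of
    the optics mixing matrix unmixes the channels back to dye abundances.
    """
    img = np.asarray(rgb, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an (h, w, 3) RGB image")
    if matrix is not None:
        m = np.asarray(matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("colour matrix must be 3x3")
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("colour matrix is singular")
        return img @ m.T
    if gains is None:
        gains = (1.0, 1.0, 1.0)
    g = np.asarray(gains, dtype=float)
    if g.shape != (3,) or np.any(g <= 0):
        raise ValueError("gains must be three positive values")
    return img * g


def unmix(rgb: np.ndarray, mixing_matrix: np.ndarray) -> np.ndarray:
    """Recover dye-abundance images from RGB via the inverse mixing matrix."""
    return color_correct(rgb, matrix=np.linalg.inv(np.asarray(mixing_matrix, dtype=float)))


def extended_depth_of_focus(
    stack: np.ndarray, window: int = 9, method: str = "variance"
) -> np.ndarray:
    """Fuse a focal stack into one all-in-focus image.

    ``variance`` (default): per pixel, take the slice maximizing the local
    intensity variance in a ``window`` x ``window`` neighbourhood (a standard
    focus measure; well suited to sparse punctate signal).  ``max``: plain
    per-pixel maximum projection.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim < 3 or stack.shape[0] == 0:
        raise ValueError("stack must be a non-empty (n, h, w[, c]) array")
    if stack.shape[0] == 1:
        return stack[0]
    if method == "max":
        return stack.max(axis=0)
    if method != "variance":
        raise ValueError(f"unknown EDF method: {method!r}")
    if stack.ndim == 4:  # focus measure on luminance, selection on all channels
        lum = stack.mean(axis=-1)
    else:
        lum = stack
    size = (1, window, window)
    mean = ndimage.uniform_filter(lum, size=size)
    var = ndimage.uniform_filter(lum * lum, size=size) - mean * mean
    best = np.argmax(var, axis=0)
    if stack.ndim == 4:
        return np.take_along_axis(stack, best[None, :, :, None], axis=0)[0]
    return np.take_along_axis(stack, best[None], axis=0)[0]


def to_16bit(image8: np.ndarray) -> np.ndarray:
    """Promote an 8-bit image to 16 bit: value x 257 (0 -> 0, 255 -> 65535).

    Spans the full 16-bit range, is order-preserving and exactly invertible
    (divide by 257); downstream quantification is intensity-scale invariant,
    so the scaling choice is inert there.
    """
    img = np.asarray(image8)
    if img.dtype != np.uint8:
        raise TypeError(f"expected a uint8 image, got {img.dtype}")
    return img.astype(np.uint16) * np.uint16(257)
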