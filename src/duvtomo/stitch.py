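"""Tile registration and mosaic assembly.

Overlapping tiles are registered by windowed phase correlation restricted to
a search radius around the nominal grid offset; global tile positions are
accumulated over a maximum-confidence spanning tree and the mosaic is
composited with linear feather blending in the overlaps.  Offsets are
integer-pixel; the contract is that cutting a synthetic section into an
overlapping grid and reassembling it reproduces the original.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .acquisition import TilePlan

__all__ = ["OffsetEstimate", "estimate_offset", "assemble_mosaic", "stitch_section"]


@dataclass(frozen=True)
class OffsetEstimate:
    """Refined translation of tile B relative to tile A, in pixels."""

    dx: int
    dy: int
    confidence: float
    fallback: bool = False


def _to_gray(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    return img.mean(axis=-1) if img.ndim == 3 else img


def estimate_offset(
    tile_a: np.ndarray,
    tile_b: np.ndarray,
    nominal_offset: tuple[int, int] = (0, 0),
    search_radius: int = 20,
    confidence_threshold: float = 3.0,
) -> OffsetEstimate:
    """Refine the translation of ``tile_b`` relative to ``tile_a``.

    Phase correlation with a Hann window; the correlation peak is searched
    within ``search_radius`` px of ``nominal_offset`` (dx, dy, meaning
    tile_b content appears at +dx, +dy in tile_a coordinates).  Confidence is
    the peak height over the mean absolute correlation; below
    ``confidence_threshold`` (e.g. featureless or pure-noise overlap) the
    nominal offset is returned as a fallback with a warning.
    """
    a = _to_gray(tile_a)
    b = _to_gray(tile_b)
    if a.shape != b.shape:
        raise ValueError("tiles must share a shape for phase correlation")
    h, w = a.shape
    win = np.hanning(h)[:, None] * np.hanning(w)[None, :]
    fa = np.fft.rfft2((a - a.mean()) * win)
    fb = np.fft.rfft2((b - b.mean()) * win)
    cross = fa * np.conj(fb)
    denom = np.abs(cross)
    denom[denom == 0] = 1.0
    corr = np.fft.irfft2(cross / denom, s=a.shape)

    # admissible shifts: nominal ± radius, wrapped FFT indexing
    dys = np.arange(nominal_offset[1] - search_radius, nominal_offset[1] + search_radius + 1)
    dxs = np.arange(nominal_offset[0] - search_radius, nominal_offset[0] + search_radius + 1)
    sub = corr[np.ix_(dys % h, dxs % w)]
    iy, ix = np.unravel_index(np.argmax(sub), sub.shape)
    peak = sub[iy, ix]
    noise = np.mean(np.abs(corr)) + 1e-12
    confidence = float(peak / noise)
    if confidence < confidence_threshold:
        warnings.warn(
            "low phase-correlation confidence; falling back to nominal offset",
            stacklevel=2,
        )
        return OffsetEstimate(nominal_offset[0], nominal_offset[1], confidence, fallback=True)
    return OffsetEstimate(int(dxs[ix]), int(dys[iy]), confidence)


def _feather_weight(shape: tuple[int, int]) -> np.ndarray:
    """Linear feather: weight rises from the tile border toward the interior."""
    h, w = shape
    wy = np.minimum(np.arange(h) + 1, np.arange(h)[::-1] + 1)
    wx = np.minimum(np.arange(w) + 1, np.arange(w)[::-1] + 1)
    return np.minimum(wy[:, None], wx[None, :]).astype(float)


def assemble_mosaic(
    tiles: dict[tuple[int, int], np.ndarray],
    nominal_positions: dict[tuple[int, int], tuple[int, int]],
    pair_offsets: dict[tuple[tuple[int, int], tuple[int, int]], OffsetEstimate] | None = None,
    loop_tolerance: int = 3,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Composite tiles into a mosaic with feather blending.

    ``tiles`` maps (row, col) to images; ``nominal_positions`` to their
    nominal (x, y) pixel positions from the tile plan.  ``pair_offsets`` maps
    adjacent-pair keys ((row, col) A, (row, col) B) to refined estimates of B's
    position relative to A.  Global positions are anchored at tile (0, 0) and
    accumulated along a maximum-confidence spanning tree; redundant pairs
    whose loop-closure residual exceeds ``loop_tolerance`` px trigger a
    warning and are averaged in.  Returns the mosaic and a placement table.
    """
    if not tiles:
        raise ValueError("no tiles to assemble")
    keys = sorted(tiles)
    anchor = keys[0]
    positions: dict[tuple[int, int], np.ndarray] = {
        anchor: np.asarray(nominal_positions[anchor], dtype=float)
    }

    if pair_offsets:
        # refined relative positions: pos[B] = pos[A] + nominal(B) - nominal(A)
        # + (refined - nominal) correction from the pairwise estimate
        edges = sorted(
            pair_offsets.items(), key=lambda kv: -kv[1].confidence
        )
        remaining = list(edges)
        progress = True
        while progress:
            progress = False
            for (ka, kb), est in list(remaining):
                known_a, known_b = ka in positions, kb in positions
                if known_a == known_b:
                    if known_a and known_b:
                        remaining.remove(((ka, kb), est))
                        predicted = positions[ka] + np.array([est.dx, est.dy], dtype=float)
                        residual = np.abs(predicted - positions[kb]).max()
                        if residual > loop_tolerance:
                            warnings.warn(
                                f"loop-closure residual {residual:.0f} px between "
                                f"{ka} and {kb}; averaging",
                                stacklevel=2,
                            )
                            positions[kb] = (positions[kb] + predicted) / 2.0
                    continue
                if known_a:
                    positions[kb] = positions[ka] + np.array([est.dx, est.dy], dtype=float)
                else:
                    positions[ka] = positions[kb] - np.array([est.dx, est.dy], dtype=float)
                remaining.remove(((ka, kb), est))
                progress = True
    for k in keys:  # unconnected tiles fall back to nominal placement
        if k not in positions:
            positions[k] = np.asarray(nominal_positions[k], dtype=float)

    pos_int = {k: np.rint(v).astype(int) for k, v in positions.items()}
    min_xy = np.min([p for p in pos_int.values()], axis=0)
    for k in pos_int:
        pos_int[k] = pos_int[k] - min_xy

    first = np.asarray(tiles[keys[0]], dtype=float)
    n_chan = first.shape[2] if first.ndim == 3 else 1
    extents = np.max(
        [pos_int[k] + np.array(tiles[k].shape[1::-1] if tiles[k].ndim == 3 else tiles[k].shape[::-1]) for k in keys],
        axis=0,
    )
    acc = np.zeros((extents[1], extents[0], n_chan), dtype=float)
    wacc = np.zeros((extents[1], extents[0], 1), dtype=float)
    rows = []
    for k in keys:
        img = np.asarray(tiles[k], dtype=float)
        if img.ndim == 2:
            img = img[:, :, None]
        x, y = pos_int[k]
        h, w = img.shape[:2]
        wgt = _feather_weight((h, w))[:, :, None]
        acc[y : y + h, x : x + w] += img * wgt
        wacc[y : y + h, x : x + w] += wgt
        rows.append({"tile_row": k[0], "tile_col": k[1], "x_px": int(x), "y_px": int(y)})
    mosaic = acc / np.clip(wacc, 1e-12, None)
    if first.ndim == 2 or (np.asarray(tiles[keys[0]]).ndim == 2):
        mosaic = mosaic[:, :, 0]
    placement = pd.DataFrame(rows)
    return mosaic, placement


def stitch_section(
    tiles: dict[tuple[int, int], np.ndarray],
    tile_plan: TilePlan,
    pixel_size_um: float,
    refine: bool = True,
    search_radius: int = 10,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stitch one section's tiles using the plan's nominal geometry.

    Nominal pixel positions come from the tile-plan origins; adjacent pairs
    (right and down neighbours) are refined by phase correlation on their
    overlap regions when ``refine`` is set.
    """
    nominal = {
        (r, c): (
            int(round(tile_plan.origin_mm(r, c)[0] * 1000.0 / pixel_size_um)),
            int(round(tile_plan.origin_mm(r, c)[1] * 1000.0 / pixel_size_um)),
        )
        for (r, c) in tiles
    }
    pair_offsets = None
    if refine and len(tiles) > 1:
        pair_offsets = {}
        for (r, c) in sorted(tiles):
            for (nr, nc) in ((r, c + 1), (r + 1, c)):
                if (nr, nc) not in tiles:
                    continue
                nom = (
                    nominal[(nr, nc)][0] - nominal[(r, c)][0],
                    nominal[(nr, nc)][1] - nominal[(r, c)][1],
                )
                a, b = tiles[(r, c)], tiles[(nr, nc)]
                h, w = a.shape[:2]
                # correlate the nominally overlapping crops so the shared
                # content sits at the window centre, not the tapered edge
                ax0, ay0 = max(nom[0], 0), max(nom[1], 0)
                ax1, ay1 = w + min(nom[0], 0), h + min(nom[1], 0)
                bx0, by0 = max(-nom[0], 0), max(-nom[1], 0)
                crop_a = a[ay0:ay1, ax0:ax1]
                crop_b = b[by0 : by0 + (ay1 - ay0), bx0 : bx0 + (ax1 - ax0)]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    corr = estimate_offset(
                        crop_a,
                        crop_b,
                        nominal_offset=(0, 0),
                        search_radius=search_radius,
                    )
                pair_offsets[((r, c), (nr, nc))] = OffsetEstimate(
                    nom[0] + corr.dx,
                    nom[1] + corr.dy,
                    corr.confidence,
                    corr.fallback,
                )
    return assemble_mosaic(tiles, nominal, pair_offsets)
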