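"""Calibration procedures of the block-face microscope.

Two measurements characterize the instrument:

* **Bead profiling** — fluorescent microbeads (4 µm) imaged as a z-stack;
  1D intensity profiles through each bead along x, y and z are averaged and
  fit with a Gaussian; the per-axis FWHM (``2*sqrt(2 ln 2) * sigma``)
  summarizes the effective 3D resolution.

* **Optical sectioning thickness** — per-cell intensities on the block-face
  image are sorted by the cell depths located in a co-registered reference
  z-stack; the depth decay is fit with Beer–Lambert ``I(z) = I0 exp(-z/d)``
  and the 1/e depth ``d`` is the sectioning-thickness estimate.  A
  depth-resolved Pearson correlation between the block-face image and each
  reference slice corroborates the estimate: similarity should peak at the
  surface and fall off beyond ``d``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats

__all__ = [
    "FWHM_PER_SIGMA",
    "GaussianFit",
    "AttenuationFit",
    "DepthCorrelationProfile",
    "detect_beads",
    "profile_psf",
    "estimate_sectioning_thickness",
    "assign_cell_depths",
    "correlation_vs_depth",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.35482...


@dataclass(frozen=True)
class GaussianFit:
    """Least-squares Gaussian + offset fit of a 1D intensity profile."""

    amplitude: float
    center: float
    sigma: float
    offset: float
    residual_rms: float

    @property
    def fwhm(self) -> float:
        return float(FWHM_PER_SIGMA * self.sigma)


@dataclass
class AttenuationFit:
    """Beer–Lambert fit of intensity vs depth: I(z) = I0 exp(-z/d)."""

    i0: float
    d_um: float  # 1/e depth = optical sectioning thickness estimate
    r_squared: float
    n_cells: int
    bins: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)
    failed: bool = False


@dataclass
class DepthCorrelationProfile:
    """Pearson r between a block-face image and each reference slice."""

    depths_um: np.ndarray
    r: np.ndarray  # NaN where a slice had zero variance

    def argmax_depth(self) -> float:
        return float(self.depths_um[np.nanargmax(self.r)])


def detect_beads(
    stack: np.ndarray,
    min_separation: float = 5.0,
    smooth_sigma: float = 1.0,
    threshold_rel: float = 0.2,
) -> np.ndarray:
    """Locate bead centroids in a (z, y, x) stack, subvoxel by intensity weight.

    Local maxima of the smoothed stack above ``threshold_rel`` of the peak
    value, non-maximum-suppressed within ``min_separation`` voxels; each
    maximum is refined by the intensity-weighted centroid of its local
    neighbourhood.  Beads closer than ``min_separation`` merge into one
    detection (with a warning when suppression removed candidates).
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3 or stack.shape[0] < 3:
        raise ValueError("need a (z, y, x) stack with >= 3 slices")
    sm = ndimage.gaussian_filter(stack, smooth_sigma)
    lo, hi = sm.min(), sm.max()
    if hi <= lo:
        raise ValueError("stack is constant; no beads detected")
    thr = lo + threshold_rel * (hi - lo)
    size = max(3, int(2 * np.floor(min_separation / 2) + 1))
    maxf = ndimage.maximum_filter(sm, size=size)
    peaks = np.argwhere((sm == maxf) & (sm > thr))
    if len(peaks) == 0:
        raise ValueError("no beads detected above threshold")
    # greedy suppression of residual near-duplicates (plateau maxima)
    order = np.argsort(-sm[tuple(peaks.T)])
    kept: list[np.ndarray] = []
    for i in order:
        p = peaks[i]
        if all(np.linalg.norm(p - q) >= min_separation for q in kept):
            kept.append(p)
    if len(kept) < len(peaks):
        warnings.warn(
            f"{len(peaks) - len(kept)} candidate maxima within min_separation "
            "were merged",
            stacklevel=2,
        )
    centroids = []
    rad = max(2, int(min_separation // 2))
    for p in kept:
        sl = tuple(
            slice(max(c - rad, 0), min(c + rad + 1, n)) for c, n in zip(p, stack.shape)
        )
        patch = np.clip(stack[sl] - thr, 0.0, None)
        if patch.sum() == 0:
            centroids.append(p.astype(float))
            continue
        grids = np.meshgrid(*(np.arange(s.start, s.stop) for s in sl), indexing="ij")
        centroids.append(np.array([(g * patch).sum() / patch.sum() for g in grids]))
    return np.array(sorted(centroids, key=tuple))


def _fit_gaussian_1d(profile: np.ndarray, coords: np.ndarray | None = None) -> GaussianFit:
    y = np.asarray(profile, dtype=float)
    x = np.arange(len(y), dtype=float) if coords is None else np.asarray(coords, dtype=float)
    off0 = float(y.min())
    amp0 = float(y.max() - off0)
    if amp0 <= 0:
        raise RuntimeError("flat profile; Gaussian fit impossible")
    c0 = float(x[np.argmax(y)])
    w = np.clip(y - off0, 0, None)
    s0 = float(np.sqrt(np.sum(w * (x - c0) ** 2) / np.sum(w))) if w.sum() > 0 else 1.0
    s0 = max(s0, (x[1] - x[0]) / 2 if len(x) > 1 else 0.5)

    def model(x, a, c, s, o):
        return a * np.exp(-0.5 * ((x - c) / s) ** 2) + o

    popt, _ = optimize.curve_fit(
        model, x, y, p0=(amp0, c0, s0, off0), maxfev=20_000
    )
    a, c, s, o = popt
    s = abs(float(s))
    resid = y - model(x, *popt)
    return GaussianFit(
        amplitude=float(a),
        center=float(c),
        sigma=s,
        offset=float(o),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def profile_psf(
    stack: np.ndarray,
    centroids: np.ndarray,
    spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
    half_width: int | None = None,
) -> dict[str, GaussianFit]:
    """Average bead profiles along each axis and fit Gaussians.

    For every centroid, 1D profiles through the (rounded) centroid voxel are
    extracted along z, y and x, aligned on the centroid and averaged across
    beads; a Gaussian + offset is least-squares fit per axis.  Returns fits
    keyed ``"x"``, ``"y"``, ``"z"`` with centers/sigmas in µm
    (``spacing_um`` is (z, y, x) voxel spacing).  Beads whose fit fails are
    excluded; all failing is an error.
    """
    stack = np.asarray(stack, dtype=float)
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    if len(centroids) == 0:
        raise ValueError("need at least one centroid")
    axes = {"z": 0, "y": 1, "x": 2}
    fits: dict[str, GaussianFit] = {}
    for name, ax in axes.items():
        n = stack.shape[ax]
        hw = half_width if half_width is not None else n // 2
        rel = np.arange(-hw, hw + 1, dtype=float)
        profiles = []
        for c in centroids:
            # sample along the axis at the centroid's sub-voxel position
            coords = np.empty((3, len(rel)))
            for a2 in range(3):
                coords[a2] = c[a2] if a2 != ax else c[ax] + rel
            prof = ndimage.map_coordinates(stack, coords, order=1, mode="nearest")
            if np.ptp(prof) > 0:
                profiles.append(prof)
        if not profiles:
            raise RuntimeError(f"no usable bead profiles along {name}")
        mean_prof = np.mean(profiles, axis=0)
        sp = spacing_um[ax]
        try:
            fit = _fit_gaussian_1d(mean_prof, coords=rel * sp)
        except RuntimeError as e:
            raise RuntimeError(f"Gaussian fit failed along {name}: {e}") from e
        if fit.sigma < sp:
            warnings.warn(
                f"{name}-profile is under-sampled (sigma {fit.sigma:.2f} µm "
                f"< voxel spacing {sp} µm)",
                stacklevel=2,
            )
        fits[name] = fit
    return fits


def estimate_sectioning_thickness(
    cell_table: pd.DataFrame,
    bin_width_um: float = 2.0,
    min_cells: int = 30,
    min_bins: int = 3,
    nonlinear_refine: bool = False,
) -> AttenuationFit:
    """Beer–Lambert 1/e-depth estimate from per-cell (depth, intensity) data.

    Cells are binned by depth (default 2 µm, the reference-stack spacing);
    the per-bin median intensity absorbs the within/between-cell intensity
    heterogeneity; ``ln(median)`` is regressed on depth and the 1/e depth is
    ``-1/slope``.  A non-negative slope raises the ``failed`` flag.  With
    ``nonlinear_refine`` the log-linear solution seeds a nonlinear
    least-squares fit of ``I0 exp(-z/d)`` to the bin medians.

    ``cell_table`` needs columns ``depth_um`` and ``intensity``.
    """
    df = cell_table.dropna(subset=["depth_um", "intensity"])
    df = df[df["intensity"] > 0]
    if len(df) < min_cells:
        raise ValueError(f"need >= {min_cells} cells with positive intensity, got {len(df)}")
    edges = np.arange(0.0, df["depth_um"].max() + bin_width_um, bin_width_um)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width_um])
    which = np.digitize(df["depth_um"], edges) - 1
    grouped = df.groupby(which)
    # median of log-intensity pairs with median depth: on exact exponential
    # data the regression recovers d without binning bias
    med_log = grouped["intensity"].agg(lambda v: np.median(np.log(v)))
    med_depth = grouped["depth_um"].median()
    n = grouped.size()
    bins = pd.DataFrame(
        {
            "depth_um": med_depth.values,
            "bin_center_um": edges[med_log.index.values] + bin_width_um / 2,
            "median_intensity": np.exp(med_log.values),
            "n": n.values,
        }
    )
    usable = bins[np.isfinite(bins["median_intensity"]) & (bins["median_intensity"] > 0)]
    if len(usable) < min_bins:
        raise ValueError(f"need >= {min_bins} usable depth bins, got {len(usable)}")
    x = usable["depth_um"].to_numpy()
    y = np.log(usable["median_intensity"].to_numpy())
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = float(1.0 - np.sum(resid**2) / ss_tot) if ss_tot > 0 else 0.0
    if slope >= -1e-12:  # flat or increasing: no attenuation signal
        return AttenuationFit(
            i0=float(np.exp(intercept)),
            d_um=float("nan"),
            r_squared=r2,
            n_cells=len(df),
            bins=bins,
            failed=True,
        )
    i0 = float(np.exp(intercept))
    d = float(-1.0 / slope)
    if nonlinear_refine:
        try:
            popt, _ = optimize.curve_fit(
                lambda z, i0_, d_: i0_ * np.exp(-z / d_),
                x,
                usable["median_intensity"].to_numpy(),
                p0=(i0, d),
                maxfev=10_000,
            )
            i0, d = float(popt[0]), float(abs(popt[1]))
        except RuntimeError:
            warnings.warn("nonlinear refinement failed; keeping log-linear fit", stacklevel=2)
    return AttenuationFit(
        i0=i0, d_um=d, r_squared=r2, n_cells=len(df), bins=bins, failed=False
    )


def assign_cell_depths(
    masks: np.ndarray,
    reference_stack: np.ndarray,
    slice_depths_um: np.ndarray | list[float],
    background_quantile: float = 0.99,
) -> pd.DataFrame:
    """Locate each segmented cell's depth in a co-registered reference stack.

    ``masks`` is a 2D label image on the same pixel grid as the stack slices;
    a cell's depth is the slice (in µm) maximizing the mean intensity over
    its mask.  Cells whose best slice does not rise above the stack's global
    background level are excluded (depth NaN).
    """
    masks = np.asarray(masks)
    stack = np.asarray(reference_stack, dtype=float)
    if stack.ndim == 4:  # RGB reference: collapse to luminance
        stack = stack.mean(axis=-1)
    depths = np.asarray(slice_depths_um, dtype=float)
    if stack.shape[0] != len(depths):
        raise ValueError("one depth per slice required")
    if masks.shape != stack.shape[1:]:
        raise ValueError("mask frame does not match the stack pixel grid")
    labels = np.unique(masks)
    labels = labels[labels != 0]
    background = float(np.quantile(stack, background_quantile) * 0.05)
    rows = []
    for lab in labels:
        m = masks == lab
        means = stack[:, m].mean(axis=1)
        k = int(np.argmax(means))
        visible = means[k] > background
        rows.append(
            {
                "label": int(lab),
                "depth_um": float(depths[k]) if visible else np.nan,
                "peak_mean_intensity": float(means[k]),
            }
        )
    return pd.DataFrame(rows, columns=["label", "depth_um", "peak_mean_intensity"])


def correlation_vs_depth(
    surface_image: np.ndarray,
    reference_stack: np.ndarray,
    slice_depths_um: np.ndarray | list[float],
    foreground_quantile: float = 0.90,
) -> DepthCorrelationProfile:
    """Pearson r between the block-face image and each reference slice.

    Computed over the union of foreground pixels (above the
    ``foreground_quantile`` of either image), so empty background does not
    inflate the correlation.  Zero-variance slices yield NaN.
    """
    surf = np.asarray(surface_image, dtype=float)
    if surf.ndim == 3:
        surf = surf.mean(axis=-1)
    stack = np.asarray(reference_stack, dtype=float)
    if stack.ndim == 4:
        stack = stack.mean(axis=-1)
    depths = np.asarray(slice_depths_um, dtype=float)
    if stack.shape[0] != len(depths):
        raise ValueError("one depth per slice required")
    if stack.shape[0] < 2:
        raise ValueError("need >= 2 slices")
    fg = surf > np.quantile(surf, foreground_quantile)
    fg |= stack.max(axis=0) > np.quantile(stack, foreground_quantile)
    if fg.sum() < 8:
        fg = np.ones_like(surf, dtype=bool)
    rs = np.full(len(depths), np.nan)
    a = surf[fg]
    if a.std() > 0:
        for k in range(len(depths)):
            b = stack[k][fg]
            if b.std() > 0:
                rs[k] = stats.pearsonr(a, b).statistic
    return DepthCorrelationProfile(depths_um=depths, r=rs)
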