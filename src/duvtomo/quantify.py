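"""Cell segmentation, counting, regional densities and statistics.

The counting channel is red by default (propidium iodide, the Nissl-like
counterstain).  Segmentation is a deterministic surrogate for manual
counting: Gaussian smooth, Otsu threshold, hole filling, distance-transform
watershed to split touching cells, then an area filter.  Counts are assigned
to regions by the label under each centroid, aggregated per section and up a
region hierarchy, and compared with the paired-t / Welch-ANOVA / Tukey /
Shapiro–Wilk tests used for such data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import watershed

__all__ = [
    "SegmentationParams",
    "segment_cells",
    "assign_regions",
    "count_and_density",
    "aggregate_region_tree",
    "paired_t",
    "welch_anova",
    "group_stats",
    "StatReport",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Knobs of the watershed segmentation surrogate (areas in µm²)."""

    smooth_sigma_um: float = 1.0
    min_area_um2: float = 12.0
    max_area_um2: float = 400.0
    split_min_distance_um: float = 4.0
    threshold_method: str = "otsu"  # or "fixed"
    fixed_threshold: float | None = None
    split: bool = True


def _counting_channel(image: np.ndarray, channel: int | None) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        return img[:, :, 0 if channel is None else channel]
    if channel not in (None, 0):
        raise ValueError("single-channel image has no channel to select")
    return img


def segment_cells(
    image: np.ndarray,
    pixel_size_um: float = 1.0,
    params: SegmentationParams | None = None,
    channel: int | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Segment cell bodies on one (mosaic) image.

    Returns the label map and a cell table with centroid (µm), area (µm²)
    and per-channel median/mean intensities.  An all-background image yields
    an empty table, not an error.  Deterministic.
    """
    if params is None:
        params = SegmentationParams()
    gray = _counting_channel(image, channel)
    px2 = pixel_size_um * pixel_size_um
    sm = ndimage.gaussian_filter(gray, params.smooth_sigma_um / pixel_size_um)
    if params.threshold_method == "fixed":
        if params.fixed_threshold is None:
            raise ValueError("fixed threshold requested but none given")
        thr = params.fixed_threshold
    elif params.threshold_method == "otsu":
        if np.ptp(sm) == 0:
            return np.zeros(gray.shape, dtype=np.int32), _empty_cell_table(image)
        thr = threshold_otsu(sm)
    else:
        raise ValueError(f"unknown threshold method {params.threshold_method!r}")
    mask = sm > thr
    if not mask.any():
        return np.zeros(gray.shape, dtype=np.int32), _empty_cell_table(image)
    mask = ndimage.binary_fill_holes(mask)

    if params.split:
        dist = ndimage.distance_transform_edt(mask) * pixel_size_um
        min_dist_px = max(1, int(round(params.split_min_distance_um / pixel_size_um)))
        peaks = peak_local_max(
            dist, min_distance=min_dist_px, labels=mask, exclude_border=False
        )
        markers = np.zeros(mask.shape, dtype=np.int32)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        if markers.max() == 0:
            labels, _ = ndimage.label(mask)
        else:
            labels = watershed(-dist, markers, mask=mask)
    else:
        labels, _ = ndimage.label(mask)

    img = np.asarray(image, dtype=float)
    multi = img.ndim == 3
    rows = []
    out = np.zeros(labels.shape, dtype=np.int32)
    next_id = 1
    for prop in regionprops(labels):
        area = prop.area * px2
        if not (params.min_area_um2 <= area <= params.max_area_um2):
            continue
        rr, cc = prop.coords[:, 0], prop.coords[:, 1]
        out[rr, cc] = next_id
        cy, cx = prop.centroid
        row = {
            "label": next_id,
            "x_um": (cx + 0.5) * pixel_size_um,
            "y_um": (cy + 0.5) * pixel_size_um,
            "area_um2": area,
        }
        if multi:
            for c, name in zip(range(img.shape[2]), ("r", "g", "b")):
                vals = img[rr, cc, c]
                row[f"median_{name}"] = float(np.median(vals))
                row[f"mean_{name}"] = float(vals.mean())
            row["intensity"] = row["median_r"]
        else:
            vals = img[rr, cc]
            row["median_intensity"] = float(np.median(vals))
            row["mean_intensity"] = float(vals.mean())
            row["intensity"] = row["median_intensity"]
        rows.append(row)
        next_id += 1
    return out, pd.DataFrame(rows, columns=_cell_columns(image))


def _cell_columns(image: np.ndarray) -> list[str]:
    base = ["label", "x_um", "y_um", "area_um2"]
    if np.asarray(image).ndim == 3:
        for name in ("r", "g", "b"):
            base += [f"median_{name}", f"mean_{name}"]
    else:
        base += ["median_intensity", "mean_intensity"]
    return base + ["intensity"]


def _empty_cell_table(image: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(columns=_cell_columns(image))


def assign_regions(
    cells: pd.DataFrame,
    label_image: np.ndarray,
    pixel_size_um: float = 1.0,
    region_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Attach region ids (and names) to cells by atlas-label lookup.

    The owning region of a cell is the label under its centroid pixel;
    centroids outside the label frame or over background get region 0.
    """
    labels = np.asarray(label_image)
    if labels.ndim != 2:
        raise ValueError("label image must be 2D (one section)")
    out = cells.copy()
    region = np.zeros(len(cells), dtype=np.int64)
    if len(cells):
        col = np.floor(cells["x_um"].to_numpy() / pixel_size_um).astype(int)
        row = np.floor(cells["y_um"].to_numpy() / pixel_size_um).astype(int)
        inside = (
            (row >= 0) & (row < labels.shape[0]) & (col >= 0) & (col < labels.shape[1])
        )
        region[inside] = labels[row[inside], col[inside]]
    out["region_id"] = region
    if region_names is not None:
        out["region_name"] = [region_names.get(r, str(r)) for r in region]
    return out


def count_and_density(
    cells: pd.DataFrame,
    region_areas_mm2: dict[int, float] | pd.DataFrame,
    section_column: str = "section_index",
) -> pd.DataFrame:
    """Count cells and compute areal density per (section, region).

    ``region_areas_mm2`` maps region_id to the region's in-plane area (mm²),
    either globally (dict) or per section (DataFrame with section_index,
    region_id, area_mm2).  Density is cells/mm².  A region with counted
    cells but zero recorded area indicates a registration bug and raises.
    """
    df = cells.copy()
    if section_column not in df.columns:
        df[section_column] = 0
    counts = (
        df[df["region_id"] != 0]
        .groupby([section_column, "region_id"])
        .size()
        .rename("count")
        .reset_index()
    )
    if isinstance(region_areas_mm2, pd.DataFrame):
        merged = counts.merge(
            region_areas_mm2, on=[section_column, "region_id"], how="left"
        )
    else:
        merged = counts.assign(
            area_mm2=[region_areas_mm2.get(r, np.nan) for r in counts["region_id"]]
        )
    bad = merged[(merged["count"] > 0) & ~(merged["area_mm2"] > 0)]
    if len(bad):
        raise ValueError(
            f"regions with cells but no positive area: "
            f"{sorted(bad['region_id'].unique())}"
        )
    merged["density_per_mm2"] = merged["count"] / merged["area_mm2"]
    return merged


def aggregate_region_tree(
    counts: dict[int, int] | pd.DataFrame,
    tree: dict[int, int | None],
    names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Aggregate counts up a rooted region hierarchy (sunburst table).

    ``tree`` maps node id -> parent id (root's parent is None).  A node's
    total is its own count plus all descendants'; percentages are relative
    to the root total.  Cycles are rejected.
    """
    if isinstance(counts, pd.DataFrame):
        own = counts.groupby("region_id")["count"].sum().to_dict()
    else:
        own = dict(counts)
    roots = [n for n, p in tree.items() if p is None]
    if len(roots) != 1:
        raise ValueError(f"tree must have exactly one root, found {len(roots)}")
    children: dict[int, list[int]] = {n: [] for n in tree}
    for n, p in tree.items():
        if p is not None:
            if p not in tree:
                raise ValueError(f"parent {p} of node {n} is not in the tree")
            children[p].append(n)
    for r in own:
        if r not in tree:
            raise ValueError(f"counted region {r} is not a tree node")

    total: dict[int, int] = {}
    state: dict[int, int] = {}

    def visit(n: int) -> int:
        if state.get(n) == 1:
            raise ValueError("cycle detected in region tree")
        if n in total:
            return total[n]
        state[n] = 1
        t = int(own.get(n, 0)) + sum(visit(c) for c in children[n])
        state[n] = 2
        total[n] = t
        return t

    root_total = visit(roots[0])
    rows = []
    for n in tree:
        visit(n)
        pct = 100.0 * total[n] / root_total if root_total > 0 else np.nan
        rows.append(
            {
                "region_id": n,
                "parent_id": tree[n],
                "name": (names or {}).get(n, str(n)),
                "count": total[n],
                "own_count": int(own.get(n, 0)),
                "pct_root": pct,
            }
        )
    return pd.DataFrame(rows)


def paired_t(series_a, series_b) -> tuple[float, int, float]:
    """Two-tailed paired t-test: returns (t, df, p) with df = n - 1."""
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1D series with n >= 2")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff, 0.0):
            return 0.0, len(a) - 1, 1.0
        raise ValueError("zero-variance non-zero differences: t undefined")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), int(len(a) - 1), float(res.pvalue)


def welch_anova(*groups) -> tuple[float, float, float, float]:
    """Welch's one-way ANOVA: returns (F, df1, df2, p).

    Allows unequal group variances; df2 is the fractional Satterthwaite
    approximation.  A zero-variance group makes the statistic undefined.
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups of n >= 2")
    if any(g.std(ddof=1) == 0 for g in gs):
        raise ValueError("zero-variance group: Welch ANOVA undefined")
    k = len(gs)
    n = np.array([len(g) for g in gs], dtype=float)
    m = np.array([g.mean() for g in gs])
    v = np.array([g.var(ddof=1) for g in gs])
    w = n / v
    mw = np.sum(w * m) / np.sum(w)
    f_num = np.sum(w * (m - mw) ** 2) / (k - 1)
    lam = np.sum((1 - w / np.sum(w)) ** 2 / (n - 1))
    f_den = 1 + 2 * (k - 2) / (k**2 - 1) * lam
    f_stat = f_num / f_den
    df1 = k - 1.0
    df2 = (k**2 - 1) / (3 * lam)
    p = float(stats.f.sf(f_stat, df1, df2))
    return float(f_stat), df1, float(df2), p


@dataclass
class StatReport:
    """Group-comparison summary: Welch ANOVA + Tukey HSD + Shapiro–Wilk."""

    welch_f: float
    welch_df1: float
    welch_df2: float
    welch_p: float
    tukey: pd.DataFrame = field(repr=False, default_factory=pd.DataFrame)
    shapiro_w: float = np.nan
    shapiro_p: float = np.nan


def group_stats(groups: dict[str, np.ndarray] | list[np.ndarray]) -> StatReport:
    """Welch one-way ANOVA with Tukey HSD pairs and Shapiro–Wilk on pooled data."""
    if isinstance(groups, dict):
        names = list(groups)
        arrays = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        arrays = [np.asarray(g, dtype=float) for g in groups]
        names = [f"group{i}" for i in range(len(arrays))]
    f_stat, df1, df2, p = welch_anova(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "mean_diff": float(arrays[i].mean() - arrays[j].mean()),
                    "p_adj": float(hsd.pvalue[i, j]),
                }
            )
    pooled = np.concatenate(arrays)
    sw = stats.shapiro(pooled)
    return StatReport(
        welch_f=f_stat,
        welch_df1=df1,
        welch_df2=df2,
        welch_p=p,
        tukey=pd.DataFrame(rows),
        shapiro_w=float(sw.statistic),
        shapiro_p=float(sw.pvalue),
    )
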