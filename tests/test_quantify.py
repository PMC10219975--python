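"""Segmentation, regional counting, hierarchy aggregation, statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from duvtomo.optics import OpticalConfig, render_block_face
from duvtomo.phantom import CellSpec, TissuePhantom
from duvtomo.quantify import (
    aggregate_region_tree,
    assign_regions,
    count_and_density,
    group_stats,
    paired_t,
    segment_cells,
    welch_anova,
)


def grid_phantom(nx, ny, spacing=24.0, z=4.0):
    """Well-separated cells on a lateral grid at fixed shallow depth."""
    cells = []
    for i in range(nx):
        for j in range(ny):
            cells.append(
                CellSpec(
                    center=((i + 0.5) * spacing, (j + 0.5) * spacing, z),
                    nucleus_radius=3.0,
                    soma_radius=5.0,
                    dye_amplitudes=(1.0,),
                )
            )
    box = (nx * spacing, ny * spacing, 100.0)
    return TissuePhantom(bounding_box=box, cells=cells, n_dyes=1)


class TestSegmentCells:
    def test_blank_image_empty_table(self):
        labels, cells = segment_cells(np.zeros((64, 64)))
        assert labels.max() == 0
        assert len(cells) == 0

    def test_planted_grid_recovered(self):
        ph = grid_phantom(7, 7)
        cfg = OpticalConfig(
            pixel_size_um=1.0,
            fov_px=(168, 168),
            illumination_ramp=0.0,
            vignette=0.0,
            photon_scale=0.5,
            read_noise=1.0,
            offset=2.0,
            gain=3.0,
        )
        img = render_block_face(ph, 0.0, cfg, seed=0).rgb
        _, cells = segment_cells(img, pixel_size_um=1.0)
        assert abs(len(cells) - 49) <= 2
        # centroid accuracy: match each truth position to nearest detection
        det = cells[["x_um", "y_um"]].to_numpy()
        for c in ph.cells:
            dist = np.linalg.norm(det - np.array(c.center[:2]), axis=1).min()
            assert dist < 2.0

    def test_touching_pair_split_by_watershed(self):
        # centres 1.2 soma-diameters apart: somas blur into one blob
        cells = [
            CellSpec((30.0, 32.0, 4.0), 3.0, 5.0, (1.0,)),
            CellSpec((42.0, 32.0, 4.0), 3.0, 5.0, (1.0,)),
        ]
        ph = TissuePhantom((64, 64, 100), cells=cells, n_dyes=1)
        cfg = OpticalConfig(
            pixel_size_um=1.0, fov_px=(64, 64), illumination_ramp=0.0,
            vignette=0.0, gain=3.0,
        )
        img = render_block_face(ph, 0.0, cfg, seed=1).rgb
        _, table = segment_cells(img, pixel_size_um=1.0)
        assert len(table) == 2

    def test_deterministic(self):
        ph = grid_phantom(3, 3)
        cfg = OpticalConfig(pixel_size_um=1.0, fov_px=(72, 72), gain=3.0)
        img = render_block_face(ph, 0.0, cfg, seed=2).rgb
        t1 = segment_cells(img)[1]
        t2 = segment_cells(img)[1]
        pd.testing.assert_frame_equal(t1, t2)


class TestAssignRegions:
    def test_single_region(self):
        cells = pd.DataFrame({"x_um": [5.0, 10.0], "y_um": [5.0, 10.0]})
        labels = np.full((20, 20), 3, dtype=np.int32)
        out = assign_regions(cells, labels)
        assert (out["region_id"] == 3).all()

    def test_boundary_pixel_owner(self):
        # centroid exactly on the first pixel of region 2 takes label 2
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[:, :5] = 1
        labels[:, 5:] = 2
        cells = pd.DataFrame({"x_um": [5.0], "y_um": [3.0]})
        out = assign_regions(cells, labels)
        assert out.loc[0, "region_id"] == 2

    def test_outside_frame_is_background(self):
        labels = np.ones((10, 10), dtype=np.int32)
        cells = pd.DataFrame({"x_um": [50.0], "y_um": [3.0]})
        out = assign_regions(cells, labels)
        assert out.loc[0, "region_id"] == 0


class TestCountAndDensity:
    def test_simple_density(self):
        cells = pd.DataFrame(
            {"region_id": [1] * 10, "section_index": [0] * 10}
        )
        out = count_and_density(cells, {1: 0.1})
        assert out.loc[0, "count"] == 10
        assert out.loc[0, "density_per_mm2"] == pytest.approx(100.0)

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        cells = pd.DataFrame(
            {
                "region_id": rng.integers(0, 3, 100),
                "section_index": rng.integers(0, 4, 100),
            }
        )
        out = count_and_density(cells, {1: 1.0, 2: 1.0})
        unassigned = (cells["region_id"] == 0).sum()
        assert out["count"].sum() + unassigned == 100

    def test_zero_area_with_cells_rejected(self):
        cells = pd.DataFrame({"region_id": [1], "section_index": [0]})
        with pytest.raises(ValueError, match="area"):
            count_and_density(cells, {1: 0.0})


class TestAggregateRegionTree:
    def test_single_node_full_share(self):
        out = aggregate_region_tree({1: 42}, {1: None})
        assert out.loc[0, "pct_root"] == 100.0

    def test_two_leaves(self):
        tree = {1: None, 2: 1, 3: 1}
        out = aggregate_region_tree({2: 30, 3: 70}, tree).set_index("region_id")
        assert out.loc[1, "count"] == 100
        assert out.loc[2, "pct_root"] == 30.0
        assert out.loc[3, "pct_root"] == 70.0

    def test_three_level_sums(self):
        tree = {1: None, 2: 1, 3: 1, 4: 2, 5: 2, 6: 3}
        counts = {4: 10, 5: 15, 6: 20, 3: 5, 1: 2}
        out = aggregate_region_tree(counts, tree).set_index("region_id")
        assert out.loc[2, "count"] == 25
        assert out.loc[3, "count"] == 25
        assert out.loc[1, "count"] == 52
        # children sum to parent totals minus the parent's own cells
        assert out.loc[4, "count"] + out.loc[5, "count"] == out.loc[2, "count"]
        assert out.loc[1, "pct_root"] == 100.0

    def test_cycle_rejected(self):
        with pytest.raises(ValueError):
            aggregate_region_tree({1: 1}, {1: 2, 2: 1})


class TestPairedT:
    def test_identical_series(self):
        t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0 and df == 2

    def test_hand_computed_example(self):
        # diffs (1.0, 2.5, 0.5): mean 4/3, sd ~1.0408, t = 2.2188
        t, df, p = paired_t([2.0, 4.0, 3.0], [1.0, 1.5, 2.5])
        assert df == 2
        assert t == pytest.approx(2.2188, abs=1e-3)

    def test_df_convention_n_minus_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        _, df, _ = paired_t(a, b)
        assert df == 9

    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=12), rng.normal(size=12)
        t, _, p = paired_t(a, b)
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue)

    def test_constant_nonzero_difference_flagged(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 2.0, 3.0], [0.0, 1.0, 2.0])


class TestWelchAnova:
    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        groups = [rng.normal(loc=m, scale=s, size=n) for m, s, n in
                  [(0.0, 1.0, 12), (0.5, 2.0, 9), (1.0, 0.5, 15)]]
        f, df1, df2, p = welch_anova(*groups)
        df = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat([0, 1, 2], [len(g) for g in groups]),
            }
        )
        ref = pg.welch_anova(data=df, dv="y", between="g")
        assert f == pytest.approx(float(ref["F"].iloc[0]), rel=1e-6)
        assert df2 == pytest.approx(float(ref["ddof2"].iloc[0]), rel=1e-6)
        assert p == pytest.approx(float(ref["p_unc"].iloc[0]), rel=1e-6)

    def test_fractional_df2(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(scale=s, size=8) for s in (0.5, 1.0, 3.0)]
        _, df1, df2, _ = welch_anova(*groups)
        assert df1 == 2.0
        assert df2 != int(df2)  # Satterthwaite df is fractional in general

    def test_zero_variance_group_rejected(self):
        with pytest.raises(ValueError):
            welch_anova([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_shifted_group_detected_by_tukey(self):
        rng = np.random.default_rng(3)
        g = {
            "a": rng.normal(size=15),
            "b": rng.normal(size=15),
            "c": rng.normal(loc=3.0, size=15),
        }
        rep = group_stats(g)
        assert rep.welch_p < 0.01
        tk = rep.tukey.set_index(["group_a", "group_b"])
        assert tk.loc[("a", "c"), "p_adj"] < 0.01
        assert tk.loc[("b", "c"), "p_adj"] < 0.01
        assert tk.loc[("a", "b"), "p_adj"] > 0.05
        assert 0 < rep.shapiro_w <= 1
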