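"""Stage arithmetic, tile planning, section scheduling, virtual acquisition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from duvtomo.acquisition import (
    distance_to_steps,
    plan_tiles,
    run_virtual_acquisition,
    schedule_sections,
    stage_resolution,
)
from duvtomo.optics import OpticalConfig
from duvtomo.phantom import TissuePhantom

from conftest import make_cell_field


class TestStageResolution:
    @pytest.mark.parametrize(
        "angle,pitch,expected",
        [(0.9, 500.0, 1.25), (360.0, 500.0, 500.0), (1.8, 500.0, 2.5)],
    )
    def test_known_values(self, angle, pitch, expected):
        assert stage_resolution(angle, pitch) == expected

    def test_exact_for_reference_hardware(self):
        # 0.9° steps on a 500 µm/rev micrometer: exactly 1.25 µm/step
        assert stage_resolution(0.9, 500.0) == 1.25

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            stage_resolution(0.0, 500.0)


class TestDistanceToSteps:
    @pytest.mark.parametrize(
        "dist,res,steps,resid",
        [(0.0, 1.25, 0, 0.0), (10.0, 1.25, 8, 0.0), (10.4, 1.25, 8, 0.4)],
    )
    def test_quantization(self, dist, res, steps, resid):
        s, r = distance_to_steps(dist, res)
        assert s == steps
        assert r == pytest.approx(resid, abs=1e-12)

    def test_residual_bounded(self):
        rng = np.random.default_rng(0)
        for d in rng.uniform(-1000, 1000, size=200):
            _, r = distance_to_steps(float(d), 1.25)
            assert abs(r) <= 1.25 / 2 + 1e-12

    def test_travel_limit_enforced(self):
        with pytest.raises(ValueError, match="travel"):
            distance_to_steps(30_000.0, 1.25, travel_limit_um=25_000.0)


class TestPlanTiles:
    def test_single_tile_when_extent_fits(self):
        plan = plan_tiles((1.3, 1.0), (1.3, 1.0), 0.2)
        assert plan.grid == (1, 1)

    def test_worked_five_by_five(self):
        # 5.2 x 4.0 mm at the 1.3 x 1.0 mm field with 20% overlap: 25 tiles
        plan = plan_tiles((5.2, 4.0), (1.3, 1.0), 0.2)
        assert plan.grid == (5, 5)
        assert plan.n_tiles == 25

    def test_zero_overlap_abutting(self):
        plan = plan_tiles((2.6, 2.0), (1.3, 1.0), 0.0)
        assert plan.grid == (2, 2)
        (x0, _), (x1, _) = plan.origin_mm(0, 0), plan.origin_mm(0, 1)
        assert x1 - x0 == pytest.approx(1.3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            plan_tiles((1.0, 1.0), (0.0, 1.0), 0.2)
        with pytest.raises(ValueError):
            plan_tiles((1.0, 1.0), (1.0, 1.0), 0.95)

    @settings(max_examples=200, deadline=None)
    @given(
        extent=st.tuples(
            st.floats(0.5, 30.0), st.floats(0.5, 30.0)
        ),
        fov=st.tuples(st.floats(0.2, 3.0), st.floats(0.2, 3.0)),
        overlap=st.floats(0.0, 0.9),
    )
    def test_coverage_and_overlap_properties(self, extent, fov, overlap):
        plan = plan_tiles(extent, fov, overlap)
        for axis in (0, 1):
            n = plan.grid[axis]
            origins = sorted({o[axis] for o in plan.origins_mm})
            assert len(origins) == n
            # union covers the extent
            assert origins[0] <= 0.0 + 1e-9
            assert origins[-1] + fov[axis] >= min(extent[axis], fov[axis]) - 1e-9
            if extent[axis] > fov[axis]:
                assert origins[-1] + fov[axis] >= extent[axis] - 1e-9
            # no gaps and at least the nominal overlap between neighbours
            for a, b in zip(origins, origins[1:]):
                assert b <= a + fov[axis] + 1e-12  # no gap
                assert (a + fov[axis]) - b >= overlap * fov[axis] - 1e-9

    def test_serpentine_order(self):
        plan = plan_tiles((2.6, 2.0), (1.3, 1.0), 0.0)
        assert plan.serpentine_order() == [(0, 0), (0, 1), (1, 1), (1, 0)]


class TestScheduleSections:
    def test_thirty_sections_at_fifty(self):
        s = schedule_sections(1500.0, 50.0)
        assert s.n_sections == 30
        assert s.face_z_um[:3] == (0.0, 50.0, 100.0)

    def test_whole_brain_117_sections(self):
        assert schedule_sections(11_700.0, 100.0).n_sections == 117

    def test_thickness_exceeding_extent_gives_single_face(self):
        with pytest.warns(UserWarning):
            s = schedule_sections(100.0, 200.0)
        assert s.n_sections == 1

    def test_warns_when_thickness_below_attenuation_depth(self):
        with pytest.warns(UserWarning, match="attenuation"):
            schedule_sections(100.0, 10.0, attenuation_depth_um=20.0)

    def test_faces_strictly_increasing(self):
        s = schedule_sections(500.0, 50.0)
        assert np.all(np.diff(s.face_z_um) > 0)


class TestRunVirtualAcquisition:
    def small_setup(self, grid_mm=(0.128, 0.064), n_sections=1):
        config = OpticalConfig(
            pixel_size_um=1.0,
            fov_px=(64, 64),
            photon_scale=0.0,
            read_noise=1.0,
            offset=5.0,
        )
        phantom = make_cell_field(
            10, (grid_mm[0] * 1000, grid_mm[1] * 1000, 300.0), (0, 40), seed=5
        )
        plan = plan_tiles(grid_mm, (0.064, 0.064), 0.0)
        schedule = schedule_sections(n_sections * 50.0, 50.0)
        return phantom, config, plan, schedule

    def test_single_tile_single_section(self):
        ph = TissuePhantom((64, 64, 100))
        config = OpticalConfig(pixel_size_um=1.0, fov_px=(64, 64))
        plan = plan_tiles((0.064, 0.064), (0.064, 0.064), 0.2)
        schedule = schedule_sections(50.0, 50.0)
        series = run_virtual_acquisition(ph, config, plan, schedule, seed=0)
        assert len(series.images) == 1
        assert len(series.manifest) == 1

    def test_grid_times_sections_and_serpentine(self):
        phantom, config, plan, schedule = self.small_setup(
            grid_mm=(0.128, 0.128), n_sections=3
        )
        assert plan.grid == (2, 2)
        series = run_virtual_acquisition(phantom, config, plan, schedule, seed=0)
        assert len(series.images) == 12
        per_face = [im.tile_index for im in series.section(0)]
        assert per_face == [(0, 0), (0, 1), (1, 1), (1, 0)]

    def test_determinism(self):
        phantom, config, plan, schedule = self.small_setup()
        s1 = run_virtual_acquisition(phantom, config, plan, schedule, seed=11)
        s2 = run_virtual_acquisition(phantom, config, plan, schedule, seed=11)
        for a, b in zip(s1.images, s2.images):
            assert (a.rgb == b.rgb).all()

    def test_truncates_when_phantom_shallow(self):
        phantom, config, plan, _ = self.small_setup()
        schedule = schedule_sections(1000.0, 50.0)  # deeper than the 300 µm phantom
        with pytest.warns(UserWarning, match="shallower"):
            series = run_virtual_acquisition(phantom, config, plan, schedule, seed=0)
        assert series.manifest["face_z_um"].max() < 300.0

    def test_writes_tiles_and_manifest(self, tmp_path):
        phantom, config, plan, schedule = self.small_setup()
        run_virtual_acquisition(phantom, config, plan, schedule, seed=0, out_dir=tmp_path)
        assert (tmp_path / "manifest.csv").exists()
        import tifffile

        files = sorted(tmp_path.glob("*.tif"))
        assert len(files) == plan.n_tiles * schedule.n_sections
        img = tifffile.imread(files[0])
        assert img.shape == (64, 64, 3)
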