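"""Bead profiling, Beer–Lambert 1/e-depth estimation, depth correlation."""

import numpy as np
import pandas as pd
import pytest

from duvtomo.calibrate import (
    FWHM_PER_SIGMA,
    assign_cell_depths,
    correlation_vs_depth,
    detect_beads,
    estimate_sectioning_thickness,
    profile_psf,
)


def gaussian_spot_stack(centers, sigmas=(3.0, 2.0, 2.0), shape=(40, 64, 64), amp=100.0):
    """Synthetic stack of 3D Gaussian spots (planted ground truth)."""
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    stack = np.zeros(shape)
    for cz, cy, cx in centers:
        stack += amp * np.exp(
            -0.5
            * (
                ((zz - cz) / sigmas[0]) ** 2
                + ((yy - cy) / sigmas[1]) ** 2
                + ((xx - cx) / sigmas[2]) ** 2
            )
        )
    return stack


class TestDetectBeads:
    def test_planted_beads_found_within_a_voxel(self):
        rng = np.random.default_rng(0)
        centers = [
            (rng.uniform(8, 32), rng.uniform(8, 56), rng.uniform(8, 56))
            for _ in range(10)
        ]
        # enforce separation of the planted truth
        ok = []
        for c in centers:
            if all(np.linalg.norm(np.subtract(c, o)) > 12 for o in ok):
                ok.append(c)
        stack = gaussian_spot_stack(ok)
        found = detect_beads(stack, min_separation=6.0)
        assert len(found) == len(ok)
        truth = np.array(sorted(ok, key=tuple))
        assert np.abs(found - truth).max() < 1.0

    def test_empty_stack_errors(self):
        with pytest.raises(ValueError):
            detect_beads(np.zeros((10, 20, 20)))

    def test_close_pair_merges_with_warning(self):
        # two resolvable maxima closer than min_separation collapse to one
        stack = gaussian_spot_stack([(20, 30, 30), (20, 30, 37)])
        with pytest.warns(UserWarning, match="merged"):
            found = detect_beads(stack, min_separation=10.0, smooth_sigma=0.5)
        assert len(found) == 1


class TestProfilePsf:
    def test_exact_gaussian_fwhm(self):
        # noiseless Gaussian of sigma 1 px: FWHM = 2.35482 px on every axis
        stack = gaussian_spot_stack([(20, 32, 32)], sigmas=(1.0, 1.0, 1.0))
        fits = profile_psf(stack, np.array([[20.0, 32.0, 32.0]]))
        for axis in ("x", "y", "z"):
            assert fits[axis].fwhm == pytest.approx(FWHM_PER_SIGMA, rel=1e-4)
            assert fits[axis].fwhm / fits[axis].sigma == pytest.approx(
                FWHM_PER_SIGMA, abs=1e-5
            )

    def test_anisotropic_sigmas_recovered(self):
        stack = gaussian_spot_stack([(20, 32, 32)], sigmas=(4.0, 1.5, 2.5))
        fits = profile_psf(stack, np.array([[20.0, 32.0, 32.0]]))
        assert fits["z"].sigma == pytest.approx(4.0, rel=0.02)
        assert fits["y"].sigma == pytest.approx(1.5, rel=0.02)
        assert fits["x"].sigma == pytest.approx(2.5, rel=0.02)

    def test_spacing_scales_to_um(self):
        stack = gaussian_spot_stack([(20, 32, 32)], sigmas=(4.0, 2.0, 2.0))
        fits = profile_psf(
            stack, np.array([[20.0, 32.0, 32.0]]), spacing_um=(2.0, 1.0, 1.0)
        )
        assert fits["z"].sigma == pytest.approx(8.0, rel=0.02)  # 4 voxels x 2 µm

    def test_delta_spike_warns_undersampled(self):
        stack = np.zeros((11, 21, 21))
        stack[5, 10, 10] = 100.0
        with pytest.warns(UserWarning, match="under-sampled"):
            fits = profile_psf(stack, np.array([[5.0, 10.0, 10.0]]), half_width=5)
        assert fits["x"].fwhm <= 2.0


class TestEstimateSectioningThickness:
    def exact_table(self, d=20.0, n=300, i0=100.0, zmax=50.0, seed=0):
        rng = np.random.default_rng(seed)
        z = rng.uniform(0, zmax, n)
        return pd.DataFrame({"depth_um": z, "intensity": i0 * np.exp(-z / d)})

    def test_exact_exponential_recovered(self):
        fit = estimate_sectioning_thickness(self.exact_table(d=20.0))
        assert not fit.failed
        assert fit.d_um == pytest.approx(20.0, rel=1e-6)
        assert fit.r_squared > 0.999

    def test_scale_invariance(self):
        t = self.exact_table(d=15.0)
        f1 = estimate_sectioning_thickness(t)
        t2 = t.assign(intensity=t["intensity"] * 37.0)
        f2 = estimate_sectioning_thickness(t2)
        assert f1.d_um == pytest.approx(f2.d_um, rel=1e-9)

    def test_constant_intensity_flags_failure(self):
        t = self.exact_table().assign(intensity=5.0)
        fit = estimate_sectioning_thickness(t)
        assert fit.failed
        assert np.isnan(fit.d_um)

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            estimate_sectioning_thickness(self.exact_table(n=10))

    def test_nonlinear_refine_agrees_on_clean_data(self):
        t = self.exact_table(d=25.0)
        lin = estimate_sectioning_thickness(t)
        nl = estimate_sectioning_thickness(t, nonlinear_refine=True)
        assert nl.d_um == pytest.approx(lin.d_um, rel=0.02)


class TestAssignCellDepths:
    def make_stack(self, cell_depth=10.0, spacing=2.0, n=16):
        depths = np.arange(0, n * spacing, spacing)
        stack = np.zeros((n, 32, 32))
        mask = np.zeros((32, 32), dtype=np.int32)
        mask[10:16, 10:16] = 1
        for k, z in enumerate(depths):
            stack[k, 10:16, 10:16] = 50.0 * np.exp(-0.5 * ((z - cell_depth) / 3.0) ** 2)
        return mask, stack, depths

    def test_planted_depth_recovered(self):
        mask, stack, depths = self.make_stack(cell_depth=10.0)
        out = assign_cell_depths(mask, stack, depths)
        assert out.loc[0, "depth_um"] == pytest.approx(10.0, abs=2.0)

    def test_surface_cell_gets_first_slice(self):
        mask, stack, depths = self.make_stack(cell_depth=0.0)
        out = assign_cell_depths(mask, stack, depths)
        assert out.loc[0, "depth_um"] == 0.0

    def test_background_mask_excluded(self):
        mask, stack, depths = self.make_stack()
        mask2 = mask.copy()
        mask2[2:5, 2:5] = 2  # region with no signal anywhere
        out = assign_cell_depths(mask2, stack, depths)
        assert np.isnan(out.set_index("label").loc[2, "depth_um"])


class TestCorrelationVsDepth:
    def test_identical_surface_slice_r_one(self):
        rng = np.random.default_rng(0)
        surf = rng.random((32, 32)) * 100
        stack = np.stack([surf, rng.random((32, 32)) * 100])
        prof = correlation_vs_depth(surf, stack, [0.0, 2.0])
        assert prof.r[0] == pytest.approx(1.0, abs=1e-12)
        assert prof.argmax_depth() == 0.0

    def test_uncorrelated_noise_low_r(self):
        rng = np.random.default_rng(1)
        surf = rng.random((64, 64))
        stack = np.stack([surf, rng.random((64, 64))])
        prof = correlation_vs_depth(surf, stack, [0.0, 2.0], foreground_quantile=0.0)
        assert abs(prof.r[1]) < 0.1

    def test_zero_variance_slice_is_nan(self):
        rng = np.random.default_rng(2)
        surf = rng.random((16, 16))
        stack = np.stack([surf, np.full((16, 16), 3.0)])
        prof = correlation_vs_depth(surf, stack, [0.0, 2.0], foreground_quantile=0.0)
        assert np.isnan(prof.r[1])

    def test_single_slice_rejected(self):
        with pytest.raises(ValueError):
            correlation_vs_depth(np.ones((8, 8)), np.ones((1, 8, 8)), [0.0])
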