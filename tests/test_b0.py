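"""B0 field maps and the sub-voxel phase modulator."""

import numpy as np
import pytest

import fidsim as fs


class TestGridShape:
    @pytest.mark.parametrize(
        "spectro, anat, expected",
        [
            ((20, 20, 20), (1, 1, 1), (20, 20, 20)),
            ((20, 10, 8), (2, 2, 2), (10, 5, 4)),
            ((1, 1, 1), (2, 2, 2), (1, 1, 1)),
        ],
    )
    def test_quotient_floored_at_one(self, spectro, anat, expected):
        assert fs.grid_shape_from_voxels(spectro, anat) == expected

    def test_non_positive_sizes_rejected(self):
        with pytest.raises(ValueError):
            fs.grid_shape_from_voxels((20, 20, 0), (1, 1, 1))


class TestFieldMap:
    def test_zero_gradient_gives_constant_map(self):
        fm = fs.simulate_field_map(fs.B0Params(mu=-3.0, grid_shape=(4, 5, 6)))
        np.testing.assert_allclose(fm.offsets, -3.0)

    def test_corner_value_approaches_mu_plus_half_widths(self):
        # mu=10, dx=dy=dz=1.5 (delta=3 Hz): extreme sampled corner sits at
        # mu + (dx+dy+dz)*(G-1)/G under midpoint sampling -> mu +- 4.5 as G grows
        p = fs.B0Params.isotropic(mu=10.0, delta=3.0, grid_shape=(5, 5, 5))
        fm = fs.simulate_field_map(p)
        assert fm.offsets[-1, -1, -1] == pytest.approx(10.0 + 4.5 * 4 / 5)
        assert fm.offsets[0, 0, 0] == pytest.approx(10.0 - 4.5 * 4 / 5)
        big = fs.simulate_field_map(
            fs.B0Params.isotropic(mu=10.0, delta=3.0, grid_shape=(150, 150, 150))
        )
        assert big.offsets[-1, -1, -1] == pytest.approx(14.5, abs=0.04)

    @pytest.mark.parametrize("shape", [(1, 1, 1), (2, 3, 4), (10, 10, 10), (7, 1, 2)])
    def test_grid_mean_equals_mu(self, shape):
        p = fs.B0Params(mu=4.2, dx=3.0, dy=1.0, dz=0.5, grid_shape=shape)
        # brute-force mean over all sub-voxel points
        assert fs.simulate_field_map(p).offsets.mean() == pytest.approx(4.2, abs=1e-12)

    def test_center_value_is_mu_for_odd_grids(self):
        p = fs.B0Params(mu=7.0, dx=2.0, dy=2.0, dz=2.0, grid_shape=(5, 7, 9))
        assert fs.simulate_field_map(p).offsets[2, 3, 4] == pytest.approx(7.0)

    def test_nonlinear_profile_hook(self):
        p = fs.B0Params(mu=0.0, dx=1.0, grid_shape=(11, 1, 1))
        fm = fs.simulate_field_map(p, profiles=(lambda u: u**3, None, None))
        u = (2 * np.arange(11) + 1 - 11) / 11
        np.testing.assert_allclose(fm.offsets[:, 0, 0], u**3)


class TestModulator:
    def test_constant_map_is_pure_phase_ramp(self, grid):
        fm = fs.simulate_field_map(fs.B0Params(mu=10.0, grid_shape=(3, 3, 3)))
        m = fs.b0_modulator(fm, grid.t)
        np.testing.assert_allclose(m, np.exp(-2j * np.pi * 10.0 * grid.t), atol=1e-12)
        np.testing.assert_allclose(np.abs(m), 1.0)

    def test_magnitude_one_at_t0_and_bounded(self, grid, rng):
        p = fs.B0Params(mu=rng.uniform(-20, 20), dx=3.0, dy=1.0, dz=2.0, grid_shape=(4, 5, 6))
        m = fs.b0_modulator(fs.simulate_field_map(p), grid.t)
        assert abs(m[0]) == pytest.approx(1.0)
        assert np.all(np.abs(m) <= 1.0 + 1e-12)

    def test_matches_brute_force_sum_1d(self, grid):
        p = fs.B0Params(mu=0.0, dx=4.0, grid_shape=(9, 1, 1))
        fm = fs.simulate_field_map(p)
        m = fs.b0_modulator(fm, grid.t)
        # explicit loop over sub-voxel points
        brute = np.zeros(grid.n_points, dtype=complex)
        for dw in fm.offsets.ravel():
            brute += np.exp(-2j * np.pi * dw * grid.t)
        np.testing.assert_allclose(m, brute / fm.offsets.size, atol=1e-10)

    def test_matches_brute_force_sum_3d(self, grid):
        p = fs.B0Params(mu=-5.0, dx=2.0, dy=3.0, dz=1.0, grid_shape=(3, 4, 5))
        fm = fs.simulate_field_map(p)
        m = fs.b0_modulator(fm, grid.t)
        brute = np.exp(-2j * np.pi * np.outer(fm.offsets.ravel(), grid.t)).mean(axis=0)
        np.testing.assert_allclose(m, brute, atol=1e-10)

    def test_separable_map_factorizes(self, grid):
        px = fs.B0Params(mu=0.0, dx=2.0, grid_shape=(4, 1, 1))
        py = fs.B0Params(mu=0.0, dy=3.0, grid_shape=(1, 5, 1))
        pz = fs.B0Params(mu=0.0, dz=1.0, grid_shape=(1, 1, 6))
        p3 = fs.B0Params(mu=0.0, dx=2.0, dy=3.0, dz=1.0, grid_shape=(4, 5, 6))
        mx = fs.b0_modulator(fs.simulate_field_map(px), grid.t)
        my = fs.b0_modulator(fs.simulate_field_map(py), grid.t)
        mz = fs.b0_modulator(fs.simulate_field_map(pz), grid.t)
        m3 = fs.b0_modulator(fs.simulate_field_map(p3), grid.t)
        np.testing.assert_allclose(m3, mx * my * mz, atol=1e-10)

    def test_continuum_limit_is_sinc_damping(self):
        # 1-D gradient at G=101 approaches |sin(2 pi dx t)/(2 pi dx t)|
        t = np.arange(2048) / 2000.0
        dx = 2.0
        p = fs.B0Params(mu=0.0, dx=dx, grid_shape=(101, 1, 1))
        m = fs.b0_modulator(fs.simulate_field_map(p), t)
        closed = np.abs(np.sinc(2 * dx * t))  # np.sinc(x) = sin(pi x)/(pi x)
        assert np.abs(np.abs(m) - closed).max() < 0.01


class TestApplyB0:
    def test_identity_modulator(self, naa_fid):
        out = fs.apply_b0(naa_fid, np.ones_like(naa_fid))
        np.testing.assert_array_equal(out, naa_fid)

    def test_length_mismatch_rejected(self, naa_fid):
        with pytest.raises(ValueError):
            fs.apply_b0(naa_fid, np.ones(7))

    def test_constant_mu_displaces_peak_by_mu_hz(self, grid, naa_fid):
        # homogeneous 10 Hz offset: peak moves +10 Hz (= 10/127.7 ppm)
        fm = fs.simulate_field_map(fs.B0Params(mu=10.0, grid_shape=(3, 3, 3)))
        m = fs.b0_modulator(fm, grid.t)
        d_ppm = fs.peak_ppm(fs.apply_b0(naa_fid, m), grid) - fs.peak_ppm(naa_fid, grid)
        assert d_ppm * grid.carrier_frequency == pytest.approx(10.0, abs=grid.hz_per_bin)

    def test_mean_offset_sets_displacement_for_any_map(self, grid, naa_fid):
        p = fs.B0Params(mu=7.0, dx=1.5, dy=1.0, dz=0.5, grid_shape=(6, 6, 6))
        m = fs.b0_modulator(fs.simulate_field_map(p), grid.t)
        d_ppm = fs.peak_ppm(fs.apply_b0(naa_fid, m), grid) - fs.peak_ppm(naa_fid, grid)
        assert d_ppm * grid.carrier_frequency == pytest.approx(7.0, abs=grid.hz_per_bin)

    def test_increasing_delta_damps_spectral_max(self, grid, naa_fid):
        heights = []
        for delta in (0.0, 2.0, 5.0, 10.0):
            p = fs.B0Params.isotropic(mu=0.0, delta=delta, grid_shape=(9, 9, 9))
            m = fs.b0_modulator(fs.simulate_field_map(p), grid.t)
            heights.append(fs.to_spectrum(fs.apply_b0(naa_fid, m)).real.max())
        assert all(a >= b for a, b in zip(heights, heights[1:]))
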