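"""Phase offsets, eddy currents, noise injection and SNR measurement."""

import numpy as np
import pytest

import fidsim as fs
from fidsim.fourier import to_spectrum


class TestPhase0:
    def test_zero_is_identity(self, naa_fid):
        np.testing.assert_array_equal(fs.apply_phase0(naa_fid, 0.0), naa_fid)

    def test_180_negates(self, naa_fid):
        np.testing.assert_allclose(fs.apply_phase0(naa_fid, 180.0), -naa_fid, atol=1e-12)

    def test_90_swaps_absorption_into_dispersion(self, naa_fid):
        # multiplying by e^{-i pi/2} = -i: the real channel becomes the
        # former imaginary (dispersion) channel
        spec0 = to_spectrum(naa_fid)
        spec90 = to_spectrum(fs.apply_phase0(naa_fid, 90.0))
        np.testing.assert_allclose(spec90.real, spec0.imag, atol=1e-9)

    def test_composition_and_periodicity(self, naa_fid):
        ab = fs.apply_phase0(fs.apply_phase0(naa_fid, 25.0), 17.0)
        np.testing.assert_allclose(ab, fs.apply_phase0(naa_fid, 42.0), atol=1e-12)
        np.testing.assert_allclose(fs.apply_phase0(naa_fid, 360.0), naa_fid, atol=1e-12)


class TestPhase1:
    def test_zero_is_identity(self, grid, naa_fid):
        spec = to_spectrum(naa_fid)
        np.testing.assert_array_equal(
            fs.apply_phase1(spec, 0.0, grid.ppm, grid.ppm_ref), spec
        )

    @pytest.mark.parametrize("phi1", [-30.0, 5.0, 120.0])
    def test_reference_point_invariant(self, grid, naa_fid, phi1):
        spec = to_spectrum(naa_fid)
        out = fs.apply_phase1(spec, phi1, grid.ppm, grid.ppm_ref)
        k = int(np.argmin(np.abs(grid.ppm - grid.ppm_ref)))
        assert grid.ppm[k] == pytest.approx(grid.ppm_ref, abs=1e-12)
        assert out[k] == spec[k]

    def test_phase_one_ppm_from_ref_equals_phi1_degrees(self, grid):
        spec = np.ones(grid.n_points, dtype=complex)
        out = fs.apply_phase1(spec, 37.0, grid.ppm, grid.ppm_ref)
        k = int(np.argmin(np.abs(grid.ppm - (grid.ppm_ref + 1.0))))
        applied = -np.angle(out[k], deg=True)
        assert applied == pytest.approx(37.0 * (grid.ppm[k] - grid.ppm_ref), abs=1e-9)


class TestEddy:
    def test_zero_amplitude_identity(self, naa_fid, grid):
        np.testing.assert_array_equal(fs.apply_eddy(naa_fid, 0.0, 0.15, grid.t), naa_fid)

    def test_pointwise_phase_formula(self, grid):
        # A0=5 Hz, tc0=0.15 s: phi(0.15) = 2*pi*5*0.15*e^-1 rad
        ones = np.ones(grid.n_points, dtype=complex)
        out = fs.apply_eddy(ones, 5.0, 0.15, grid.t)
        k = int(np.argmin(np.abs(grid.t - 0.15)))
        expected = 2 * np.pi * 5.0 * grid.t[k] * np.exp(-grid.t[k] / 0.15)
        assert -np.angle(out[k]) % (2 * np.pi) == pytest.approx(expected % (2 * np.pi), abs=1e-9)

    def test_long_time_constant_is_global_shift(self, grid, naa_fid):
        # tc0 >> acquisition: effect converges to a +A0 Hz frequency shift
        out = fs.apply_eddy(naa_fid, 8.0, 1e4, grid.t)
        d_ppm = fs.peak_ppm(out, grid) - fs.peak_ppm(naa_fid, grid)
        assert d_ppm * grid.carrier_frequency == pytest.approx(8.0, abs=grid.hz_per_bin)

    def test_unitary_operators_preserve_magnitude(self, grid, naa_fid):
        # phase0/phase1 preserve |F| pointwise; the eddy operator reshapes
        # the spectrum (that is its artifact) but preserves the pointwise
        # time-domain modulus and the total spectral energy
        mag = np.abs(to_spectrum(naa_fid))
        out0 = fs.apply_phase0(naa_fid, 73.0)
        np.testing.assert_allclose(np.abs(to_spectrum(out0)), mag, atol=1e-9)
        phased = fs.apply_phase1(to_spectrum(naa_fid), 45.0, grid.ppm, grid.ppm_ref)
        np.testing.assert_allclose(np.abs(phased), mag, atol=1e-9)
        eddied = fs.apply_eddy(naa_fid, 5.0, 0.05, grid.t)
        np.testing.assert_allclose(np.abs(eddied), np.abs(naa_fid), atol=1e-12)
        assert np.sum(np.abs(to_spectrum(eddied)) ** 2) == pytest.approx(
            np.sum(mag**2)
        )


class TestNoise:
    def test_same_seed_bit_reproducible(self, naa_fid):
        a, _ = fs.add_noise(naa_fid, 15.0, 1.0, 42)
        b, _ = fs.add_noise(naa_fid, 15.0, 1.0, 42)
        np.testing.assert_array_equal(a, b)

    def test_different_seeds_nearly_uncorrelated(self, naa_fid):
        a, _ = fs.add_noise(naa_fid, 15.0, 1.0, 1)
        b, _ = fs.add_noise(naa_fid, 15.0, 1.0, 2)
        na, nb = (a - naa_fid).real, (b - naa_fid).real
        assert abs(np.corrcoef(na, nb)[0, 1]) < 0.1

    def test_infinite_snr_sentinel(self, naa_fid):
        out, sigma = fs.add_noise(naa_fid, np.inf, 1.0, 0)
        np.testing.assert_array_equal(out, naa_fid)
        assert sigma == 0.0

    def test_non_positive_snr_rejected(self, naa_fid):
        with pytest.raises(ValueError):
            fs.add_noise(naa_fid, 0.0, 1.0, 0)

    def test_spectral_noise_sd_matches_sigma(self, grid):
        # Monte-Carlo estimate of signal-free spectral SD vs analytic sigma
        zero = np.zeros(grid.n_points, dtype=complex)
        sds = []
        for seed in range(200):
            noisy, sigma = fs.add_noise(zero, 20.0, 1.0, seed)
            sds.append(np.std(to_spectrum(noisy).real))
        assert np.mean(sds) == pytest.approx(sigma, rel=0.05)

    def test_correlated_mode_quadrature_channels(self, grid):
        zero = np.zeros(grid.n_points, dtype=complex)
        noisy, _ = fs.add_noise(zero, 10.0, 1.0, 3, correlated=True)
        # imaginary channel is the quadrature partner: same power, orthogonal
        re, im = noisy.real, noisy.imag
        assert np.std(im) == pytest.approx(np.std(re), rel=0.1)
        assert abs(np.corrcoef(re, im)[0, 1]) < 0.15

    def test_requested_vs_measured_snr(self, toy_basis, grid):
        # mean measured SNR within 3% of target over 100 replicates
        p = fs.MetaboliteParams(
            amplitudes={"NAA": 1.0, "Cr": 0.8, "Cho": 0.6},
            lorentzian={n: 2.0 for n in toy_basis.names},
        )
        clean = fs.scale_and_sum(toy_basis, p)
        ref = to_spectrum(clean).real.max()
        measured = [
            fs.measure_snr(to_spectrum(fs.add_noise(clean, 15.0, ref, seed)[0]))
            for seed in range(100)
        ]
        assert np.mean(measured) == pytest.approx(15.0, rel=0.03)


class TestMeasureSnr:
    def test_scale_invariance(self, grid, naa_fid):
        noisy, _ = fs.add_noise(naa_fid, 15.0, 1.0, 5)
        spec = to_spectrum(noisy)
        assert fs.measure_snr(3.7 * spec) == pytest.approx(fs.measure_snr(spec))

    def test_noiseless_returns_infinity(self):
        spec = np.zeros(1024, dtype=complex)
        spec[100] = 1.0  # lone peak, dead-flat noise region
        assert fs.measure_snr(spec) == np.inf

    def test_empty_region_rejected(self, naa_fid):
        with pytest.raises(ValueError):
            fs.measure_snr(to_spectrum(naa_fid), noise_region=slice(0, 1))
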