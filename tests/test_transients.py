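"""Coil operator: sensitivities, per-transient SNR, drifts, recombination."""

import numpy as np
import pytest

import fidsim as fs
from fidsim.fourier import to_spectrum
from fidsim.transients import rebuild_transient


@pytest.fixture(scope="module")
def clean(toy_basis):
    p = fs.MetaboliteParams(
        amplitudes={"NAA": 10.0, "Cr": 8.0, "Cho": 2.0},
        lorentzian={n: 2.0 for n in toy_basis.names},
    )
    return fs.scale_and_sum(toy_basis, p)


@pytest.fixture(scope="module")
def ref_height(clean):
    return float(to_spectrum(clean).real.max())


class TestSensitivities:
    def test_zero_std_all_equal_mu(self):
        cfg = fs.CoilConfig(n_transients=6, sens_std=0.0)
        np.testing.assert_allclose(fs.sample_sensitivities(cfg, 0), 1.0)

    def test_default_sampler_mean_and_clamp(self):
        # clamp [0, 2] is symmetric about mu=1.0, so the mean is preserved
        cfg = fs.CoilConfig(n_transients=10**6)
        draws = fs.sample_sensitivities(cfg, 12345)
        assert draws.mean() == pytest.approx(1.0, abs=0.002)
        assert draws.min() >= 0.0 and draws.max() <= 2.0


class TestTransientSnrs:
    def test_single_coil_zero_spread(self):
        cfg = fs.CoilConfig(n_transients=1, snr_spread=0.0)
        np.testing.assert_allclose(fs.sample_transient_snrs(15.0, cfg, 0), [15.0])

    def test_four_coils_zero_spread(self):
        cfg = fs.CoilConfig(n_transients=4, snr_spread=0.0)
        np.testing.assert_allclose(fs.sample_transient_snrs(15.0, cfg, 0), 7.5)

    def test_mean_maintained_with_spread(self):
        cfg = fs.CoilConfig(n_transients=8)
        draws = np.concatenate(
            [fs.sample_transient_snrs(15.0, cfg, seed) for seed in range(2000)]
        )
        assert draws.mean() == pytest.approx(15.0 / np.sqrt(8), rel=0.02)


class TestMakeTransients:
    def test_single_coil_degenerate_is_add_noise(self, clean, grid, ref_height):
        cfg = fs.CoilConfig(n_transients=1, sens_std=0.0, snr_spread=0.0,
                            drift_freq_range=0.0, drift_phase_range=0.0)
        tset = fs.make_transients(clean, grid, cfg, 15.0, ref_height, seed=4)
        rec = tset.records[0]
        expected, sigma = fs.add_noise(clean, 15.0, ref_height, rec.noise_seed)
        np.testing.assert_array_equal(tset.fids[0], expected)
        assert tset.sigma[0] == pytest.approx(sigma)

    @pytest.mark.parametrize("n_coils", [2, 4, 8])
    def test_sqrt_c_snr_gain(self, clean, grid, ref_height, n_coils):
        # averaging C transients improves SNR by sqrt(C), within 10%
        cfg = fs.CoilConfig(n_transients=n_coils, sens_std=0.0, snr_spread=0.0,
                            drift_freq_range=0.0, drift_phase_range=0.0)
        gains = []
        for rep in range(50):
            tset = fs.make_transients(clean, grid, cfg, 15.0, ref_height, seed=900 + rep)
            combined_snr = fs.measure_snr(to_spectrum(fs.combine_transients(tset)))
            transient_snr = np.mean(
                [fs.measure_snr(to_spectrum(f)) for f in tset.fids]
            )
            gains.append(combined_snr / transient_snr)
        assert 0.9 * np.sqrt(n_coils) <= np.mean(gains) <= 1.1 * np.sqrt(n_coils)

    def test_ground_truth_records_resimulate_exactly(self, clean, grid, ref_height):
        cfg = fs.CoilConfig(n_transients=8)
        tset = fs.make_transients(clean, grid, cfg, 15.0, ref_height, seed=21)
        for i in range(cfg.n_transients):
            np.testing.assert_array_equal(rebuild_transient(tset, i, clean), tset.fids[i])

    def test_drift_round_trip_realigns(self, clean, grid, ref_height):
        # negating the stored drifts re-aligns each transient to within noise
        cfg = fs.CoilConfig(n_transients=4, sens_std=0.0, snr_spread=0.0)
        tset = fs.make_transients(clean, grid, cfg, 200.0, ref_height, seed=8)
        for i, rec in enumerate(tset.records):
            aligned = fs.apply_phase0(
                fs.apply_freq_shift(tset.fids[i], -rec.freq_drift_hz, grid.t),
                -rec.phase_drift_deg,
            )
            resid = np.abs(to_spectrum(aligned - clean).real)
            assert resid.max() < 8 * tset.sigma[i]

    def test_correlated_noise_matches_requested_matrix(self, grid):
        corr = np.array(
            [[1.0, 0.5, 0.2, 0.1],
             [0.5, 1.0, 0.5, 0.2],
             [0.2, 0.5, 1.0, 0.5],
             [0.1, 0.2, 0.5, 1.0]]
        )
        g = fs.build_grid(4096, 2000.0)
        cfg = fs.CoilConfig(n_transients=4, sens_std=0.0, snr_spread=0.0,
                            drift_freq_range=0.0, drift_phase_range=0.0,
                            noise_correlation=corr)
        tset = fs.make_transients(
            np.full(4096, 1e-12, dtype=complex), g, cfg, 15.0, 1.0, seed=9
        )
        empirical = np.corrcoef(tset.fids.real)
        assert np.abs(empirical - corr).max() < 0.05

    def test_grid_mismatch_rejected(self, clean, ref_height):
        small = fs.build_grid(256, 2000.0)
        with pytest.raises(ValueError):
            fs.make_transients(clean, small, fs.CoilConfig(), 15.0, ref_height, 0)


class TestCombine:
    def make_set(self, clean, grid, n):
        from fidsim.transients import TransientRecord, TransientSet

        fids = np.tile(clean, (n, 1))
        recs = [TransientRecord(1.0, 15.0, 0.0, 0.0, i) for i in range(n)]
        return TransientSet(fids=fids, records=recs, grid=grid, sigma=np.zeros(n))

    def test_single_transient_identity(self, clean, grid):
        tset = self.make_set(clean, grid, 1)
        np.testing.assert_allclose(fs.combine_transients(tset), clean)

    def test_identical_transients_average_to_any_input(self, clean, grid):
        tset = self.make_set(clean, grid, 5)
        np.testing.assert_allclose(fs.combine_transients(tset), clean)

    def test_single_nonzero_weight_selects_that_transient(self, clean, grid):
        tset = self.make_set(clean, grid, 3)
        tset.fids[1] *= 2.0
        out = fs.combine_transients(tset, weights=[0.0, 1.0, 0.0])
        np.testing.assert_allclose(out, 2.0 * clean)

    def test_sum_mode_equals_average_mode(self, clean, grid, rng):
        tset = self.make_set(clean, grid, 4)
        w = rng.uniform(0.1, 1.0, 4)
        np.testing.assert_allclose(
            fs.combine_transients(tset, w, mode="average"),
            fs.combine_transients(tset, w, mode="sum"),
        )

    def test_all_zero_weights_rejected(self, clean, grid):
        with pytest.raises(ValueError):
            fs.combine_transients(self.make_set(clean, grid, 2), weights=[0.0, 0.0])
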