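"""Spectral estimation, band power bookkeeping, smoothing, and PAF."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import signal as sps

from tcdeeg.spectral import (DEFAULT_BANDS, Band, FrequencyBands, Spectrum,
                             band_power, compute_paf, epoch_fft_power,
                             relative_power, smooth_on_cortex, welch_psd)

BIN_COUNTS = {"delta": 3, "theta": 8, "alpha1": 4, "alpha2": 5,
              "beta": 34, "gamma1": 50, "gamma2": 50}


def flat_unit_spectrum(fmax=100.0):
    f = np.arange(0.0, fmax + 0.25, 0.5)
    return Spectrum(f, np.ones((1, len(f))))


class TestEpochFFT:
    def test_matches_scipy_periodogram(self, rng):
        x = rng.standard_normal((4, 3, 1000))
        _, want = sps.periodogram(x, fs=500.0, window="hann",
                                  detrend="linear", axis=-1)
        got = epoch_fft_power(x, 500.0)
        assert np.allclose(got.power, want, rtol=1e-10, atol=1e-15)

    def test_sinusoid_power_concentrates_at_its_bin(self):
        t = np.arange(1000) / 500.0
        x = np.sin(2 * np.pi * 10.0 * t)[None, None, :]
        spec = epoch_fft_power(x, 500.0)
        f = spec.frequencies
        near = np.abs(f - 10.0) <= 0.5 + 1e-9
        assert spec.power[0, 0, near].sum() / spec.power.sum() > 0.99

    def test_zero_signal_zero_spectrum(self):
        spec = epoch_fft_power(np.zeros((2, 1, 1000)), 500.0)
        assert np.all(spec.power == 0)

    def test_white_noise_spectrum_flat_after_averaging(self, rng):
        x = rng.standard_normal((10000, 1, 500))       # fs 250, 2-s epochs
        spec = epoch_fft_power(x, 250.0)
        mean = spec.power.mean(axis=0)[0]
        f = spec.frequencies
        sel = (f >= 2.0) & (f <= 90.0)
        assert mean[sel].max() / mean[sel].min() < 1.2

    def test_wrong_epoch_length_rejected(self):
        with pytest.raises(ValueError):
            epoch_fft_power(np.zeros((1, 1, 900)), 500.0)


class TestWelch:
    def test_matches_scipy_welch(self, rng):
        x = rng.standard_normal((3, 7000))
        _, want = sps.welch(x, fs=500.0, window="hann", nperseg=1000,
                            noverlap=500, detrend="linear", axis=-1)
        got = welch_psd(x, 500.0)
        assert np.allclose(got.power, want, rtol=1e-10, atol=1e-15)

    def test_peak_bin_agrees_with_epoch_path(self):
        t = np.arange(20000) / 500.0
        x = np.sin(2 * np.pi * 9.5 * t)
        w = welch_psd(x[None, :], 500.0)
        e = epoch_fft_power(x[:10000].reshape(10, 1, 1000), 500.0)
        assert (w.frequencies[w.power[0].argmax()]
                == e.frequencies[e.power.mean(axis=0)[0].argmax()])

    def test_parseval_for_white_noise(self, rng):
        sigma = 2.5
        x = sigma * rng.standard_normal((1, 200000))
        spec = welch_psd(x, 500.0)
        var = np.trapezoid(spec.power[0], spec.frequencies)
        assert var == pytest.approx(sigma**2, rel=0.05)

    def test_quadratic_amplitude_scaling(self, rng):
        x = rng.standard_normal((2, 5000))
        a = welch_psd(x, 500.0).power
        b = welch_psd(2 * x, 500.0).power
        assert np.allclose(b, 4 * a, rtol=1e-10)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros((1, 1200)), 500.0)


class TestBandPower:
    def test_flat_spectrum_band_bin_counts(self):
        bp = band_power(flat_unit_spectrum())
        assert bp.shape == (1, 7)
        for name, count in BIN_COUNTS.items():
            j = DEFAULT_BANDS.names.index(name)
            assert bp[0, j] == count

    def test_boundary_10hz_goes_to_alpha2(self):
        spec = flat_unit_spectrum()
        power = np.zeros_like(spec.power)
        power[0, np.where(spec.frequencies == 10.0)[0][0]] = 7.0
        bp = band_power(Spectrum(spec.frequencies, power))
        assert bp[0, DEFAULT_BANDS.names.index("alpha2")] == 7.0
        assert bp.sum() == 7.0

    def test_60hz_falls_in_notch_gap(self):
        spec = flat_unit_spectrum()
        power = np.zeros_like(spec.power)
        power[0, np.where(spec.frequencies == 60.0)[0][0]] = 5.0
        bp = band_power(Spectrum(spec.frequencies, power))
        assert bp.sum() == 0.0

    def test_grid_not_covering_band_rejected(self):
        f = np.arange(0.0, 60.25, 0.5)     # covers gamma1 but not gamma2
        with pytest.raises(ValueError, match="gamma2"):
            band_power(Spectrum(f, np.ones((1, len(f)))))

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError):
            FrequencyBands((Band("a", 2.0, 5.0), Band("b", 4.0, 8.0)))


class TestRelativePower:
    def test_single_band_holds_all_power(self):
        abs_p = np.zeros((1, 7))
        abs_p[0, 2] = 3.3
        table = relative_power(abs_p)
        assert table.rel_power[0, 2] == 1.0
        assert table.rel_power.sum() == 1.0

    def test_epoch_averaging_is_arithmetic(self):
        abs_p = np.zeros((2, 1, 7))
        abs_p[0, 0] = [0, 2, 0, 0, 0, 8, 0]     # theta share 0.2
        abs_p[1, 0] = [0, 4, 0, 0, 0, 6, 0]     # theta share 0.4
        table = relative_power(abs_p)
        assert table.rel_power[0, 1] == pytest.approx(0.3)

    def test_flat_spectrum_shares_are_bin_fractions(self):
        bp = band_power(flat_unit_spectrum())
        table = relative_power(bp)
        j = DEFAULT_BANDS.names.index("gamma1")
        assert table.rel_power[0, j] == pytest.approx(50.0 / 154.0)

    def test_zero_total_power_rejected(self):
        with pytest.raises(ValueError):
            relative_power(np.zeros((1, 7)))

    @given(st.integers(0, 2**31 - 1))
    def test_shares_always_sum_to_one(self, seed):
        r = np.random.default_rng(seed)
        abs_p = r.exponential(size=(3, 2, 7)) + 1e-12
        table = relative_power(abs_p)
        assert np.allclose(table.rel_epoch.sum(axis=-1), 1.0, atol=1e-10)

    def test_pipeline_equals_one_shot_oracle(self, rng):
        power = rng.exponential(size=(5, 2, 181))
        f = np.arange(0, 90.5, 0.5)
        spec = Spectrum(f, power, per_epoch=True)
        table = relative_power(band_power(spec))
        # brute force per epoch/location
        for e in range(5):
            for loc in range(2):
                shares = []
                for b in DEFAULT_BANDS:
                    m = (f >= b.low) & (f < b.high)
                    shares.append(power[e, loc, m].sum())
                shares = np.array(shares) / np.sum(shares)
                assert np.allclose(table.rel_epoch[e, loc], shares, atol=1e-12)


class TestSmoothing:
    def test_constant_map_unchanged(self, mesh):
        out = smooth_on_cortex(np.full(mesh.n_vertices, 3.7), mesh, 10.0)
        assert np.abs(out - 3.7).max() < 1e-12

    def test_impulse_mass_conserved(self, mesh):
        x = np.zeros(mesh.n_vertices)
        x[17] = 5.0
        out = smooth_on_cortex(x, mesh, 15.0)
        assert out.sum() == pytest.approx(5.0, abs=1e-9)

    def test_zero_fwhm_is_identity(self, mesh, rng):
        x = rng.standard_normal(mesh.n_vertices)
        assert np.array_equal(smooth_on_cortex(x, mesh, 0.0), x)

    def test_mean_preserved(self, mesh, rng):
        x = rng.standard_normal(mesh.n_vertices)
        out = smooth_on_cortex(x, mesh, 12.0)
        assert out.mean() == pytest.approx(x.mean(), abs=1e-9)


class TestPAF:
    def _bump_spectrum(self, centers_heights):
        f = np.arange(2.0, 45.5, 0.5)
        base = 100.0 / f          # 1/f background
        for c, h in centers_heights:
            base = base + h * np.exp(-0.5 * ((f - c) / 0.6) ** 2)
        return Spectrum(f, base[None, :])

    def test_single_bump_recovered(self):
        paf = compute_paf(self._bump_spectrum([(9.5, 50.0)]))
        assert paf[0] == 9.5

    def test_monotone_spectrum_flagged_missing(self):
        f = np.arange(2.0, 45.5, 0.5)
        spec = Spectrum(f, (100.0 / f)[None, :])
        assert np.isnan(compute_paf(spec)[0])

    def test_larger_of_two_bumps_wins(self):
        paf = compute_paf(self._bump_spectrum([(7.0, 80.0), (10.0, 40.0)]))
        assert paf[0] == 7.0

    def test_peak_outside_window_ignored(self):
        paf = compute_paf(self._bump_spectrum([(20.0, 500.0)]))
        assert np.isnan(paf[0])
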