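"""Spectral estimation: Welch PSD, band power, magnitude spectra, the 5 Hz
band-power emulation, and tremor-peak detection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

import tremorloop as tl

FS = 422.0


def tone(freq, fs=FS, dur=10.0, amp=1.0):
    t = np.arange(0.0, dur, 1.0 / fs)
    return amp * np.sin(2 * np.pi * freq * t)


class TestWelchPsd:
    def test_zero_input_gives_zero_power(self):
        spec = tl.welch_psd(np.zeros(4220), FS)
        assert np.all(spec.power == 0)

    def test_unit_tone_integrates_to_half_with_peak_at_the_tone(self):
        spec = tl.welch_psd(tone(20.0), FS)
        total = spec.power.sum() * spec.df
        assert total == pytest.approx(0.5, rel=0.05)
        assert abs(spec.freqs_hz[np.argmax(spec.power)] - 20.0) <= spec.df

    def test_quadratic_homogeneity(self):
        x = tone(20.0) + 0.3 * np.random.default_rng(0).standard_normal(4220)
        a = tl.welch_psd(x, FS)
        b = tl.welch_psd(2 * x, FS)
        assert np.allclose(b.power, 4 * a.power)

    def test_parseval_for_broadband_noise(self):
        x = np.random.default_rng(1).standard_normal(int(30 * FS))
        spec = tl.welch_psd(x, FS)
        assert spec.power.sum() * spec.df == pytest.approx(np.mean(x**2), rel=0.05)

    def test_short_input_raises(self):
        with pytest.raises(ValueError, match="segment"):
            tl.welch_psd(np.zeros(100), FS)


class TestNormalization:
    def _stats(self, n_bins=50):
        rng = np.random.default_rng(2)
        freqs = np.arange(n_bins, dtype=float)
        return tl.NormStats(freqs, rng.uniform(1, 3, n_bins), rng.uniform(0.1, 1, n_bins))

    def test_spectrum_equal_to_training_mean_maps_to_zero(self):
        stats = self._stats()
        spec = tl.Spectrum(stats.freqs_hz, stats.mean.copy(), FS)
        z = tl.normalize_spectrum(spec, stats)
        assert np.allclose(z.power, 0.0)
        assert z.normalized

    def test_z_score_definition(self):
        stats = tl.NormStats(np.array([0.0, 1.0]), np.array([2.0, 2.0]), np.array([1.0, 1.0]))
        spec = tl.Spectrum(np.array([0.0, 1.0]), np.array([4.0, 2.0]), FS)
        z = tl.normalize_spectrum(spec, stats)
        assert z.power[0] == pytest.approx(2.0)
        assert z.power[1] == pytest.approx(0.0)

    def test_round_trip_is_identity(self):
        stats = self._stats()
        rng = np.random.default_rng(3)
        spec = tl.Spectrum(stats.freqs_hz, rng.uniform(0, 5, stats.mean.size), FS)
        back = tl.denormalize_spectrum(tl.normalize_spectrum(spec, stats), stats)
        assert np.allclose(back.power, spec.power, atol=1e-12)

    def test_zero_sd_bin_is_named_in_the_error(self):
        stats = self._stats()
        stats.sd[7] = 0.0
        spec = tl.Spectrum(stats.freqs_hz, stats.mean.copy(), FS)
        with pytest.raises(ValueError, match="7 Hz"):
            tl.normalize_spectrum(spec, stats)

    def test_grid_mismatch_rejected(self):
        stats = self._stats()
        spec = tl.Spectrum(stats.freqs_hz + 0.5, stats.mean.copy(), FS)
        with pytest.raises(ValueError, match="grid"):
            tl.normalize_spectrum(spec, stats)


class TestBandPower:
    def test_full_band_recovers_total_variance(self):
        x = tone(20.0) + tone(50.0)
        spec = tl.welch_psd(x, FS)
        assert tl.band_power(spec, (0.0, FS / 2)) == pytest.approx(1.0, rel=0.05)

    def test_two_tone_beta_band_isolates_the_in_band_tone(self):
        spec = tl.welch_psd(tone(3.0) + tone(20.0), FS)
        assert tl.band_power(spec, (12.0, 30.0)) == pytest.approx(0.5, rel=0.05)

    def test_malformed_band_raises(self):
        spec = tl.welch_psd(tone(20.0), FS)
        with pytest.raises(ValueError, match="malformed"):
            tl.band_power(spec, (30.0, 12.0))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(split=st.floats(5.0, 200.0))
    def test_additive_over_a_partition_of_the_spectrum(self, split):
        x = np.random.default_rng(4).standard_normal(4220)
        spec = tl.welch_psd(x, FS)
        total = tl.band_power(spec, (0.0, FS / 2))
        lo = tl.band_power(spec, (0.0, split))
        hi = tl.band_power(spec, (split, FS / 2))
        assert lo + hi == pytest.approx(total, rel=1e-9)


class TestGyroMagnitudeSpectrum:
    def test_single_axis_signal_equals_that_axis_psd(self):
        g = np.zeros((4220, 3))
        g[:, 1] = tone(5.0, dur=10.0)
        mag = tl.gyro_magnitude_spectrum(g, FS)
        axis = tl.welch_psd(g[:, 1], FS)
        assert np.allclose(mag.power, axis.power)

    def test_identical_axes_scale_by_sqrt3(self):
        x = tone(5.0, dur=10.0)
        g = np.stack([x, x, x], axis=1)
        mag = tl.gyro_magnitude_spectrum(g, FS)
        axis = tl.welch_psd(x, FS)
        assert np.allclose(mag.power, np.sqrt(3) * axis.power)

    def test_matches_brute_force_euclidean_norm_of_per_axis_psds(self):
        rng = np.random.default_rng(5)
        g = rng.standard_normal((4220, 3))
        mag = tl.gyro_magnitude_spectrum(g, FS)
        # independent oracle straight from scipy
        cfg = tl.WindowConfig()
        psds = [
            sps.welch(g[:, i], fs=FS, window="hann", nperseg=422, noverlap=211,
                      detrend=False)[1]
            for i in range(3)
        ]
        oracle = np.sqrt(psds[0] ** 2 + psds[1] ** 2 + psds[2] ** 2)
        assert np.allclose(mag.power, oracle)

    def test_axis_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            tl.gyro_magnitude_spectrum(np.zeros((100, 2)), FS)


class TestPeakTremorFrequency:
    FS_IMU = 100.0

    def _mag(self, x):
        g = np.zeros((x.size, 3))
        g[:, 0] = x
        return tl.gyro_magnitude_spectrum(g, self.FS_IMU, tl.WindowConfig(4.0, 0.5))

    def test_pure_tone_recovered_within_one_bin(self):
        mag = self._mag(tone(5.0, self.FS_IMU, 30.0))
        res = tl.peak_tremor_frequency(mag)
        assert res.found and abs(res.peak_hz - 5.0) <= mag.df

    def test_larger_of_two_peaks_wins(self):
        x = tone(3.0, self.FS_IMU, 30.0, amp=2.0) + tone(6.0, self.FS_IMU, 30.0, amp=1.0)
        res = tl.peak_tremor_frequency(self._mag(x))
        assert abs(res.peak_hz - 3.0) <= 0.25

    def test_sub_movement_band_content_yields_no_peak(self):
        # <1.5 Hz is ordinary movement, not tremor
        res = tl.peak_tremor_frequency(self._mag(tone(0.5, self.FS_IMU, 30.0, amp=5.0)))
        assert not res.found
        assert res.peak_hz is None

    def test_invariant_to_overall_scaling(self):
        x = tone(5.0, self.FS_IMU, 30.0) + 0.1 * np.random.default_rng(6).standard_normal(3000)
        a = tl.peak_tremor_frequency(self._mag(x))
        b = tl.peak_tremor_frequency(self._mag(100 * x))
        assert a.peak_hz == b.peak_hz

    def test_coarse_resolution_rejected(self):
        mag = self._mag(tone(5.0, self.FS_IMU, 30.0))
        coarse = tl.Spectrum(mag.freqs_hz[::4], mag.power[::4], self.FS_IMU)
        with pytest.raises(ValueError, match="resolution"):
            tl.peak_tremor_frequency(coarse)


class TestStreamingBandPower:
    def test_zero_input_zero_stream(self):
        s = tl.streaming_band_power(np.zeros(int(10 * FS)), FS, (12.0, 30.0))
        assert np.all(s.values == 0)

    def test_output_rate_contract(self):
        s = tl.streaming_band_power(np.zeros(int(60 * FS)), FS, (12.0, 30.0))
        assert s.values.size == 300
        assert np.allclose(np.diff(s.times_s), 0.2)

    def test_steady_tone_converges_to_tone_power_and_tracks_steps(self):
        smoothing = 0.5
        x = tone(20.0, dur=30.0)
        s = tl.streaming_band_power(x, FS, (12.0, 30.0), smoothing)
        assert np.mean(s.values[50:]) == pytest.approx(0.5, rel=0.10)
        # amplitude step: reaches 90% of the new level within 3 time constants
        x2 = np.concatenate([x, tone(20.0, dur=30.0, amp=2.0)])
        s2 = tl.streaming_band_power(x2, FS, (12.0, 30.0), smoothing)
        k_step = 150  # step at t=30 s
        k_3tau = k_step + int(np.ceil(3 * smoothing * 5))
        assert s2.values[k_3tau] >= 0.5 + 0.9 * (2.0 - 0.5)

    def test_monotone_in_tone_amplitude(self):
        outs = [
            np.mean(tl.streaming_band_power(tone(20.0, dur=20.0, amp=a), FS,
                                            (12.0, 30.0)).values[50:])
            for a in (0.5, 1.0, 2.0, 4.0)
        ]
        assert all(b > a for a, b in zip(outs[:-1], outs[1:]))

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="fs/2"):
            tl.streaming_band_power(np.zeros(4220), FS, (150.0, 300.0))

    def test_causal_chain_matches_batch_computation(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(int(20 * FS))
        batch = tl.streaming_band_power(x, FS, (12.0, 30.0))
        chain = tl.spectral.CausalBandPower(FS, (12.0, 30.0))
        out = []
        step = 422 // 5
        idx = np.floor(np.arange(1, 101) * FS / 5).astype(int)
        prev = 0
        for i in idx:
            out.append(chain.push(x[prev:i]))
            prev = i
        assert np.allclose(out, batch.values[:100], rtol=1e-9)


def test_spectrum_csv_round_trip(tmp_path):
    spec = tl.welch_psd(tone(20.0), FS)
    spec.to_csv(tmp_path / "spec.csv")
    back = tl.Spectrum.from_csv(tmp_path / "spec.csv", FS)
    assert np.allclose(back.freqs_hz, spec.freqs_hz)
    assert np.allclose(back.power, spec.power)
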