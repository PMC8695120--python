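"""Spectral estimation and band-power features.

Welch periodograms (Hann window, 1 s segments, 50% overlap by default) feed
both the movement classifiers and the gyroscope tremor metrics; a digital
band-pass / square / smooth / decimate chain emulates the implanted device's
5 Hz analog band-power telemetry.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

BAND_POWER_RATE_HZ = 5.0  # device band-power telemetry rate
TREMOR_SEARCH_BAND = (1.5, 8.0)  # sub-1.5 Hz content is ordinary movement


@dataclass(frozen=True)
class WindowConfig:
    """Welch segmentation: Hann window, ``segment_length_s`` long segments
    overlapping by ``overlap_fraction``."""

    segment_length_s: float = 1.0
    overlap_fraction: float = 0.5
    window_shape: str = "hann"

    def __post_init__(self) -> None:
        if not (0 <= self.overlap_fraction < 1):
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.segment_length_s <= 0:
            raise ValueError("segment_length_s must be positive")

    def nperseg(self, fs: float) -> int:
        n = int(round(self.segment_length_s * fs))
        if n < 8:
            raise ValueError(
                f"segment of {self.segment_length_s} s at {fs} Hz is only {n} samples; "
                "need at least 8"
            )
        return n

    def noverlap(self, fs: float) -> int:
        return int(round(self.overlap_fraction * self.nperseg(fs)))


@dataclass
class Spectrum:
    """One-sided power spectral density on a uniform bin grid."""

    freqs_hz: np.ndarray
    power: np.ndarray
    fs: float
    window_cfg: WindowConfig | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs_hz.shape != self.power.shape or self.freqs_hz.ndim != 1:
            raise ValueError("freqs_hz and power must be equal-length 1-D arrays")
        if np.any(np.diff(self.freqs_hz) <= 0):
            raise ValueError("frequency bins must be strictly increasing")
        if not self.normalized and np.any(self.power < -1e-12):
            raise ValueError("un-normalized power must be non-negative")

    @property
    def df(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])

    def to_csv(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.freqs_hz, self.power]),
            delimiter=",",
            header="freq_hz,power",
            comments="",
        )

    @classmethod
    def from_csv(cls, path, fs: float) -> "Spectrum":
        data = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(data[:, 0], data[:, 1], fs)


@dataclass
class NormStats:
    """Per-bin mean and standard deviation of training power spectra."""

    freqs_hz: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self) -> None:
        self.freqs_hz = np.asarray(self.freqs_hz, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (self.freqs_hz.shape == self.mean.shape == self.sd.shape):
            raise ValueError("freqs_hz, mean and sd must have identical shapes")
        if np.any(self.sd < 0):
            raise ValueError("standard deviations must be >= 0")

    @classmethod
    def from_spectra(cls, spectra: list[Spectrum]) -> "NormStats":
        grid = spectra[0].freqs_hz
        for s in spectra[1:]:
            _check_grid(s.freqs_hz, grid)
        power = np.stack([s.power for s in spectra])
        return cls(grid.copy(), power.mean(axis=0), power.std(axis=0))


@dataclass
class BandPowerStream:
    """Band power sampled at the device telemetry rate (5 Hz)."""

    times_s: np.ndarray
    values: np.ndarray
    band_hz: tuple[float, float]
    rate_hz: float = BAND_POWER_RATE_HZ

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.shape != self.values.shape:
            raise ValueError("times_s and values must have the same shape")
        if np.any(self.values < 0):
            raise ValueError("band power must be non-negative")


def _check_grid(freqs: np.ndarray, reference: np.ndarray) -> None:
    if freqs.shape != reference.shape or not np.allclose(freqs, reference, atol=1e-9):
        raise ValueError("frequency bin grids do not match")


def welch_psd(samples, fs: float, window_cfg: WindowConfig | None = None) -> Spectrum:
    """One-sided Welch PSD with a Hann window.

    No detrending is applied, so the integral over all bins approximates the
    mean-square of the signal (Parseval).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    cfg = window_cfg or WindowConfig()
    x = np.asarray(samples, dtype=float)
    nperseg = cfg.nperseg(fs)
    if x.size < nperseg:
        raise ValueError(
            f"need at least one full segment ({nperseg} samples at {fs} Hz); got {x.size}"
        )
    f, p = sps.welch(
        x, fs=fs, window=cfg.window_shape, nperseg=nperseg,
        noverlap=cfg.noverlap(fs), detrend=False,
    )
    return Spectrum(f, p, fs, cfg)


def normalize_spectrum(spectrum: Spectrum, stats: NormStats) -> Spectrum:
    """Per-bin z-score against training statistics."""
    _check_grid(spectrum.freqs_hz, stats.freqs_hz)
    zero = np.flatnonzero(stats.sd == 0)
    if zero.size:
        raise ValueError(
            "degenerate training data: zero standard deviation at bin(s) "
            + ", ".join(f"{stats.freqs_hz[i]:g} Hz" for i in zero[:5])
        )
    z = (spectrum.power - stats.mean) / stats.sd
    return replace(spectrum, power=z, normalized=True)


def denormalize_spectrum(spectrum: Spectrum, stats: NormStats) -> Spectrum:
    """Inverse of :func:`normalize_spectrum`."""
    _check_grid(spectrum.freqs_hz, stats.freqs_hz)
    if not spectrum.normalized:
        raise ValueError("spectrum is not normalized")
    return replace(spectrum, power=spectrum.power * stats.sd + stats.mean, normalized=False)


def band_power(spectrum: Spectrum, band_hz: tuple[float, float]) -> float:
    """Integrated power over the half-open band [lo, hi), by bin center."""
    if spectrum.normalized:
        raise ValueError("band power requires an un-normalized spectrum")
    lo, hi = band_hz
    if not lo < hi:
        raise ValueError(f"malformed band [{lo}, {hi}): need lo < hi")
    if lo < 0 or hi > spectrum.fs / 2 + spectrum.df:
        raise ValueError(f"band [{lo}, {hi}) exceeds [0, fs/2]")
    mask = (spectrum.freqs_hz >= lo) & (spectrum.freqs_hz < hi)
    if not mask.any():
        raise ValueError(f"band [{lo}, {hi}) Hz contains no frequency bins")
    return float(spectrum.power[mask].sum() * spectrum.df)


def gyro_magnitude_spectrum(
    gyro_3axis, fs: float, window_cfg: WindowConfig | None = None
) -> Spectrum:
    """Per-axis Welch PSD combined across axes by per-bin Euclidean norm."""
    g = np.asarray(gyro_3axis, dtype=float)
    if g.ndim != 2 or g.shape[1] != 3:
        raise ValueError("gyro_3axis must have shape (n_samples, 3)")
    spectra = [welch_psd(g[:, i], fs, window_cfg) for i in range(3)]
    power = np.sqrt(sum(s.power**2 for s in spectra))
    return Spectrum(spectra[0].freqs_hz, power, fs, spectra[0].window_cfg)


@dataclass(frozen=True)
class PeakTremorResult:
    """Peak tremor frequency and the +-halfwidth band around it (or no peak)."""

    peak_hz: float | None
    tremor_band_hz: tuple[float, float] | None

    @property
    def found(self) -> bool:
        return self.peak_hz is not None


def peak_tremor_frequency(
    magnitude_spectrum: Spectrum,
    band_halfwidth_hz: float = 1.0,
    search_band: tuple[float, float] = TREMOR_SEARCH_BAND,
    floor_factor: float = 4.0,
) -> PeakTremorResult:
    """Largest local spectral maximum in the 1.5-8.0 Hz tremor band.

    A candidate peak must exceed ``floor_factor`` times the median in-band
    level (the noise-floor criterion); if none does the result reports no
    tremor peak.  Ties resolve to the lower frequency.  The result's band is
    peak +- ``band_halfwidth_hz``, clipped to the search band.
    """
    spec = magnitude_spectrum
    lo, hi = search_band
    if spec.df > 0.5 + 1e-9:
        raise ValueError(
            f"spectral resolution {spec.df:.3g} Hz is too coarse; need <= 0.5 Hz "
            "over the tremor band"
        )
    mask = (spec.freqs_hz >= lo) & (spec.freqs_hz <= hi)
    if not mask.any():
        raise ValueError("spectrum has no bins in the tremor search band")
    p = spec.power[mask]
    f = spec.freqs_hz[mask]
    floor = floor_factor * float(np.median(p))
    peaks, _ = sps.find_peaks(p)
    peaks = peaks[p[peaks] > floor]
    if peaks.size == 0:
        return PeakTremorResult(None, None)
    best = peaks[np.argmax(p[peaks])]  # argmax returns the first (lowest-f) max
    peak_hz = float(f[best])
    band = (max(lo, peak_hz - band_halfwidth_hz), min(hi, peak_hz + band_halfwidth_hz))
    return PeakTremorResult(peak_hz, band)


def streaming_band_power(
    samples,
    fs: float,
    band_hz: tuple[float, float],
    smoothing_s: float = 0.5,
    output_rate_hz: float = BAND_POWER_RATE_HZ,
) -> BandPowerStream:
    """Emulated device band-power telemetry at 5 Hz.

    Causal chain: 4th-order Butterworth band-pass, square, single-pole
    exponential smoother with time constant ``smoothing_s``, then decimation
    to ``output_rate_hz``.  For a steady in-band tone of amplitude *a* the
    output settles at the tone power a**2/2.
    """
    lo, hi = band_hz
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band [{lo}, {hi}) Hz must lie strictly inside (0, fs/2)")
    if smoothing_s < 0.2:
        raise ValueError("smoothing_s must be >= 0.2 s")
    x = np.asarray(samples, dtype=float)
    n_out = int(np.floor(x.size / fs * output_rate_hz + 1e-9))
    if n_out == 0 and x.size > 0:
        raise ValueError("input shorter than one output sample period")
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfilt(sos, x) ** 2
    alpha = 1.0 - np.exp(-1.0 / (fs * smoothing_s))
    smoothed = sps.lfilter([alpha], [1.0, -(1.0 - alpha)], y)
    idx = np.floor((np.arange(1, n_out + 1) * fs / output_rate_hz)).astype(int) - 1
    values = np.clip(smoothed[idx], 0.0, None)
    times = np.arange(1, n_out + 1) / output_rate_hz
    return BandPowerStream(times, values, (lo, hi), output_rate_hz)


class CausalBandPower:
    """Sample-streaming version of :func:`streaming_band_power`.

    Feed raw samples chunk by chunk; ``latest`` holds the current smoothed
    band-power estimate.  Identical filter chain and coefficients as the
    batch function, with filter state carried across chunks.
    """

    def __init__(self, fs: float, band_hz: tuple[float, float], smoothing_s: float = 0.5):
        lo, hi = band_hz
        if not (0 < lo < hi < fs / 2):
            raise ValueError(f"band [{lo}, {hi}) Hz must lie strictly inside (0, fs/2)")
        if smoothing_s < 0.2:
            raise ValueError("smoothing_s must be >= 0.2 s")
        self.fs = fs
        self.band_hz = (lo, hi)
        self._sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
        self._zi = np.zeros((self._sos.shape[0], 2))
        self._alpha = 1.0 - np.exp(-1.0 / (fs * smoothing_s))
        self._state = 0.0
        self.latest = 0.0

    def push(self, samples) -> float:
        x = np.asarray(samples, dtype=float)
        if x.size:
            y, self._zi = sps.sosfilt(self._sos, x, zi=self._zi)
            sq = y**2
            sm, zf = sps.lfilter(
                [self._alpha], [1.0, -(1.0 - self._alpha)], sq,
                zi=np.array([(1.0 - self._alpha) * self._state]),
            )
            self._state = sm[-1]
            self.latest = max(float(sm[-1]), 0.0)
        return self.latest
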