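"""Synthetic essential-tremor patient ("plant") for closed-loop testing.

The plant emits the sensor streams an implanted research system would see:

* cortical LFP (µV): pink (1/f) background, a band-limited beta rhythm
  (unit-RMS carrier spanning the beta band) whose amplitude drops during
  overt and imagined movement (event-related desynchronization), and a
  stimulation artifact — a tone at the stimulation
  frequency plus a small broadband floor lift, both proportional to the
  applied amplitude;
* 9-axis IMU at 100 Hz: gyroscope (deg/s) carrying a sub-1.5 Hz voluntary
  movement component and a tremor tone in the 1.5–8 Hz band whose amplitude
  grows during movement and is suppressed by stimulation through a sigmoid
  efficacy curve, with first-order (exponential) dynamics; accelerometer and
  compass channels are noise placeholders;
* surface EMG (mV): baseline noise with broadband bursts during overt
  movement.

All stochastic components are pre-generated from named substreams of one
seed and are independent of the stimulation input, so a closed-loop run and
a scripted run with the same seed share sample-exact noise.  Only the
artifact amplitude and the tremor-suppression target depend on the applied
stimulation, and those are advanced incrementally tick by tick.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Callable, Union

import numpy as np
from scipy import signal as sps

from ._rng import substream
from .schedule import PromptSchedule
from .stim import StimLog, StimParameters

SUPPORTED_LFP_FS = (200.0, 422.0, 800.0)


@dataclass
class TimeSeries:
    """Uniformly sampled multichannel stream starting at t = 0."""

    data: np.ndarray  # (n,) or (n, n_channels)
    fs: float
    channels: tuple[str, ...]
    units: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 1:
            self.data = self.data[:, None]
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel count does not match data shape")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class PatientConfig:
    """Parameters of the synthetic patient.

    Amplitudes are in the stream's native units (LFP µV, gyro deg/s, EMG mV);
    the efficacy curve maps applied stimulation voltage to the fraction of
    tremor amplitude suppressed, rescaled so that 0 V suppresses nothing.
    """

    lfp_fs: float = 422.0
    imu_fs: float = 100.0
    emg_fs: float = 500.0
    beta_band: tuple[float, float] = (12.0, 30.0)
    beta_baseline_amp_uv: float = 4.0
    erd_fraction: float = 0.5
    pink_noise_scale_uv: float = 3.0
    stim_artifact_gain_uv_per_v: float = 0.5
    artifact_floor_gain_uv_per_v: float = 0.05
    tremor_freq_hz: float = 5.0
    tremor_baseline_amp_dps: float = 20.0
    tremor_time_constant_s: float = 0.5
    transition_time_constant_s: float = 0.5
    movement_lowfreq_amp_dps: float = 30.0
    movement_lowfreq_hz: float = 0.4
    gyro_noise_scale_dps: float = 0.5
    accel_noise_scale_mps2: float = 0.05
    compass_noise_scale_au: float = 0.01
    emg_noise_scale_mv: float = 0.02
    emg_burst_gain_mv: float = 0.5
    therapeutic_voltage_v: float = 2.0
    efficacy_half_max_v: float = 1.0
    efficacy_slope_per_v: float = 4.0

    def __post_init__(self) -> None:
        self.beta_band = tuple(float(b) for b in self.beta_band)
        self.validate()

    def validate(self) -> None:
        if float(self.lfp_fs) not in SUPPORTED_LFP_FS:
            raise ValueError(f"lfp_fs must be one of {SUPPORTED_LFP_FS}")
        if not (1.5 <= self.tremor_freq_hz <= 8.0):
            raise ValueError("tremor_freq_hz must lie in the 1.5-8.0 Hz tremor band")
        if not (0 <= self.erd_fraction <= 1):
            raise ValueError("erd_fraction must be in [0, 1]")
        for name in (
            "beta_baseline_amp_uv", "pink_noise_scale_uv", "stim_artifact_gain_uv_per_v",
            "artifact_floor_gain_uv_per_v", "tremor_baseline_amp_dps",
            "movement_lowfreq_amp_dps", "gyro_noise_scale_dps", "emg_noise_scale_mv",
            "emg_burst_gain_mv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.tremor_time_constant_s <= 0 or self.transition_time_constant_s <= 0:
            raise ValueError("time constants must be positive")
        if self.efficacy_slope_per_v <= 0:
            raise ValueError("efficacy_slope_per_v must be positive")

    def efficacy(self, amplitude_v) -> np.ndarray:
        """Fraction of tremor amplitude suppressed at a given voltage.

        A logistic in voltage (half-max ``efficacy_half_max_v``, slope
        ``efficacy_slope_per_v``) rescaled so efficacy(0) = 0 and the
        asymptote remains 1; always in [0, 1].
        """
        v = np.asarray(amplitude_v, dtype=float)
        k, v0 = self.efficacy_slope_per_v, self.efficacy_half_max_v
        raw = 1.0 / (1.0 + np.exp(-k * (v - v0)))
        floor = 1.0 / (1.0 + np.exp(k * v0))
        eff = (raw - floor) / (1.0 - floor)
        return np.clip(eff, 0.0, 1.0)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta_band"] = list(self.beta_band)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PatientConfig":
        d = dict(d)
        if "beta_band" in d:
            d["beta_band"] = tuple(d["beta_band"])
        return cls(**d)


@dataclass
class SessionRecording:
    """Synchronized multi-stream recording plus its ground truth."""

    lfp: TimeSeries
    imu: TimeSeries
    emg: TimeSeries
    stim_log: StimLog
    schedule: PromptSchedule
    seed: int
    config: PatientConfig

    def __post_init__(self) -> None:
        dur = self.schedule.total_duration_s
        for name, ts in (("lfp", self.lfp), ("imu", self.imu), ("emg", self.emg)):
            expected = dur * ts.fs
            if abs(ts.n_samples - expected) > 1.0:
                raise ValueError(
                    f"{name} stream has {ts.n_samples} samples, expected "
                    f"~{expected:.0f} for {dur} s at {ts.fs} Hz"
                )

    @property
    def gyro(self) -> np.ndarray:
        """Gyroscope channels (n, 3) in deg/s."""
        return self.imu.data[:, :3]


IMU_CHANNELS = (
    "gyro_x_dps", "gyro_y_dps", "gyro_z_dps",
    "accel_x_mps2", "accel_y_mps2", "accel_z_mps2",
    "mag_x_au", "mag_y_au", "mag_z_au",
)


def _pink_noise(rng: np.random.Generator, n: int, fs: float, scale: float) -> np.ndarray:
    """Spectrally shaped (1/f power) Gaussian noise with RMS ``scale``.

    Amplitude shaping flattens below 1 Hz to keep the variance finite.
    """
    if scale == 0 or n == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = 1.0 / np.sqrt(np.maximum(f, 1.0))
    x = np.fft.irfft(spec * shaping, n)
    sd = x.std()
    return x * (scale / sd) if sd > 0 else x


def _beta_carrier(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Unit-RMS band-limited Gaussian carrier for the beta rhythm.

    Zero-phase filtered so the carrier is stationary from the first sample;
    the ERD envelope multiplies it, so band power tracks envelope**2.
    """
    if n == 0:
        return np.zeros(0)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _smooth_gate(raw: np.ndarray, fs: float, tau_s: float) -> np.ndarray:
    """First-order exponential response of a binary prompt gate."""
    a = np.exp(-1.0 / (fs * tau_s))
    y, _ = sps.lfilter([1.0 - a], [1.0, -a], raw, zi=np.zeros(1))
    return y


class TremorPlant:
    """Incremental session generator; see the module docstring for the model.

    ``advance_to(t_end, stim_v)`` generates all streams up to ``t_end``
    assuming the applied amplitude is held at ``stim_v`` over the new chunk,
    then records that amplitude in the stimulation log.
    """

    def __init__(
        self,
        config: PatientConfig,
        schedule: PromptSchedule,
        stim_params: StimParameters,
        seed: int,
    ):
        config.validate()
        if stim_params.frequency_hz >= config.lfp_fs / 2:
            raise ValueError(
                f"stimulation frequency {stim_params.frequency_hz} Hz is at or above "
                f"the LFP Nyquist frequency {config.lfp_fs / 2} Hz; the artifact tone "
                "would alias"
            )
        self.config = config
        self.schedule = schedule
        self.stim_params = stim_params
        self.seed = int(seed)
        dur = schedule.total_duration_s
        cfg = config

        self.n_lfp = int(round(dur * cfg.lfp_fs))
        self.n_imu = int(round(dur * cfg.imu_fs))
        self.n_emg = int(round(dur * cfg.emg_fs))
        t_lfp = np.arange(self.n_lfp) / cfg.lfp_fs
        t_imu = np.arange(self.n_imu) / cfg.imu_fs
        t_emg = np.arange(self.n_emg) / cfg.emg_fs
        self._t_lfp, self._t_imu, self._t_emg = t_lfp, t_imu, t_emg

        # Prompt gates.  ERD responds to overt and imagined movement; the
        # peripheral channels (gyro, EMG) respond to overt movement only.
        move_lfp = schedule.mask(t_lfp, "movement")
        erd_raw = (move_lfp | schedule.mask(t_lfp, "imagined")).astype(float)
        self._move_raw_imu = schedule.mask(t_imu, "movement").astype(float)
        move_emg = schedule.mask(t_emg, "movement").astype(float)
        g_erd = _smooth_gate(erd_raw, cfg.lfp_fs, cfg.transition_time_constant_s)
        g_move_imu = _smooth_gate(self._move_raw_imu, cfg.imu_fs, cfg.transition_time_constant_s)
        g_move_emg = _smooth_gate(move_emg, cfg.emg_fs, cfg.transition_time_constant_s)

        # Stimulation-independent parts of every stream, full session.
        beta_amp = cfg.beta_baseline_amp_uv * (1.0 - cfg.erd_fraction * g_erd)
        self._lfp_base = (
            _pink_noise(substream(seed, "lfp_noise"), self.n_lfp, cfg.lfp_fs,
                        cfg.pink_noise_scale_uv)
            + beta_amp * _beta_carrier(
                substream(seed, "beta_carrier"), self.n_lfp, cfg.lfp_fs, cfg.beta_band
            )
        )
        self._artifact_white = (
            substream(seed, "artifact_floor").standard_normal(self.n_lfp)
            if cfg.artifact_floor_gain_uv_per_v > 0 else np.zeros(self.n_lfp)
        )

        gyro_rng = substream(seed, "gyro_noise")
        gyro = gyro_rng.standard_normal((self.n_imu, 3)) * cfg.gyro_noise_scale_dps
        lowfreq = np.sin(2 * np.pi * cfg.movement_lowfreq_hz * t_imu) * g_move_imu
        gyro[:, 0] += cfg.movement_lowfreq_amp_dps * lowfreq
        gyro[:, 1] += 0.6 * cfg.movement_lowfreq_amp_dps * lowfreq
        gyro[:, 2] += 0.3 * cfg.movement_lowfreq_amp_dps * lowfreq
        self._gyro_base = gyro
        self._accel = (
            substream(seed, "accel_noise").standard_normal((self.n_imu, 3))
            * cfg.accel_noise_scale_mps2
        )
        self._compass = (
            substream(seed, "compass_noise").standard_normal((self.n_imu, 3))
            * cfg.compass_noise_scale_au
        )
        emg_rng = substream(seed, "emg_noise")
        self._emg = (
            emg_rng.standard_normal(self.n_emg) * cfg.emg_noise_scale_mv
            + cfg.emg_burst_gain_mv * g_move_emg * emg_rng.standard_normal(self.n_emg)
        )

        # Stimulation-dependent state, advanced chunk by chunk.
        self.lfp = np.zeros(self.n_lfp)
        self._tremor_amp = np.zeros(self.n_imu)
        a = np.exp(-1.0 / (cfg.imu_fs * cfg.tremor_time_constant_s))
        self._tremor_ba = ([1.0 - a], [1.0, -a])
        self._tremor_zi = np.zeros(1)
        self._cursor_lfp = 0
        self._cursor_imu = 0
        self._log_times: list[float] = []
        self._log_amps: list[float] = []

    @property
    def duration_s(self) -> float:
        return self.schedule.total_duration_s

    def _end_index(self, t_end: float, fs: float, n: int) -> int:
        return min(n, int(np.floor(t_end * fs + 1e-9)))

    def advance_to(self, t_end: float, stim_v: float) -> None:
        """Generate all streams on [current time, t_end) at amplitude stim_v."""
        stim_v = float(stim_v)
        if stim_v < 0:
            raise ValueError("stimulation amplitude must be >= 0")
        cfg, sp = self.config, self.stim_params
        i0, i1 = self._cursor_lfp, self._end_index(t_end, cfg.lfp_fs, self.n_lfp)
        if i1 > i0:
            sl = slice(i0, i1)
            t = self._t_lfp[sl]
            chunk = self._lfp_base[sl].copy()
            if stim_v > 0:
                chunk += (
                    cfg.stim_artifact_gain_uv_per_v * stim_v
                    * np.sin(2 * np.pi * sp.frequency_hz * t)
                    + cfg.artifact_floor_gain_uv_per_v * stim_v * self._artifact_white[sl]
                )
            self.lfp[sl] = chunk
            if not self._log_times or self._log_amps[-1] != stim_v:
                self._log_times.append(self._t_lfp[i0])
                self._log_amps.append(stim_v)
            self._cursor_lfp = i1

        j0, j1 = self._cursor_imu, self._end_index(t_end, cfg.imu_fs, self.n_imu)
        if j1 > j0:
            sl = slice(j0, j1)
            eff = float(self.config.efficacy(stim_v))
            target = self._move_raw_imu[sl] * cfg.tremor_baseline_amp_dps * (1.0 - eff)
            b, a = self._tremor_ba
            amp, self._tremor_zi = sps.lfilter(b, a, target, zi=self._tremor_zi)
            self._tremor_amp[sl] = amp
            self._cursor_imu = j1

    def build_recording(self) -> SessionRecording:
        """Assemble the finished session (requires the full duration generated)."""
        if self._cursor_lfp < self.n_lfp or self._cursor_imu < self.n_imu:
            raise RuntimeError("plant has not been advanced to the end of the session")
        cfg = self.config
        gyro = self._gyro_base.copy()
        gyro[:, 0] += self._tremor_amp * np.sin(2 * np.pi * cfg.tremor_freq_hz * self._t_imu)
        imu = TimeSeries(
            np.hstack([gyro, self._accel, self._compass]),
            cfg.imu_fs, IMU_CHANNELS, units="mixed",
        )
        if not self._log_times:  # zero-length edge; keep the log well-formed
            self._log_times, self._log_amps = [0.0], [0.0]
        if self._log_times[0] > 0.0:
            self._log_times.insert(0, 0.0)
            self._log_amps.insert(0, 0.0)
        return SessionRecording(
            lfp=TimeSeries(self.lfp, cfg.lfp_fs, ("lfp_uv",), units="uV"),
            imu=imu,
            emg=TimeSeries(self._emg, cfg.emg_fs, ("emg_mv",), units="mV"),
            stim_log=StimLog(self._log_times, self._log_amps),
            schedule=self.schedule,
            seed=self.seed,
            config=cfg,
        )


StimInput = Union[None, float, StimLog, Callable[[float], float]]


def simulate_session(
    config: PatientConfig,
    schedule: PromptSchedule,
    stim: StimInput = None,
    seed: int = 0,
    stim_params: StimParameters | None = None,
    control_tick_s: float = 0.4,
) -> SessionRecording:
    """Run the plant open-loop under a scripted or callback stimulation input.

    ``stim`` may be None (no stimulation), a constant voltage, a
    :class:`StimLog` step function, or a callable ``f(t_s) -> volts``
    queried once per ``control_tick_s``.  Deterministic for a fixed seed.
    """
    if stim_params is None:
        stim_params = StimParameters()
    plant = TremorPlant(config, schedule, stim_params, seed)
    dur = schedule.total_duration_s
    if stim is None or isinstance(stim, (int, float)):
        plant.advance_to(dur, 0.0 if stim is None else float(stim))
    elif isinstance(stim, StimLog):
        for t0, t1, v in stim.segments(0.0, dur):
            plant.advance_to(t1, v)
    elif callable(stim):
        n_ticks = int(np.ceil(dur / control_tick_s - 1e-9))
        for k in range(n_ticks):
            t1 = min((k + 1) * control_tick_s, dur)
            plant.advance_to(t1, float(stim(k * control_tick_s)))
    else:
        raise TypeError(f"unsupported stimulation input {type(stim)!r}")
    return plant.build_recording()
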