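"""Therapy evaluation: tremor severity, delivered electrical energy, and
detection/latency metrics.

Tremor severity is computed per sliding window from the gyroscope magnitude
spectrum as (tremor-band power)^2 / total power — squaring the band power
emphasises windows where the tremor rhythm dominates, while dividing by
total power discounts windows where broadband voluntary movement dominates.

Total electrical energy delivered (TEED) integrates V(t)^2 * f * p / z over
the experiment; it is reported in joules and, more usefully, as the ratio
to the energy a conventional always-on stimulator at the maximum amplitude
would have delivered over the same interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedule import PromptSchedule
from .spectral import WindowConfig, band_power, gyro_magnitude_spectrum
from .stim import StimLog, StimParameters

TREMOR_BAND_LIMITS = (1.5, 8.0)


@dataclass
class TremorMetrics:
    """Per-window tremor quantification from the gyroscope."""

    times_s: np.ndarray  # window centers
    tremor_band_hz: tuple[float, float]
    tremor_band_power: np.ndarray  # (deg/s)^2
    total_power: np.ndarray  # (deg/s)^2
    severity: np.ndarray  # unitless

    def mean_severity(self, schedule: PromptSchedule | None = None, label: str | None = None):
        """Mean severity, optionally restricted to windows whose center
        carries the given prompt label."""
        if schedule is None or label is None:
            return float(self.severity.mean())
        mask = schedule.mask(self.times_s, label)
        if not mask.any():
            raise ValueError(f"no severity windows fall in {label!r} intervals")
        return float(self.severity[mask].mean())


@dataclass
class TEEDResult:
    teed_joules: float
    teed_ratio_vs_cdbs: float
    teed_per_s_movement: float | None
    teed_per_s_rest: float | None


@dataclass
class DetectionReport:
    """Tick/interval-level agreement between stimulation and the schedule."""

    sensitivity_pct: float  # % of movement time with effective stimulation
    false_positive_pct: float  # % of rest time with effective stimulation
    stim_time_movement_pct: float  # % of movement time with any stimulation
    stim_time_rest_pct: float
    latencies_s: np.ndarray  # one per movement event; NaN if never effective
    reached_effective: np.ndarray  # bool per movement event


def tremor_severity(
    gyro_3axis,
    fs: float,
    tremor_band: tuple[float, float],
    window_s: float = 2.0,
    hop_s: float = 1.0,
    eps: float = 1e-10,
    severity_exponent: float = 2.0,
    window_cfg: WindowConfig | None = None,
) -> TremorMetrics:
    """Sliding-window tremor severity from 3-axis gyroscope data.

    Each window's magnitude spectrum is integrated over ``tremor_band`` and
    over the full [0, fs/2) range; severity = band_power**severity_exponent
    / total_power, with windows below the ``eps`` total-power floor scored 0.
    """
    lo, hi = tremor_band
    if not (TREMOR_BAND_LIMITS[0] <= lo < hi <= TREMOR_BAND_LIMITS[1]):
        raise ValueError(
            f"tremor_band must lie within {TREMOR_BAND_LIMITS} Hz; got [{lo}, {hi}]"
        )
    if window_s < 2.0:
        raise ValueError("severity window must be at least 2 s")
    if window_s < 2.0 / lo:
        raise ValueError(
            f"severity window of {window_s} s is shorter than two tremor periods "
            f"at {lo} Hz"
        )
    g = np.asarray(gyro_3axis, dtype=float)
    if g.ndim != 2 or g.shape[1] != 3:
        raise ValueError("gyro_3axis must have shape (n_samples, 3)")
    win_cfg = window_cfg or WindowConfig(segment_length_s=window_s, overlap_fraction=0.0)
    n_win = int(round(window_s * fs))
    hop = int(round(hop_s * fs))
    starts = range(0, g.shape[0] - n_win + 1, hop)
    times, bp_arr, tot_arr, sev_arr = [], [], [], []
    for s in starts:
        chunk = g[s : s + n_win]
        spec = gyro_magnitude_spectrum(chunk, fs, win_cfg)
        bp = band_power(spec, (lo, hi))
        total = band_power(spec, (0.0, fs / 2))
        sev = 0.0 if total < eps else bp**severity_exponent / total
        times.append((s + n_win / 2) / fs)
        bp_arr.append(bp)
        tot_arr.append(total)
        sev_arr.append(sev)
    return TremorMetrics(
        np.array(times), (lo, hi), np.array(bp_arr), np.array(tot_arr), np.array(sev_arr)
    )


def compute_teed(
    stim_log: StimLog,
    stim_params: StimParameters,
    interval: tuple[float, float],
    schedule: PromptSchedule | None = None,
) -> TEEDResult:
    """TEED in joules over ``interval`` and its ratio to always-on cDBS.

    When a schedule is given, per-second energies over movement and rest
    time are also reported (None when the schedule has no such time).
    """
    t0, t1 = interval
    if t1 <= t0:
        raise ValueError("empty evaluation interval")
    coeff = stim_params.power_coefficient_w_per_v2
    segments = stim_log.segments(t0, t1)

    def energy(a: float, b: float) -> float:
        return sum(
            v**2 * coeff * (min(b, e) - max(a, s))
            for s, e, v in segments
            if min(b, e) > max(a, s)
        )

    teed = energy(t0, t1)
    cdbs = stim_params.max_amplitude_v**2 * coeff * (t1 - t0)
    ratio = teed / cdbs

    per_move = per_rest = None
    if schedule is not None:
        move = [
            (max(t0, iv.start_s), min(t1, iv.end_s))
            for iv in schedule.movement_intervals
            if iv.end_s > t0 and iv.start_s < t1
        ]
        rest = [
            (max(t0, a), min(t1, b))
            for a, b in schedule.rest_intervals()
            if b > t0 and a < t1
        ]
        move_dur = sum(b - a for a, b in move)
        rest_dur = sum(b - a for a, b in rest)
        if move_dur > 0:
            per_move = sum(energy(a, b) for a, b in move) / move_dur
        if rest_dur > 0:
            per_rest = sum(energy(a, b) for a, b in rest) / rest_dur
    return TEEDResult(teed, ratio, per_move, per_rest)


def _merge_intervals(mask_starts, mask_ends):
    out = []
    for a, b in zip(mask_starts, mask_ends):
        if out and a <= out[-1][1] + 1e-12:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _level_intervals(log: StimLog, t0: float, t1: float, level: float):
    """Intervals within [t0, t1) where the amplitude is >= level."""
    segs = log.segments(t0, t1)
    raw = [(s, e) for s, e, v in segs if v >= level - 1e-9]
    return _merge_intervals([r[0] for r in raw], [r[1] for r in raw])


def _overlap(intervals_a, intervals_b) -> float:
    total = 0.0
    for a0, a1 in intervals_a:
        for b0, b1 in intervals_b:
            total += max(0.0, min(a1, b1) - max(a0, b0))
    return total


def detection_metrics(
    trace_or_stimlog,
    schedule: PromptSchedule,
    stim_params: StimParameters,
    effective_fraction: float = 1.0,
    interval: tuple[float, float] | None = None,
) -> DetectionReport:
    """Sensitivity, false-positive rate and onset latencies vs the schedule.

    "Effective" stimulation means amplitude >= effective_fraction * V_max
    (default: the full maximum level).  Imagined-movement prompts carry no
    overt movement and are counted as rest here.  Latency per movement event
    is the first time stimulation reaches the effective level after onset
    (searched until the next onset); events already effective at onset score
    zero, events never reaching the level are flagged.
    """
    if not (0 < effective_fraction <= 1):
        raise ValueError("effective_fraction must be in (0, 1]")
    if not schedule.movement_intervals:
        raise ValueError("schedule contains no movement intervals to evaluate against")
    log = (
        trace_or_stimlog
        if isinstance(trace_or_stimlog, StimLog)
        else trace_or_stimlog.applied_stim_log()
    )
    t0, t1 = interval if interval is not None else (0.0, schedule.total_duration_s)
    eff_level = effective_fraction * stim_params.max_amplitude_v
    any_level = stim_params.min_amplitude_v + 1e-6  # any stimulation above the floor
    eff = _level_intervals(log, t0, t1, eff_level)
    on = _level_intervals(log, t0, t1, any_level)

    move = [
        (max(t0, iv.start_s), min(t1, iv.end_s))
        for iv in schedule.movement_intervals
        if iv.end_s > t0 and iv.start_s < t1
    ]
    rest = [(max(t0, a), min(t1, b)) for a, b in schedule.rest_intervals() if b > t0 and a < t1]
    rest += [  # imagined prompts count as rest for stimulation purposes
        (max(t0, iv.start_s), min(t1, iv.end_s))
        for iv in schedule.intervals_with_label("imagined")
        if iv.end_s > t0 and iv.start_s < t1
    ]
    move_dur = sum(b - a for a, b in move)
    rest_dur = sum(b - a for a, b in rest)

    sensitivity = 100.0 * _overlap(eff, move) / move_dur if move_dur else 0.0
    fpr = 100.0 * _overlap(eff, rest) / rest_dur if rest_dur else 0.0
    on_move = 100.0 * _overlap(on, move) / move_dur if move_dur else 0.0
    on_rest = 100.0 * _overlap(on, rest) / rest_dur if rest_dur else 0.0

    onsets = [iv.start_s for iv in schedule.movement_intervals if t0 <= iv.start_s < t1]
    latencies, reached = [], []
    for i, onset in enumerate(onsets):
        horizon = onsets[i + 1] if i + 1 < len(onsets) else t1
        hit = None
        for a, b in eff:
            if b <= onset:
                continue
            start = max(a, onset)
            if start < horizon:
                hit = start
                break
        if hit is None:
            latencies.append(np.nan)
            reached.append(False)
        else:
            latencies.append(hit - onset)
            reached.append(True)
    return DetectionReport(
        sensitivity_pct=sensitivity,
        false_positive_pct=fpr,
        stim_time_movement_pct=on_move,
        stim_time_rest_pct=on_rest,
        latencies_s=np.array(latencies),
        reached_effective=np.array(reached, dtype=bool),
    )
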