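"""Closed-loop stimulation control: ramp-limited state machine, telemetry
timing, and the full plant-in-the-loop runner.

The automaton has four states — OFF, RAMP_UP, ON, RAMP_DOWN.  A single
movement call triggers ramp-up; ramp-down requires K consecutive rest calls
(rest-side hysteresis, implementing the clinical preference for delivering
stimulation over withholding it).  A movement call during RAMP_DOWN
re-enters RAMP_UP.  The active classifier follows the machine state: the
stimulation-off classifier serves OFF/RAMP_DOWN, the stimulation-on
classifier serves ON/RAMP_UP.

Timing model: in distributed mode decisions are quantized to the 400 ms
telemetry packet grid and commands suffer a 400 ms transport delay, so the
biomarker-to-response latency is bounded by 800 ms.  In embedded mode
decisions run at the 5 Hz on-board band-power rate with no transport delay.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Union

import numpy as np
import pandas as pd

from ._rng import substream_seed
from .classifiers import (
    EmbeddedBandClassifier,
    EnvelopeConfig,
    SpectralMovementClassifier,
    detect_movement_peripheral,
)
from .patient import PatientConfig, SessionRecording, TremorPlant
from .schedule import PromptSchedule
from .spectral import CausalBandPower, WindowConfig, welch_psd
from .stim import StimLog, StimParameters


class MachineState(str, Enum):
    OFF = "OFF"
    RAMP_UP = "RAMP_UP"
    ON = "ON"
    RAMP_DOWN = "RAMP_DOWN"


#: classifier regime used in each machine state
STATE_TAG = {
    MachineState.OFF: "off",
    MachineState.RAMP_DOWN: "off",
    MachineState.RAMP_UP: "on",
    MachineState.ON: "on",
}


@dataclass(frozen=True)
class ControllerConfig:
    mode: str = "distributed"  # distributed | embedded | peripheral
    tick_s: float = 0.4
    ramp_rate_v_per_s: float = 2.0
    off_consecutive: int = 3  # K rest calls required before ramping down
    transport_delay_s: float = 0.4
    buffer_s: float = 2.0  # trailing LFP buffer for distributed spectra
    smoothing_s: float = 0.5  # embedded band-power smoother

    def __post_init__(self) -> None:
        if self.mode not in ("distributed", "embedded", "peripheral"):
            raise ValueError(f"unknown controller mode {self.mode!r}")
        if self.tick_s <= 0:
            raise ValueError("tick_s must be positive")
        if self.ramp_rate_v_per_s <= 0:
            raise ValueError("ramp_rate_v_per_s must be positive")
        if self.off_consecutive < 1:
            raise ValueError("off_consecutive must be >= 1")
        if self.transport_delay_s < 0:
            raise ValueError("transport_delay_s must be >= 0")

    @classmethod
    def for_mode(cls, mode: str, **overrides) -> "ControllerConfig":
        """Mode defaults: distributed 0.4 s tick + 0.4 s transport;
        embedded 0.2 s tick (the 5 Hz band-power rate), no transport;
        peripheral runs on the distributed timing."""
        base = {
            "distributed": dict(mode=mode, tick_s=0.4, transport_delay_s=0.4),
            "embedded": dict(mode=mode, tick_s=0.2, transport_delay_s=0.0),
            "peripheral": dict(mode=mode, tick_s=0.4, transport_delay_s=0.4),
        }[mode]
        base.update(overrides)
        return cls(**base)


@dataclass(frozen=True)
class ControllerState:
    """Automaton state plus the rest-call hysteresis counter."""

    machine: MachineState = MachineState.OFF
    rest_count: int = 0


def apply_ramp(current_v: float, target_v: float, ramp_rate: float, dt: float) -> float:
    """Move toward the target by at most ramp_rate * dt, clamping at it."""
    if ramp_rate < 0:
        raise ValueError("ramp_rate must be >= 0")
    if dt <= 0:
        raise ValueError("dt must be positive")
    # snap within 1e-9 so a traverse of exactly N steps lands on the target
    # despite float accumulation
    step = ramp_rate * dt
    if target_v > current_v:
        nxt = current_v + step
        return target_v if nxt >= target_v - 1e-9 else nxt
    nxt = current_v - step
    return target_v if nxt <= target_v + 1e-9 else nxt


def controller_step(
    state: ControllerState,
    movement: bool,
    config: ControllerConfig,
    stim_params: StimParameters,
    current_v: float,
) -> tuple[ControllerState, float]:
    """One tick of the stimulation automaton.

    Returns the next state and the amplitude target the ramp should move
    toward.  ``current_v`` is the amplitude before this tick's ramp step and
    is used for the RAMP_UP→ON / RAMP_DOWN→OFF completion checks.
    """
    v_max, v_min = stim_params.max_amplitude_v, stim_params.min_amplitude_v
    K = config.off_consecutive
    eps = 1e-9
    m = state.machine
    if not isinstance(m, MachineState):
        raise ValueError(f"unknown controller state {m!r}")
    if m == MachineState.OFF:
        if movement:
            return ControllerState(MachineState.RAMP_UP, 0), v_max
        return ControllerState(MachineState.OFF, 0), v_min
    if m in (MachineState.RAMP_UP, MachineState.ON):
        rest = 0 if movement else state.rest_count + 1
        if rest >= K:
            return ControllerState(MachineState.RAMP_DOWN, 0), v_min
        if m == MachineState.RAMP_UP and current_v >= v_max - eps:
            return ControllerState(MachineState.ON, rest), v_max
        return ControllerState(m, rest), v_max
    # RAMP_DOWN
    if movement:
        return ControllerState(MachineState.RAMP_UP, 0), v_max
    if current_v <= v_min + eps:
        return ControllerState(MachineState.OFF, 0), v_min
    return ControllerState(MachineState.RAMP_DOWN, 0), v_min


def telemetry_delay(
    command_times_s, config: ControllerConfig, align: bool = True
) -> np.ndarray:
    """Map command times to applied times through the telemetry link.

    Each command is shifted by the transport delay and, when ``align`` is
    set, postponed to the next tick-grid boundary; commands landing exactly
    on a boundary apply there.  Effective latency therefore lies in
    [transport_delay_s, transport_delay_s + tick_s].
    """
    t = np.asarray(command_times_s, dtype=float) + config.transport_delay_s
    if align and config.tick_s > 0:
        t = np.ceil(t / config.tick_s - 1e-9) * config.tick_s
    return t


@dataclass
class ControllerTrace:
    """Tick-by-tick record of the closed loop."""

    times_s: np.ndarray
    scores: np.ndarray
    movement: np.ndarray
    classifier_tag: np.ndarray
    state: np.ndarray
    commanded_v: np.ndarray
    applied_v: np.ndarray
    tick_s: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "score": self.scores,
                "movement": self.movement.astype(int),
                "classifier": self.classifier_tag,
                "state": self.state,
                "commanded_v": self.commanded_v,
                "applied_v": self.applied_v,
            }
        )

    def applied_stim_log(self) -> StimLog:
        """Applied amplitude as a step function on the tick grid."""
        starts = self.times_s - self.tick_s
        return StimLog.from_samples(starts, self.applied_v)


class OracleClassifier:
    """Ground-truth movement labels injected as the decision stream.

    Used for closed-form timing checks: with a perfect decoder the
    onset-to-maximum latency is exactly the telemetry latency plus the ramp
    traverse time.
    """

    def __init__(self, schedule: PromptSchedule):
        self.schedule = schedule

    def __call__(self, t_s: float) -> bool:
        return bool(self.schedule.mask(np.array([t_s]), "movement")[0])


Classifiers = Union[
    Mapping[str, SpectralMovementClassifier],
    EmbeddedBandClassifier,
    EnvelopeConfig,
    OracleClassifier,
    str,
]


def _expected_grid(fs: float, buffer_s: float, window_cfg: WindowConfig) -> np.ndarray:
    n = int(round(buffer_s * fs))
    probe = welch_psd(np.zeros(n), fs, window_cfg)
    return probe.freqs_hz


def run_closed_loop(
    patient_cfg: PatientConfig,
    schedule: PromptSchedule,
    controller_cfg: ControllerConfig,
    classifiers: Classifiers,
    stim_params: StimParameters | None = None,
    seed: int = 0,
    window_cfg: WindowConfig | None = None,
) -> tuple[SessionRecording, ControllerTrace]:
    """Run the plant, feature chain, classifier and controller in a loop.

    Per tick: the plant emits samples at the currently applied amplitude,
    features are computed on the trailing data, the state-appropriate
    classifier is called, and controller_step + apply_ramp + the telemetry
    delay produce the amplitude applied in a later tick.  Deterministic for
    a fixed seed.
    """
    if stim_params is None:
        stim_params = StimParameters()
    cfg = controller_cfg
    window_cfg = window_cfg or WindowConfig()
    mode = cfg.mode

    if mode == "distributed":
        if not (isinstance(classifiers, Mapping) and {"off", "on"} <= set(classifiers)):
            if not isinstance(classifiers, (OracleClassifier,)):
                raise ValueError(
                    "distributed mode needs {'off': clf, 'on': clf} spectral classifiers"
                )
    elif mode == "embedded":
        if not isinstance(classifiers, (EmbeddedBandClassifier, OracleClassifier)):
            raise ValueError("embedded mode needs an EmbeddedBandClassifier")
    elif mode == "peripheral":
        if not isinstance(classifiers, (EnvelopeConfig, OracleClassifier)):
            raise ValueError("peripheral mode needs an EnvelopeConfig for the EMG trigger")

    oracle = isinstance(classifiers, OracleClassifier)
    if mode == "distributed" and not oracle:
        grid = _expected_grid(patient_cfg.lfp_fs, cfg.buffer_s, window_cfg)
        for tag in ("off", "on"):
            clf = classifiers[tag]
            if clf.freqs_hz_.shape != grid.shape or not np.allclose(
                clf.freqs_hz_, grid, atol=1e-9
            ):
                raise ValueError(
                    f"'{tag}' classifier bin grid is incompatible with fs="
                    f"{patient_cfg.lfp_fs} Hz and a {cfg.buffer_s} s buffer"
                )

    plant = TremorPlant(patient_cfg, schedule, stim_params, substream_seed(seed, "plant"))
    dur = schedule.total_duration_s
    tick = cfg.tick_s
    n_ticks = int(np.ceil(dur / tick - 1e-9))
    delay_ticks = int(round(cfg.transport_delay_s / tick))
    applied = np.full(n_ticks + delay_ticks + 1, stim_params.min_amplitude_v)

    if mode == "embedded" and not oracle:
        beta_chain = CausalBandPower(patient_cfg.lfp_fs, classifiers.beta_band, cfg.smoothing_s)
        stim_chain = CausalBandPower(patient_cfg.lfp_fs, classifiers.stim_band, cfg.smoothing_s)
        warmup_s = 3 * cfg.smoothing_s
    if mode == "peripheral" and not oracle:
        peripheral = None  # computed lazily from the (stim-independent) EMG stream

    state = ControllerState()
    v_cmd = stim_params.min_amplitude_v
    buf_samples = int(round(cfg.buffer_s * patient_cfg.lfp_fs))
    rows_time, rows_score, rows_move = [], [], []
    rows_tag, rows_state, rows_cmd, rows_applied = [], [], [], []
    prev_cursor = 0
    held_call = False
    buf_ticks = int(np.ceil(cfg.buffer_s / tick - 1e-9))

    for k in range(n_ticks):
        t1 = min((k + 1) * tick, dur)
        v_applied = float(applied[k])
        plant.advance_to(t1, v_applied)

        tag = STATE_TAG[state.machine]
        if oracle:
            movement = classifiers(min(t1, dur - 1e-9))
            score = float(movement)
        elif mode == "distributed":
            if plant._cursor_lfp >= buf_samples:
                buf = plant.lfp[plant._cursor_lfp - buf_samples : plant._cursor_lfp]
                spec = welch_psd(buf, patient_cfg.lfp_fs, window_cfg)
                score = classifiers[tag].score_spectrum(spec)
                # Each classifier is only valid on data recorded in its own
                # stimulation regime.  During ramps (and for one buffer
                # length afterwards) the trailing buffer mixes regimes, so
                # the controller holds its previous decision; the movement
                # call that triggered RAMP_UP and the rest run that triggered
                # RAMP_DOWN persist through the transition.
                span = applied[max(0, k - buf_ticks + 1) : k + 1]
                if tag == "off":
                    pure = bool(np.all(span <= stim_params.min_amplitude_v + 1e-9))
                else:
                    pure = bool(np.all(span >= stim_params.max_amplitude_v - 1e-9))
                movement = score > classifiers[tag].threshold if pure else held_call
            else:
                score, movement = float("nan"), False
            held_call = movement
        elif mode == "embedded":
            new = plant.lfp[prev_cursor : plant._cursor_lfp]
            beta_p = beta_chain.push(new)
            stim_p = stim_chain.push(new)
            if t1 >= warmup_s:
                eps = np.finfo(float).tiny
                call = classifiers.classify(
                    float(np.log10(max(beta_p, eps))),
                    float(np.log10(max(stim_p, eps))),
                    time_s=t1,
                )
                score, movement = call.score, call.movement
            else:
                score, movement = float("nan"), False
        else:  # peripheral
            if peripheral is None:
                peripheral = detect_movement_peripheral(
                    plant._emg, patient_cfg.emg_fs, classifiers
                )
            idx = min(
                int(np.floor(t1 * patient_cfg.emg_fs - 1e-9)), peripheral.movement.size - 1
            )
            movement = bool(peripheral.movement[idx])
            score = float(peripheral.envelope[idx])

        prev_cursor = plant._cursor_lfp
        state, target = controller_step(state, movement, cfg, stim_params, v_cmd)
        v_cmd = apply_ramp(v_cmd, target, cfg.ramp_rate_v_per_s, tick)
        applied[k + 1 + delay_ticks] = v_cmd

        rows_time.append(t1)
        rows_score.append(score)
        rows_move.append(movement)
        rows_tag.append(tag)
        rows_state.append(state.machine.value)
        rows_cmd.append(v_cmd)
        rows_applied.append(v_applied)

    recording = plant.build_recording()
    trace = ControllerTrace(
        times_s=np.array(rows_time),
        scores=np.array(rows_score),
        movement=np.array(rows_move, dtype=bool),
        classifier_tag=np.array(rows_tag, dtype=object),
        state=np.array(rows_state, dtype=object),
        commanded_v=np.array(rows_cmd),
        applied_v=np.array(rows_applied),
        tick_s=tick,
    )
    return recording, trace
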