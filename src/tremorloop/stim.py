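"""Stimulation parameters and amplitude logs.

These live in their own module because both the synthetic patient (which
needs the stimulation frequency to paint the artifact tone) and the
controller depend on them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class StimParameters:
    """Fixed electrical parameters of the stimulation train.

    Amplitude is the controlled variable; frequency and pulse width stay
    constant (clinically 150 Hz / 90 µs here), and impedance is the measured
    electrode-tissue impedance used in the energy computation.
    """

    frequency_hz: float = 150.0
    pulse_width_s: float = 90e-6
    impedance_ohm: float = 1200.0
    max_amplitude_v: float = 2.0
    min_amplitude_v: float = 0.0

    def __post_init__(self) -> None:
        if self.frequency_hz <= 0:
            raise ValueError("stimulation frequency must be positive")
        if self.pulse_width_s <= 0:
            raise ValueError("pulse width must be positive")
        if self.impedance_ohm <= 0:
            raise ValueError("impedance must be positive")
        if not (0 <= self.min_amplitude_v < self.max_amplitude_v):
            raise ValueError("need 0 <= min_amplitude_v < max_amplitude_v")

    @property
    def power_coefficient_w_per_v2(self) -> float:
        """TEED power per squared volt: f * p / z (watts per V**2)."""
        return self.frequency_hz * self.pulse_width_s / self.impedance_ohm


class StimLog:
    """Right-continuous step function of applied stimulation amplitude.

    ``times_s`` are strictly increasing segment start times; ``amps_v[i]``
    holds from ``times_s[i]`` until the next start time (or forever for the
    last segment).
    """

    def __init__(self, times_s, amps_v):
        t = np.asarray(times_s, dtype=float)
        v = np.asarray(amps_v, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times_s and amps_v must be equal-length 1-D arrays")
        if t.size == 0:
            raise ValueError("stimulation log must contain at least one segment")
        if np.any(np.diff(t) <= 0):
            raise ValueError("stimulation log times must be strictly increasing")
        if np.any(v < 0):
            raise ValueError("stimulation amplitudes must be non-negative")
        self.times_s = t
        self.amps_v = v

    @classmethod
    def constant(cls, amplitude_v: float, start_s: float = 0.0) -> "StimLog":
        return cls([start_s], [amplitude_v])

    @classmethod
    def from_samples(cls, times_s, amps_v) -> "StimLog":
        """Compress a sampled amplitude sequence into change-point form."""
        t = np.asarray(times_s, dtype=float)
        v = np.asarray(amps_v, dtype=float)
        if t.size == 0:
            raise ValueError("empty amplitude sequence")
        keep = np.concatenate(([True], np.diff(v) != 0))
        return cls(t[keep], v[keep])

    def amplitude_at(self, times_s) -> np.ndarray:
        """Amplitude at each query time (0 before the first segment)."""
        t = np.atleast_1d(np.asarray(times_s, dtype=float))
        idx = np.searchsorted(self.times_s, t, side="right") - 1
        out = np.where(idx >= 0, self.amps_v[np.clip(idx, 0, None)], 0.0)
        return out

    def segments(self, t0: float, t1: float) -> list[tuple[float, float, float]]:
        """Constant-amplitude pieces (start, end, amplitude) covering [t0, t1)."""
        if t1 <= t0:
            raise ValueError("empty interval")
        if t0 < self.times_s[0] - 1e-12:
            raise ValueError(
                f"stimulation log starts at {self.times_s[0]} s and does not cover "
                f"the interval from {t0} s"
            )
        pieces = []
        edges = self.times_s[(self.times_s > t0) & (self.times_s < t1)]
        bounds = np.concatenate(([t0], edges, [t1]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            pieces.append((float(a), float(b), float(self.amplitude_at(a)[0])))
        return pieces

    def to_dict(self) -> dict:
        return {"times_s": self.times_s.tolist(), "amps_v": self.amps_v.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "StimLog":
        return cls(d["times_s"], d["amps_v"])
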