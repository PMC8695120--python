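"""Turn labelled session recordings into classifier training data.

The distributed decoder trains on Welch spectra of short LFP windows taken
wholly inside rest or movement prompts (with a margin that skips the
transition transients); the embedded decoder trains on 30 s blocks of LFP
per (stimulation x behaviour) state.
"""

from __future__ import annotations

import numpy as np

from .classifiers import (
    EMBEDDED_STATES,
    EmbeddedBandClassifier,
    SpectralMovementClassifier,
    train_embedded_classifier,
    train_spectral_classifier,
)
from .patient import SessionRecording
from .spectral import Spectrum, WindowConfig, welch_psd


def _labelled_windows(recording, label: str, window_s: float, step_s: float, margin_s: float):
    """Start/stop sample index pairs of LFP windows wholly inside ``label``
    intervals, shrunk by ``margin_s`` at both ends."""
    fs = recording.lfp.fs
    sched = recording.schedule
    if label == "rest":
        intervals = sched.rest_intervals()
    else:
        intervals = [(iv.start_s, iv.end_s) for iv in sched.intervals_with_label(label)]
    out = []
    for a, b in intervals:
        a, b = a + margin_s, b - margin_s
        t = a
        while t + window_s <= b + 1e-9:
            i0 = int(round(t * fs))
            out.append((i0, i0 + int(round(window_s * fs))))
            t += step_s
    return out


def extract_training_spectra(
    recording: SessionRecording,
    window_s: float = 2.0,
    step_s: float = 1.0,
    margin_s: float = 1.0,
    window_cfg: WindowConfig | None = None,
) -> tuple[list[Spectrum], list[Spectrum]]:
    """(rest_spectra, movement_spectra) from a prompted-task recording."""
    cfg = window_cfg or WindowConfig()
    fs = recording.lfp.fs
    x = recording.lfp.data[:, 0]
    out = []
    for label in ("rest", "movement"):
        windows = _labelled_windows(recording, label, window_s, step_s, margin_s)
        out.append([welch_psd(x[i0:i1], fs, cfg) for (i0, i1) in windows if i1 <= x.size])
    return out[0], out[1]


def extract_state_segment(
    recording: SessionRecording, label: str, duration_s: float = 30.0, margin_s: float = 1.0
) -> np.ndarray:
    """Concatenated LFP samples carrying ``label``, trimmed to ``duration_s``."""
    fs = recording.lfp.fs
    x = recording.lfp.data[:, 0]
    windows = _labelled_windows(recording, label, 1.0, 1.0, margin_s)
    chunks = [x[i0:i1] for i0, i1 in windows if i1 <= x.size]
    if not chunks:
        raise ValueError(f"recording contains no usable {label!r} data")
    cat = np.concatenate(chunks)
    need = int(round(duration_s * fs))
    if cat.size < need:
        raise ValueError(
            f"only {cat.size / fs:.1f} s of {label!r} data available; need {duration_s} s"
        )
    return cat[:need]


def train_distributed_pair(
    session_off: SessionRecording,
    session_on: SessionRecording,
    window_s: float = 2.0,
    step_s: float = 1.0,
    margin_s: float = 1.0,
    threshold: float = 0.5,
    window_cfg: WindowConfig | None = None,
) -> dict[str, SpectralMovementClassifier]:
    """Train the stimulation-off and stimulation-on spectral decoders."""
    out = {}
    for tag, session in (("off", session_off), ("on", session_on)):
        rest, move = extract_training_spectra(session, window_s, step_s, margin_s, window_cfg)
        out[tag] = train_spectral_classifier(rest, move, stim_tag=tag, threshold=threshold)
    return out


def train_embedded_from_sessions(
    session_off: SessionRecording,
    session_on: SessionRecording,
    duration_s: float = 30.0,
    stim_freq_hz: float = 150.0,
    **kwargs,
) -> EmbeddedBandClassifier:
    """Assemble the four 30 s state blocks and train the embedded decoder."""
    sessions = {"off": session_off, "on": session_on}
    segments = {
        (stim, behav): extract_state_segment(sessions[stim], behav, duration_s)
        for stim, behav in EMBEDDED_STATES
    }
    return train_embedded_classifier(segments, session_off.lfp.fs, stim_freq_hz, **kwargs)
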