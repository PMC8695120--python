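"""Session-directory and classifier-file readers/writers.

A session is a directory of plain CSV streams plus JSON metadata:

    lfp.csv   time_s,lfp_uv
    imu.csv   time_s,gyro_x_dps,...,mag_z_au
    emg.csv   time_s,emg_mv
    stim.csv  time_s,amplitude_v          (step-function change points)
    schedule.json
    meta.json                              (format version, fs, units, seed,
                                            config and its hash)

Classifiers serialize to versioned JSON so trained models can move between
the trainer and the loop runner.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classifiers import EmbeddedBandClassifier, SpectralMovementClassifier
from .patient import IMU_CHANNELS, PatientConfig, SessionRecording, TimeSeries
from .schedule import PromptSchedule
from .stim import StimLog

SESSION_FORMAT_VERSION = "1.0"
CLASSIFIER_FORMAT_VERSION = "1.0"


def config_hash(config: PatientConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_stream(path: Path, ts: TimeSeries) -> None:
    df = pd.DataFrame({"time_s": ts.times_s})
    for i, ch in enumerate(ts.channels):
        df[ch] = ts.data[:, i]
    df.to_csv(path, index=False)


def _read_stream(path: Path, expected_fs: float, name: str) -> TimeSeries:
    if not path.exists():
        raise FileNotFoundError(f"missing stream file: {path.name}")
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        raise ValueError(
            f"non-monotone time in {path.name} at row {int(bad[0]) + 1} "
            f"(time {t[bad[0] + 1]!r} after {t[bad[0]]!r})"
        )
    if t.size > 1:
        fs_obs = 1.0 / np.median(dt)
        if abs(fs_obs - expected_fs) > 0.01 * expected_fs:
            raise ValueError(
                f"{path.name}: observed sampling rate {fs_obs:.3f} Hz does not match "
                f"manifest fs {expected_fs} Hz"
            )
    channels = tuple(c for c in df.columns if c != "time_s")
    return TimeSeries(df[list(channels)].to_numpy(), expected_fs, channels, units=name)


def write_session(recording: SessionRecording, path) -> dict:
    """Write a session directory; returns the manifest dict."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    _write_stream(path / "lfp.csv", recording.lfp)
    _write_stream(path / "imu.csv", recording.imu)
    _write_stream(path / "emg.csv", recording.emg)
    stim_df = pd.DataFrame(
        {"time_s": recording.stim_log.times_s, "amplitude_v": recording.stim_log.amps_v}
    )
    stim_df.to_csv(path / "stim.csv", index=False)
    (path / "schedule.json").write_text(json.dumps(recording.schedule.to_dict(), indent=1))
    manifest = {
        "format_version": SESSION_FORMAT_VERSION,
        "seed": recording.seed,
        "config": recording.config.to_dict(),
        "config_hash": config_hash(recording.config),
        "streams": {
            "lfp": {"file": "lfp.csv", "fs": recording.lfp.fs, "units": "uV",
                    "channels": list(recording.lfp.channels)},
            "imu": {"file": "imu.csv", "fs": recording.imu.fs, "units": "mixed",
                    "channels": list(recording.imu.channels)},
            "emg": {"file": "emg.csv", "fs": recording.emg.fs, "units": "mV",
                    "channels": list(recording.emg.channels)},
        },
    }
    (path / "meta.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def read_session(path) -> SessionRecording:
    """Read a session directory back into a :class:`SessionRecording`."""
    path = Path(path)
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing manifest: {meta_path}")
    meta = json.loads(meta_path.read_text())
    if meta.get("format_version") != SESSION_FORMAT_VERSION:
        raise ValueError(
            f"unsupported session format_version {meta.get('format_version')!r}; "
            f"this reader supports {SESSION_FORMAT_VERSION}"
        )
    config = PatientConfig.from_dict(meta["config"])
    schedule = PromptSchedule.from_dict(json.loads((path / "schedule.json").read_text()))
    lfp = _read_stream(path / "lfp.csv", meta["streams"]["lfp"]["fs"], "uV")
    imu = _read_stream(path / "imu.csv", meta["streams"]["imu"]["fs"], "mixed")
    emg = _read_stream(path / "emg.csv", meta["streams"]["emg"]["fs"], "mV")
    stim_df = pd.read_csv(path / "stim.csv")
    stim_log = StimLog(stim_df["time_s"].to_numpy(), stim_df["amplitude_v"].to_numpy())
    return SessionRecording(
        lfp=lfp, imu=imu, emg=emg, stim_log=stim_log, schedule=schedule,
        seed=int(meta["seed"]), config=config,
    )


def save_classifier(model, path) -> None:
    """Serialize a trained classifier to versioned JSON."""
    path = Path(path)
    if isinstance(model, SpectralMovementClassifier):
        doc = {
            "format_version": CLASSIFIER_FORMAT_VERSION,
            "kind": "spectral",
            "stim_tag": model.stim_tag,
            "threshold": model.threshold,
            "freqs_hz": model.freqs_hz_.tolist(),
            "mean": model.mean_.tolist(),
            "sd": model.sd_.tolist(),
            "weights": model.coef_.tolist(),
            "bias": model.intercept_,
        }
    elif isinstance(model, EmbeddedBandClassifier):
        doc = {
            "format_version": CLASSIFIER_FORMAT_VERSION,
            "kind": "embedded",
            "beta_band": list(model.beta_band),
            "stim_freq_hz": model.stim_freq_hz,
            "stim_band_halfwidth_hz": model.stim_band_halfwidth_hz,
            "sensitivity_bias": model.sensitivity_bias,
            "smoothing_s": model.smoothing_s,
            "stim_state_threshold": model.stim_state_threshold_,
            "beta_threshold_off": model.beta_threshold_off_,
            "beta_threshold_on": model.beta_threshold_on_,
            "separation_warning": model.separation_warning_,
            "fs": model.fs_,
        }
    else:
        raise TypeError(f"cannot serialize classifier of type {type(model).__name__}")
    path.write_text(json.dumps(doc, indent=1))


def load_classifier(path):
    """Load a classifier saved by :func:`save_classifier`."""
    doc = json.loads(Path(path).read_text())
    version = doc.get("format_version")
    if version != CLASSIFIER_FORMAT_VERSION:
        raise ValueError(
            f"unsupported classifier format_version {version!r}; "
            f"this loader supports {CLASSIFIER_FORMAT_VERSION}"
        )
    kind = doc.get("kind")
    if kind == "spectral":
        required = ["stim_tag", "threshold", "freqs_hz", "mean", "sd", "weights", "bias"]
        missing = [k for k in required if k not in doc]
        if missing:
            raise ValueError(f"classifier file is missing fields: {missing}")
        clf = SpectralMovementClassifier(stim_tag=doc["stim_tag"], threshold=doc["threshold"])
        clf.freqs_hz_ = np.asarray(doc["freqs_hz"], dtype=float)
        clf.mean_ = np.asarray(doc["mean"], dtype=float)
        clf.sd_ = np.asarray(doc["sd"], dtype=float)
        clf.coef_ = np.asarray(doc["weights"], dtype=float)
        clf.intercept_ = float(doc["bias"])
        clf.classes_ = np.array([0, 1])
        clf.n_features_in_ = clf.freqs_hz_.size
        return clf
    if kind == "embedded":
        required = [
            "beta_band", "stim_freq_hz", "stim_band_halfwidth_hz", "sensitivity_bias",
            "smoothing_s", "stim_state_threshold", "beta_threshold_off",
            "beta_threshold_on", "fs",
        ]
        missing = [k for k in required if k not in doc]
        if missing:
            raise ValueError(f"classifier file is missing fields: {missing}")
        clf = EmbeddedBandClassifier(
            beta_band=tuple(doc["beta_band"]),
            stim_freq_hz=doc["stim_freq_hz"],
            stim_band_halfwidth_hz=doc["stim_band_halfwidth_hz"],
            sensitivity_bias=doc["sensitivity_bias"],
            smoothing_s=doc["smoothing_s"],
        )
        clf.stim_state_threshold_ = float(doc["stim_state_threshold"])
        clf.beta_threshold_off_ = float(doc["beta_threshold_off"])
        clf.beta_threshold_on_ = float(doc["beta_threshold_on"])
        clf.separation_warning_ = bool(doc.get("separation_warning", False))
        clf.fs_ = float(doc["fs"])
        return clf
    raise ValueError(f"unknown classifier kind {kind!r}")
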