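"""Movement decoders: distributed spectral classifiers, the fully implanted
band-power classifier, and peripheral EMG/IMU envelope triggers.

The distributed decoder is a linear discriminant in z-scored spectral space:
each frequency bin gets a weight equal to the class-mean difference of its
z-scored power between movement and rest (identity-covariance LDA), and the
weighted sum passes through a logistic whose bias maps the midpoint between
the class means to 0.5.  Because beta power *drops* during movement (ERD),
the beta-bin weights come out negative and a desynchronized spectrum scores
above 0.5.  Lowering the threshold below 0.5 trades false positives for
sensitivity, the clinically preferred direction.  Two such
decoders are trained in parallel — one on stimulation-off data, one on
stimulation-on data — because the stimulation artifact reshapes the
spectrum.

The embedded decoder mirrors what a constrained implanted device can do:
two log band powers at the 5 Hz telemetry rate (one band near the
stimulation frequency, one beta band), a threshold on the stimulation band
to infer the stimulation state, and per-state beta thresholds — raised by a
sensitivity bias so that movement (low beta) is called more readily.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from .spectral import (
    NormStats,
    Spectrum,
    _check_grid,
    streaming_band_power,
)

MIN_SPECTRA_PER_CLASS = 5
EMBEDDED_SEGMENT_MIN_S = 30.0
EMBEDDED_STATES = (("off", "rest"), ("off", "movement"), ("on", "rest"), ("on", "movement"))


@dataclass(frozen=True)
class MovementCall:
    """One decision tick: movement verdict plus the evidence behind it."""

    time_s: float
    movement: bool
    score: float
    inferred_stim_state: str | None = None


class SpectralMovementClassifier(ClassifierMixin, BaseEstimator):
    """Per-bin weighted spectral movement decoder with a logistic readout.

    Parameters
    ----------
    stim_tag : {"off", "on"}
        Which stimulation state the training data was collected under.
    threshold : float in (0, 1)
        Logistic score above which a tick is called movement; 0.5 is the
        balanced decision point, lower values favor sensitivity.

    Fitted attributes
    -----------------
    freqs_hz_, mean_, sd_ : the training bin grid and normalization stats
    coef_ : per-bin weights (mean z movement - mean z rest)
    intercept_ : logistic bias
    """

    def __init__(self, stim_tag: str = "off", threshold: float = 0.5):
        self.stim_tag = stim_tag
        self.threshold = threshold

    def _validate_params(self) -> None:
        if self.stim_tag not in ("off", "on"):
            raise ValueError("stim_tag must be 'off' or 'on'")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must be in (0, 1)")

    def fit(self, X, y, freqs_hz=None) -> "SpectralMovementClassifier":
        """Fit from raw (un-normalized) power spectra.

        X is (n_spectra, n_bins); y is 0 for rest, 1 for movement.
        """
        self._validate_params()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_spectra, n_bins) aligned with y")
        classes = np.unique(y)
        if not np.array_equal(classes, [0, 1]):
            raise ValueError("y must contain both classes 0 (rest) and 1 (movement)")
        for c in (0, 1):
            if (y == c).sum() < MIN_SPECTRA_PER_CLASS:
                raise ValueError(
                    f"class {c} has {(y == c).sum()} spectra; need at least "
                    f"{MIN_SPECTRA_PER_CLASS}"
                )
        freqs = (
            np.arange(X.shape[1], dtype=float)
            if freqs_hz is None else np.asarray(freqs_hz, dtype=float)
        )
        if freqs.shape[0] != X.shape[1]:
            raise ValueError("freqs_hz length must match the number of bins")
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            raise ValueError(
                "degenerate training data: zero variance at bin(s) "
                + ", ".join(f"{freqs[i]:g} Hz" for i in zero[:5])
            )
        # Movement-minus-rest class-mean difference in z-space: beta ERD makes
        # the beta-bin weights negative, so a desynchronized spectrum scores
        # above the 0.5 rest level.
        Z = (X - mean) / sd
        w = Z[y == 1].mean(axis=0) - Z[y == 0].mean(axis=0)
        midpoint = (Z[y == 1].mean(axis=0) + Z[y == 0].mean(axis=0)) / 2
        self.classes_ = np.array([0, 1])
        self.freqs_hz_ = freqs
        self.mean_ = mean
        self.sd_ = sd
        self.coef_ = w
        # bias anchors the 0.5 score level at the midpoint between the class
        # means, so the default threshold 0.5 is the balanced decision point
        self.intercept_ = -float(midpoint @ w)
        self.n_features_in_ = X.shape[1]
        return self

    @property
    def norm_stats_(self) -> NormStats:
        return NormStats(self.freqs_hz_, self.mean_, self.sd_)

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError("frequency bin grids do not match")
        Z = (X - self.mean_) / self.sd_
        return Z @ self.coef_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        p = expit(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (expit(self.decision_function(X)) > self.threshold).astype(int)

    def score_spectrum(self, spectrum: Spectrum) -> float:
        """Logistic movement score for one un-normalized spectrum."""
        if spectrum.normalized:
            raise ValueError("classifier expects un-normalized spectra")
        _check_grid(spectrum.freqs_hz, self.freqs_hz_)
        return float(expit(self.decision_function(spectrum.power[None, :]))[0])


def train_spectral_classifier(
    rest_spectra: list[Spectrum],
    move_spectra: list[Spectrum],
    stim_tag: str = "off",
    threshold: float = 0.5,
) -> SpectralMovementClassifier:
    """Train the distributed decoder from labelled Welch spectra."""
    if len(rest_spectra) < MIN_SPECTRA_PER_CLASS or len(move_spectra) < MIN_SPECTRA_PER_CLASS:
        raise ValueError(
            f"need at least {MIN_SPECTRA_PER_CLASS} spectra per class; got "
            f"{len(rest_spectra)} rest and {len(move_spectra)} movement"
        )
    grid = rest_spectra[0].freqs_hz
    for s in list(rest_spectra) + list(move_spectra):
        _check_grid(s.freqs_hz, grid)
    X = np.stack([s.power for s in rest_spectra] + [s.power for s in move_spectra])
    y = np.concatenate([np.zeros(len(rest_spectra), int), np.ones(len(move_spectra), int)])
    clf = SpectralMovementClassifier(stim_tag=stim_tag, threshold=threshold)
    return clf.fit(X, y, freqs_hz=grid)


def classify_spectrum(
    classifier: SpectralMovementClassifier, spectrum: Spectrum, time_s: float = 0.0
) -> MovementCall:
    """Score one spectrum and apply the decision threshold."""
    score = classifier.score_spectrum(spectrum)
    return MovementCall(time_s=time_s, movement=score > classifier.threshold, score=score)


class EmbeddedBandClassifier(BaseEstimator):
    """Cascaded two-band threshold decoder for the fully implanted device.

    First the log power in the stimulation band decides the stimulation
    state; then the log beta power is compared against that state's beta
    threshold — desynchronization means low beta implies movement.  Both
    beta thresholds are raised by ``sensitivity_bias`` (log10 units) so the
    decoder favors calling movement (and hence stimulation).
    """

    def __init__(
        self,
        beta_band: tuple[float, float] = (12.0, 28.0),
        stim_freq_hz: float = 150.0,
        stim_band_halfwidth_hz: float = 5.0,
        sensitivity_bias: float = 0.25,
        smoothing_s: float = 0.5,
    ):
        self.beta_band = beta_band
        self.stim_freq_hz = stim_freq_hz
        self.stim_band_halfwidth_hz = stim_band_halfwidth_hz
        self.sensitivity_bias = sensitivity_bias
        self.smoothing_s = smoothing_s

    @property
    def stim_band(self) -> tuple[float, float]:
        return (
            self.stim_freq_hz - self.stim_band_halfwidth_hz,
            self.stim_freq_hz + self.stim_band_halfwidth_hz,
        )

    def _validate_params(self) -> None:
        if self.sensitivity_bias < 0:
            raise ValueError("sensitivity_bias must be >= 0")
        lo, hi = self.beta_band
        slo, shi = self.stim_band
        if max(lo, slo) < min(hi, shi):
            raise ValueError("stim band must be disjoint from the beta band")

    def fit(self, segments: dict, fs: float) -> "EmbeddedBandClassifier":
        """Fit thresholds from the four 30 s state blocks.

        ``segments`` maps (stim_state, behaviour) keys — ("off"/"on",
        "rest"/"movement") — to raw LFP sample arrays of at least 30 s each.
        """
        self._validate_params()
        missing = [k for k in EMBEDDED_STATES if k not in segments]
        if missing or len(segments) != 4:
            raise ValueError(
                f"need exactly the four state segments {list(EMBEDDED_STATES)}; "
                f"missing {missing}, got {sorted(segments)}"
            )
        feats: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        warmup = int(np.ceil(3 * self.smoothing_s * 5))
        for key, x in segments.items():
            x = np.asarray(x, dtype=float)
            if x.size < EMBEDDED_SEGMENT_MIN_S * fs:
                raise ValueError(
                    f"state {key} segment is {x.size / fs:.1f} s; need >= "
                    f"{EMBEDDED_SEGMENT_MIN_S:.0f} s"
                )
            beta = streaming_band_power(x, fs, self.beta_band, self.smoothing_s)
            stim = streaming_band_power(x, fs, self.stim_band, self.smoothing_s)
            eps = np.finfo(float).tiny
            feats[key] = (
                np.log10(np.maximum(beta.values[warmup:], eps)),
                np.log10(np.maximum(stim.values[warmup:], eps)),
            )

        def mean_stim(state):  # pooled over rest+movement within a stim state
            return np.concatenate([feats[(state, b)][1] for b in ("rest", "movement")])

        off_stim, on_stim = mean_stim("off"), mean_stim("on")
        self.stim_state_threshold_ = float((off_stim.mean() + on_stim.mean()) / 2)
        pooled_sd = float(np.concatenate([off_stim, on_stim]).std())
        self.separation_warning_ = bool(
            abs(on_stim.mean() - off_stim.mean()) <= pooled_sd
        )
        if self.separation_warning_:
            warnings.warn(
                "stimulation-band class means are separated by less than one "
                "standard deviation; stimulation-state inference may be unreliable",
                UserWarning,
                stacklevel=2,
            )
        thresholds = {}
        for state in ("off", "on"):
            rest = feats[(state, "rest")][0].mean()
            move = feats[(state, "movement")][0].mean()
            thresholds[state] = float((rest + move) / 2 + self.sensitivity_bias)
        self.beta_threshold_off_ = thresholds["off"]
        self.beta_threshold_on_ = thresholds["on"]
        self.fs_ = fs
        return self

    def classify(
        self, beta_logpower: float, stim_logpower: float, time_s: float = 0.0
    ) -> MovementCall:
        if not (np.isfinite(beta_logpower) and np.isfinite(stim_logpower)):
            raise ValueError("band-power features must be finite")
        state = "on" if stim_logpower > self.stim_state_threshold_ else "off"
        thr = self.beta_threshold_on_ if state == "on" else self.beta_threshold_off_
        margin = thr - beta_logpower  # positive margin = movement evidence
        return MovementCall(
            time_s=time_s,
            movement=beta_logpower < thr,
            score=float(margin),
            inferred_stim_state=state,
        )


def train_embedded_classifier(
    segments: dict, fs: float, stim_freq_hz: float = 150.0, **kwargs
) -> EmbeddedBandClassifier:
    """Train the implanted-device decoder from the four state blocks."""
    clf = EmbeddedBandClassifier(stim_freq_hz=stim_freq_hz, **kwargs)
    return clf.fit(segments, fs)


def classify_band_powers(
    classifier: EmbeddedBandClassifier,
    beta_logpower: float,
    stim_logpower: float,
    time_s: float = 0.0,
) -> MovementCall:
    """Apply the cascaded stimulation-state / beta-threshold decision."""
    return classifier.classify(beta_logpower, stim_logpower, time_s)


@dataclass(frozen=True)
class EnvelopeConfig:
    """Rectified moving-average envelope detector with hold-time hysteresis."""

    window_s: float = 0.25
    threshold: float = 0.1
    hold_s: float = 1.0

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.hold_s < 0 or self.threshold < 0:
            raise ValueError("envelope parameters must be non-negative (window > 0)")


@dataclass
class PeripheralDetection:
    """Boolean movement stream at the envelope sample rate."""

    times_s: np.ndarray
    movement: np.ndarray
    envelope: np.ndarray
    fs: float


def detect_movement_peripheral(
    signal, fs: float, envelope_cfg: EnvelopeConfig
) -> PeripheralDetection:
    """Threshold a rectified moving-average envelope of EMG or gyro magnitude.

    The detector latches: once the envelope exceeds the threshold the stream
    reads movement, and it only releases after the envelope has stayed at or
    below threshold for ``hold_s`` continuously.
    """
    x = np.abs(np.asarray(signal, dtype=float))
    win = int(round(envelope_cfg.window_s * fs))
    if win < 3:
        raise ValueError(f"envelope window of {win} samples is too short; need >= 3")
    env = sps.lfilter(np.ones(win) / win, [1.0], x)
    hold = int(round(envelope_cfg.hold_s * fs))
    above = env > envelope_cfg.threshold
    moving = np.zeros(x.size, dtype=bool)
    state = False
    below_run = 0
    for i in range(x.size):
        if above[i]:
            state = True
            below_run = 0
        elif state:
            below_run += 1
            if below_run >= hold:
                state = False
        moving[i] = state
    return PeripheralDetection(np.arange(x.size) / fs, moving, env, fs)
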