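"""Movement decoders: spectral LDA training/inference, the embedded
band-threshold cascade, and the peripheral envelope trigger."""

import numpy as np
import pytest
from scipy.special import expit

import tremorloop as tl
from tremorloop.classifiers import EMBEDDED_STATES
from tremorloop.training import extract_state_segment


def _toy_classifier(weights, bias, threshold=0.5):
    clf = tl.SpectralMovementClassifier(threshold=threshold)
    n = len(weights)
    clf.freqs_hz_ = np.arange(n, dtype=float)
    clf.mean_ = np.zeros(n)
    clf.sd_ = np.ones(n)
    clf.coef_ = np.asarray(weights, dtype=float)
    clf.intercept_ = bias
    clf.classes_ = np.array([0, 1])
    clf.n_features_in_ = n
    return clf


class TestSpectralClassifier:
    def test_identical_classes_give_zero_weights_and_half_scores(self):
        rng = np.random.default_rng(0)
        X_class = rng.uniform(1, 2, size=(10, 20))
        X = np.vstack([X_class, X_class])
        y = np.array([0] * 10 + [1] * 10)
        clf = tl.SpectralMovementClassifier().fit(X, y)
        assert np.allclose(clf.coef_, 0.0)
        assert np.allclose(expit(clf.decision_function(X_class)), 0.5)

    def test_hand_evaluated_logistic(self):
        # w=(1,-1,0), z=(2,1,5), b=0 -> logistic(1) = 0.7311
        clf = _toy_classifier([1.0, -1.0, 0.0], 0.0)
        spec = tl.Spectrum(np.arange(3, dtype=float), np.array([2.0, 1.0, 5.0]), 422.0)
        call = tl.classify_spectrum(clf, spec)
        assert call.score == pytest.approx(0.7311, abs=1e-4)
        assert call.movement

    def test_threshold_semantics(self):
        clf = _toy_classifier([1.0, -1.0, 0.0], 0.0, threshold=0.6)
        spec = tl.Spectrum(np.arange(3, dtype=float), np.array([3.0, 1.0, 0.0]), 422.0)
        call = tl.classify_spectrum(clf, spec)  # logit 2 -> score 0.88
        assert call.score > 0.6 and call.movement

    def test_score_is_monotone_in_the_weighted_sum(self):
        clf = _toy_classifier([1.0], 0.0)
        grid = np.linspace(-5, 5, 21)
        scores = expit(clf.decision_function(grid[:, None]))
        assert np.all(np.diff(scores) > 0)

    def test_too_few_spectra_per_class_rejected(self):
        X = np.random.default_rng(1).uniform(1, 2, (6, 5))
        y = np.array([0, 0, 0, 0, 1, 1])
        with pytest.raises(ValueError, match="at least 5"):
            tl.SpectralMovementClassifier().fit(X, y)

    def test_grid_mismatch_rejected_at_inference(self, classifier_pair):
        clf = classifier_pair["off"]
        bad = tl.Spectrum(np.arange(10, dtype=float), np.ones(10), 422.0)
        with pytest.raises(ValueError, match="grid"):
            clf.score_spectrum(bad)

    def test_erd_localized_training_puts_top_weights_in_beta_band(
        self, classifier_pair, patient_cfg
    ):
        lo, hi = patient_cfg.beta_band
        for clf in classifier_pair.values():
            top5 = clf.freqs_hz_[np.argsort(-np.abs(clf.coef_))[:5]]
            in_beta = (top5 >= lo) & (top5 <= hi)
            assert in_beta.all(), f"top-weight bins {sorted(top5)} stray outside beta"

    def test_sklearn_get_set_params_round_trip(self):
        clf = tl.SpectralMovementClassifier(stim_tag="on", threshold=0.4)
        params = clf.get_params()
        clone = tl.SpectralMovementClassifier().set_params(**params)
        assert clone.stim_tag == "on" and clone.threshold == 0.4


class TestEmbeddedClassifier:
    def test_definitional_threshold_cases(self):
        clf = tl.EmbeddedBandClassifier()
        clf.stim_state_threshold_ = 1.0
        clf.beta_threshold_off_ = 2.0
        clf.beta_threshold_on_ = 3.0
        call = tl.classify_band_powers(clf, beta_logpower=1.5, stim_logpower=0.5)
        assert call.inferred_stim_state == "off" and call.movement
        call = tl.classify_band_powers(clf, beta_logpower=3.2, stim_logpower=1.4)
        assert call.inferred_stim_state == "on" and not call.movement

    def test_decision_flips_exactly_once_across_the_beta_threshold(self):
        clf = tl.EmbeddedBandClassifier()
        clf.stim_state_threshold_ = 0.0
        clf.beta_threshold_off_ = 1.0
        clf.beta_threshold_on_ = 1.5
        calls = [
            tl.classify_band_powers(clf, b, -1.0).movement
            for b in np.linspace(-2, 4, 601)
        ]
        flips = np.sum(np.diff(np.asarray(calls).astype(int)) != 0)
        assert flips == 1

    def test_non_finite_features_rejected(self):
        clf = tl.EmbeddedBandClassifier()
        clf.stim_state_threshold_ = 0.0
        clf.beta_threshold_off_ = clf.beta_threshold_on_ = 1.0
        with pytest.raises(ValueError, match="finite"):
            tl.classify_band_powers(clf, np.nan, 0.0)

    def test_three_states_rejected(self, train_sessions, patient_cfg):
        off, _ = train_sessions
        segments = {
            k: extract_state_segment(off, k[1]) for k in EMBEDDED_STATES[:3]
        }
        with pytest.raises(ValueError, match="four state"):
            tl.train_embedded_classifier(segments, patient_cfg.lfp_fs)

    def test_stim_state_decoded_reliably_on_training_ticks(
        self, embedded_clf, train_sessions, patient_cfg
    ):
        sessions = {"off": train_sessions[0], "on": train_sessions[1]}
        warm = int(np.ceil(3 * embedded_clf.smoothing_s * 5))
        correct = total = 0
        for stim_state, behav in EMBEDDED_STATES:
            seg = extract_state_segment(sessions[stim_state], behav)
            beta = tl.streaming_band_power(seg, patient_cfg.lfp_fs, embedded_clf.beta_band)
            stim = tl.streaming_band_power(seg, patient_cfg.lfp_fs, embedded_clf.stim_band)
            for b, s in zip(beta.values[warm:], stim.values[warm:]):
                call = embedded_clf.classify(np.log10(max(b, 1e-300)),
                                             np.log10(max(s, 1e-300)))
                correct += call.inferred_stim_state == stim_state
                total += 1
        assert correct / total >= 0.95

    def test_sensitivity_bias_never_increases_false_negatives(
        self, train_sessions, patient_cfg
    ):
        off, on = train_sessions
        held = tl.simulate_session(
            patient_cfg, tl.make_prompt_schedule(120.0, 5, (8.0, 12.0), seed=31),
            stim=None, seed=77,
        )
        fns = {}
        for bias in (0.0, 0.5):
            clf = tl.train_embedded_from_sessions(off, on, sensitivity_bias=bias)
            beta = tl.streaming_band_power(
                held.lfp.data[:, 0], patient_cfg.lfp_fs, clf.beta_band
            )
            stim = tl.streaming_band_power(
                held.lfp.data[:, 0], patient_cfg.lfp_fs, clf.stim_band
            )
            labels = held.schedule.mask(beta.times_s, "movement")
            calls = np.array([
                clf.classify(np.log10(max(b, 1e-300)), np.log10(max(s, 1e-300))).movement
                for b, s in zip(beta.values, stim.values)
            ])
            fns[bias] = int(np.sum(labels & ~calls))
        assert fns[0.5] <= fns[0.0]

    def test_overlapping_stim_and_beta_bands_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            tl.EmbeddedBandClassifier(beta_band=(12.0, 28.0), stim_freq_hz=25.0)._validate_params()


class TestPeripheralDetector:
    FS = 500.0

    def test_zero_signal_never_detects(self):
        cfg = tl.EnvelopeConfig(window_s=0.25, threshold=0.1, hold_s=1.0)
        det = tl.detect_movement_peripheral(np.zeros(5000), self.FS, cfg)
        assert not det.movement.any()

    def test_burst_onset_and_offset_timing(self):
        rng = np.random.default_rng(8)
        x = 0.02 * rng.standard_normal(int(8 * self.FS))
        burst = slice(int(2 * self.FS), int(4 * self.FS))
        x[burst] += 0.5 * rng.standard_normal(int(2 * self.FS))
        rest_env = np.abs(x[: int(1 * self.FS)]).mean()
        cfg = tl.EnvelopeConfig(window_s=0.25, threshold=5 * rest_env, hold_s=1.0)
        det = tl.detect_movement_peripheral(x, self.FS, cfg)
        onset = det.times_s[np.argmax(det.movement)]
        assert 2.0 <= onset <= 2.0 + 2 * cfg.window_s
        last = det.times_s[det.movement][-1]
        assert 4.0 - 0.1 <= last <= 4.0 + cfg.hold_s + 2 * cfg.window_s

    def test_zero_threshold_latches_on_any_activity(self):
        x = 0.1 * np.random.default_rng(9).standard_normal(2000)
        cfg = tl.EnvelopeConfig(window_s=0.25, threshold=0.0, hold_s=0.5)
        det = tl.detect_movement_peripheral(x, self.FS, cfg)
        warm = int(0.25 * self.FS)
        assert det.movement[warm:].all()

    def test_too_short_envelope_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            tl.detect_movement_peripheral(np.zeros(100), 4.0, tl.EnvelopeConfig(window_s=0.5))


def test_chance_level_on_label_shuffled_training(classifier_pair, train_sessions):
    """Shuffling labels destroys the ERD signal: held-out accuracy is chance."""
    off, _ = train_sessions
    rest, move = tl.extract_training_spectra(off)
    X = np.stack([s.power for s in rest + move])
    y = np.array([0] * len(rest) + [1] * len(move))
    accs = []
    for rep in range(20):
        rng = np.random.default_rng(1000 + rep)
        y_shuf = y[rng.permutation(y.size)]  # labels decoupled from spectra
        split = rng.permutation(y.size)
        half = y.size // 2
        train_idx, test_idx = split[:half], split[half:]
        try:
            clf = tl.SpectralMovementClassifier().fit(X[train_idx], y_shuf[train_idx])
        except ValueError:
            continue  # a degenerate shuffle without 5 spectra per class
        pred = clf.predict(X[test_idx])
        accs.append(np.mean(pred == y_shuf[test_idx]))
    assert 0.40 <= np.mean(accs) <= 0.60
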