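"""Feature extraction, supervised training and duration-aware decoding."""

import numpy as np
import pytest
from scipy.signal import hilbert

from conftest import exhaustive_segmentation_score, make_record
from pcgseg import pipeline
from pcgseg.hsmm_core import (
    N_STATES,
    FrameFeatures,
    HsmmModel,
    StateLabel,
    _sliding_kurtosis,
    decode,
    duration_support,
    extract_features,
    label_frames,
    train,
    viterbi_decode,
)
from pcgseg.signal_io import EcgAnnotations, ValidationError, Waveform


class TestFeatures:
    def test_hilbert_envelope_of_tone_is_constant(self):
        t = np.arange(4000) / 1000.0
        env = np.abs(hilbert(np.sin(2 * np.pi * 80 * t)))
        interior = env[200:-200]
        assert np.std(interior) / np.mean(interior) < 0.01

    def test_noise_envelope_kurtosis_in_rayleigh_range(self):
        # Hilbert envelope of Gaussian noise is Rayleigh; its Pearson
        # kurtosis is ~3.25. Check the sliding estimator lands in [2, 4.5].
        rng = np.random.default_rng(11)
        env = np.abs(hilbert(rng.normal(size=200_000)))
        kurt = _sliding_kurtosis(env, win=200, hop=200)
        vals = kurt[100::200][:900]
        # Rayleigh kurtosis is 3.245; a 200-sample estimator scatters around
        # it, so bound the bulk and the mean rather than every window.
        assert np.mean((vals > 2.0) & (vals < 4.5)) >= 0.95
        assert 2.8 < np.mean(vals) < 3.7

    def test_kurtosis_peaks_at_isolated_burst(self):
        fs = 1000.0
        t = np.arange(int(4 * fs)) / fs
        x = 0.001 * np.random.default_rng(12).normal(size=t.size)
        x += np.exp(-0.5 * ((t - 2.0) / 0.01) ** 2) * np.sin(2 * np.pi * 60 * t)
        w = Waveform(x, fs=fs)
        feats = extract_features(w)
        k = feats.values[:, 1]
        peak_frame = int(np.argmax(k))
        assert abs(peak_frame * feats.hop - 2000) <= 120

    def test_too_short_for_kurtosis_window_rejected(self):
        w = Waveform(np.random.default_rng(1).normal(size=2200), fs=1000.0)
        with pytest.raises(ValidationError):
            extract_features(w, kurtosis_win_ms=3000.0)


class TestLabelFrames:
    def test_window_arithmetic_at_50hz(self):
        ann = EcgAnnotations(r_peaks=[2000], t_ends=[2600], fs=1000.0)
        # single R is rejected; add a second beat far away
        ann = EcgAnnotations(r_peaks=[2000, 3000], t_ends=[2600], fs=1000.0)
        labels = label_frames(ann, n_frames=200, frame_rate=50.0)
        s1 = np.flatnonzero(labels == StateLabel.S1)
        s2 = np.flatnonzero(labels == StateLabel.S2)
        assert s1.min() == 100 and s1.max() == 105  # [100, 106)
        assert s2.min() == 128 and s2.max() == 132  # [128, 133)

    def test_single_beat_rejected(self):
        ann = EcgAnnotations(r_peaks=[2000], t_ends=[], fs=1000.0)
        with pytest.raises(ValidationError):
            label_frames(ann, n_frames=200)

    def test_labels_follow_cyclic_order(self):
        _, ecg, truth = make_record(seed=9)
        labels = label_frames(truth.annotations, n_frames=1500)
        change = np.flatnonzero(np.diff(labels)) + 1
        for idx in change:
            prev, cur = labels[idx - 1], labels[idx]
            assert cur == (prev + 1) % N_STATES


def simulate_labelled_frames(rng, n_beats, dur_mean, dur_sd):
    """Sample a label sequence from known duration Gaussians with
    state-indicator features plus noise."""
    labels = []
    for _ in range(n_beats):
        for s in StateLabel:
            d = max(1, int(round(rng.normal(dur_mean[s], dur_sd[s]))))
            labels.extend([int(s)] * d)
    labels = np.asarray(labels)
    feats = rng.normal(0, 0.3, size=(labels.size, 3))
    for s in range(3):
        feats[labels == s, s] += 2.0
    # diastole is the all-low class
    return FrameFeatures(values=feats, frame_rate=50.0, fs=1000.0), labels


class TestTrain:
    def test_duplicated_recording_gives_same_model(self):
        rng = np.random.default_rng(21)
        ex = simulate_labelled_frames(rng, 40, [6, 8, 5, 24], [0.8, 1.2, 0.7, 2.5])
        m1 = train([ex])
        m2 = train([ex, ex])
        np.testing.assert_allclose(m1.dur_mean, m2.dur_mean)
        np.testing.assert_allclose(m1.dur_sd, m2.dur_sd, rtol=0.05)
        np.testing.assert_allclose(m1.emis_weights, m2.emis_weights, atol=1e-3)

    def test_missing_state_rejected(self):
        rng = np.random.default_rng(22)
        feats, labels = simulate_labelled_frames(rng, 10, [6, 8, 5, 24], [0.8, 1.2, 0.7, 2.5])
        labels = np.where(labels == int(StateLabel.S2), int(StateLabel.SYSTOLE), labels)
        with pytest.raises(ValidationError, match="S2"):
            train([(feats, labels)])

    def test_separable_features_reproduce_labels(self):
        rng = np.random.default_rng(23)
        feats, labels = simulate_labelled_frames(rng, 60, [6, 8, 5, 24], [0.8, 1.2, 0.7, 2.5])
        model = train([(feats, labels)])
        rr = (labels.size / 60) / 50.0
        seg = decode(model, feats, rr_estimate_s=rr)
        acc = np.mean(seg.states == labels)
        assert acc >= 0.99

    def test_serialization_round_trip(self, tmp_path, clean_model):
        path = tmp_path / "model.json"
        clean_model.to_json(path)
        back = HsmmModel.from_json(path)
        np.testing.assert_allclose(back.dur_mean, clean_model.dur_mean)
        np.testing.assert_allclose(back.emis_weights, clean_model.emis_weights)
        assert back.s12_mu == clean_model.s12_mu


class TestDecode:
    def test_matches_exhaustive_search_on_toy_instance(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            T = int(rng.integers(15, 41))
            dur_mean = rng.uniform(3, 9, 4)
            dur_sd = rng.uniform(0.4, 1.2, 4)
            log_emit = rng.normal(0, 2, (T, N_STATES))
            _, score = viterbi_decode(log_emit, dur_mean, dur_sd)
            assert score == pytest.approx(
                exhaustive_segmentation_score(log_emit, dur_mean, dur_sd), abs=1e-9
            )

    def test_clean_synthetic_truth_recovered(self, clean_model, clean_record):
        pcg, _, truth = clean_record
        seg = pipeline.segment(pcg, clean_model, refine="none")
        for kind, true_iv in (("s1", truth.s1), ("s2", truth.s2)):
            for a, b in true_iv:
                hits = [
                    beat
                    for beat in seg.beats
                    for (c, d) in [getattr(beat, kind)]
                    if c < b and a < d
                ]
                assert len(hits) == 1

    def test_path_never_skips_states(self, clean_model, clean_record):
        pcg, _, _ = clean_record
        seg = pipeline.segment(pcg, clean_model, refine="none")
        change = np.flatnonzero(np.diff(seg.states)) + 1
        for idx in change:
            assert seg.states[idx] == (seg.states[idx - 1] + 1) % N_STATES

    def test_interior_run_lengths_within_support(self):
        rng = np.random.default_rng(32)
        dur_mean = np.array([6.0, 8.0, 5.0, 24.0])
        dur_sd = np.array([0.8, 1.2, 0.7, 2.5])
        log_emit = rng.normal(0, 1, (300, N_STATES))
        path, _ = viterbi_decode(log_emit, dur_mean, dur_sd)
        change = np.flatnonzero(np.diff(path)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [path.size]])
        for a, b in list(zip(starts, ends))[1:-1]:
            lo, hi = duration_support(dur_mean[path[a]], dur_sd[path[a]])
            assert lo <= b - a <= hi
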