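"""Viola-integral envelope, first-order Shannon energy and S1 onset search."""

import numpy as np
import pytest

from conftest import AS_CONDITIONS, make_record, viola_direct
from pcgseg import pipeline
from pcgseg.hsmm_core import Beat, Segmentation
from pcgseg.s1_refine import (
    EnvelopeSeries,
    ShannonSeries,
    first_order_ase,
    refine_s1,
    viola_envelope,
)
from pcgseg.signal_io import ValidationError, Waveform


class TestViolaEnvelope:
    def test_half_window_is_50_samples_at_1khz(self):
        w = Waveform(np.random.default_rng(1).normal(size=3000), fs=1000.0)
        env = viola_envelope(w)
        assert env.half_window == 50

    def test_constant_signal_degenerate(self):
        with pytest.raises(ValidationError, match="degenerate"):
            viola_envelope(Waveform(np.full(3000, 3.7), fs=1000.0))

    def test_matches_direct_double_loop(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=2000)
        w = Waveform(x, fs=1000.0)
        env = viola_envelope(w)
        direct = viola_direct(x, env.half_window)
        direct /= direct.max()
        np.testing.assert_allclose(env.values, direct, atol=1e-9)

    def test_normalized_to_unit_peak(self):
        w = Waveform(np.random.default_rng(3).normal(size=3000), fs=1000.0)
        assert viola_envelope(w).values.max() == pytest.approx(1.0)


class TestShannonEnergy:
    def test_closed_form_values(self):
        # -x ln x at x = 1/e is 1/e; at x = 0.4 it is 0.36652
        x = 1 / np.e
        assert -x * np.log(x) == pytest.approx(1 / np.e)
        assert -0.4 * np.log(0.4) == pytest.approx(0.36652, abs=5e-6)

    def test_ase_standardized(self):
        rng = np.random.default_rng(4)
        env = EnvelopeSeries(values=rng.uniform(0.01, 1.0, 4000), half_window=50, fs=1000.0)
        s = first_order_ase(env)
        assert np.mean(s.ase) == pytest.approx(0.0, abs=1e-9)
        assert np.std(s.ase) == pytest.approx(1.0, abs=1e-9)

    def test_flat_envelope_rejected(self):
        env = EnvelopeSeries(values=np.full(4000, 0.5), half_window=50, fs=1000.0)
        with pytest.raises(ValidationError, match="flat"):
            first_order_ase(env)


def one_beat_seg(s1, s2, fs=1000.0):
    return Segmentation(states=np.array([], dtype=int), beats=(Beat(s1=s1, s2=s2),), fs=fs, frame_hop=20)


class TestRefineS1:
    def test_ramp_crossing_moves_onset_to_crossing(self):
        # ASE ramps 0 -> 1 across the S1 interval; 0.7 crossed at index 170
        ase = np.zeros(1000)
        ase[100:200] = np.linspace(0.0, 1.0, 100)
        s = ShannonSeries(ase=ase, window=20, hop=10, fs=1000.0)
        seg = one_beat_seg(s1=(100, 200), s2=(400, 470))
        out = refine_s1(seg, s)
        k = 100 + int(np.flatnonzero(ase[100:200] <= 0.7 * ase[199])[-1])
        assert out.beats[0].s1 == (k, k + 100)

    def test_plateau_never_below_threshold_keeps_boundaries(self):
        ase = np.zeros(1000)
        ase[100:200] = 1.0
        s = ShannonSeries(ase=ase, window=20, hop=10, fs=1000.0)
        seg = one_beat_seg(s1=(100, 200), s2=(400, 470))
        out = refine_s1(seg, s)
        assert out.beats[0].s1 == (100, 200)

    def test_duration_preserved_for_every_beat(self, clean_model, clean_record):
        pcg, _, _ = clean_record
        base = pipeline.segment(pcg, clean_model, refine="none")
        full = pipeline.segment(pcg, clean_model, refine="s1")
        assert len(base.beats) == len(full.beats)
        for b0, b1 in zip(base.beats, full.beats):
            assert (b1.s1[1] - b1.s1[0]) == (b0.s1[1] - b0.s1[0])

    def test_idempotent_on_clean_bursts(self, clean_model, clean_record):
        pcg, _, _ = clean_record
        clean = pipeline.prepare_pcg(pcg)
        from pcgseg.s1_refine import first_order_ase, viola_envelope

        ase = first_order_ase(viola_envelope(clean))
        seg = pipeline.segment(pcg, clean_model, refine="none")
        once = refine_s1(seg, ase)
        twice = refine_s1(once, ase)
        for b1, b2 in zip(once.beats, twice.beats):
            assert abs(b1.s1[0] - b2.s1[0]) <= 1

    def test_murmur_cohort_onsets_not_worse_than_baseline(self, corpus_model):
        # systolic murmur at half S1 amplitude: refined onsets should be at
        # least as close to truth as the decoded onsets for most beats
        n_better_or_equal = 0
        n_total = 0
        seed = 300
        while n_total < 200:
            pcg, _, truth = make_record(
                seed=seed, murmur="systolic_diamond", murmur_ratio=0.5
            )
            seed += 1
            base = pipeline.segment(pcg, corpus_model, refine="none")
            ref = pipeline.segment(pcg, corpus_model, refine="s1")
            for b0, b1 in zip(base.beats, ref.beats):
                k = np.argmin(np.abs(truth.s1[:, 0] - b0.s1[0]))
                true_start = truth.s1[k, 0]
                if abs(b1.s1[0] - true_start) <= abs(b0.s1[0] - true_start):
                    n_better_or_equal += 1
                n_total += 1
        assert n_better_or_equal / n_total >= 0.8
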