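"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive quantities by a different route than
the implementation (direct double-loop sums, exhaustive enumeration) so the
fast implementations are checked against something they do not share code
with.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest
from scipy.stats import norm

from pcgseg import pipeline
from pcgseg.hsmm_core import N_STATES, duration_support
from pcgseg.synth_pcg import SynthConfig, generate

# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def viola_direct(x: np.ndarray, L: int) -> np.ndarray:
    """Direct double-loop windowed variance on the reflect-padded signal."""
    xp = np.pad(x, L, mode="reflect")
    win = 2 * L + 1
    out = np.empty(x.size)
    for m in range(x.size):
        seg = xp[m : m + win]
        mu = seg.sum() / win
        out[m] = ((seg - mu) ** 2).sum() / win
    return out


def second_order_direct(x: np.ndarray, N: int, hop: int) -> np.ndarray:
    """Direct per-window evaluation of -(1/N) sum x^2 ln(x^2)."""
    starts = range(0, x.size - N + 1, hop)
    out = []
    for a in starts:
        acc = 0.0
        for v in x[a : a + N]:
            if v != 0.0:
                acc -= v * v * np.log(v * v)
        out.append(acc / N)
    return np.asarray(out)


def exhaustive_segmentation_score(
    log_emit: np.ndarray, dur_mean: np.ndarray, dur_sd: np.ndarray, span: float = 3.0
) -> float:
    """Maximum score over all legal cyclic segmentations.

    Enumerates run compositions by memoized recursion over (start frame,
    state, first-run flag); interior runs are constrained to the truncated
    duration support, edge runs may be cut short by the record boundary.
    """
    T = log_emit.shape[0]
    sup = [duration_support(dur_mean[s], dur_sd[s], span) for s in range(N_STATES)]
    cum = np.vstack([np.zeros(N_STATES), np.cumsum(log_emit, axis=0)])
    dlp = {
        (s, d): float(norm.logpdf(d, dur_mean[s], max(dur_sd[s], 1e-6)))
        for s in range(N_STATES)
        for d in range(1, sup[s][1] + 1)
    }

    @lru_cache(maxsize=None)
    def best_from(t: int, s: int, first: bool) -> float:
        out = -np.inf
        lo = 1 if first else sup[s][0]
        for d in range(lo, sup[s][1] + 1):
            end = t + d
            if end > T:
                break
            em = cum[end, s] - cum[t, s]
            if end == T:
                out = max(out, dlp[(s, d)] + em)
            elif first or d >= sup[s][0]:
                out = max(out, dlp[(s, d)] + em + best_from(end, (s + 1) % N_STATES, False))
        if not first:  # last run may be right-truncated below the minimum
            for d in range(1, sup[s][0]):
                if t + d == T:
                    out = max(out, dlp[(s, d)] + (cum[T, s] - cum[t, s]))
        return out

    return max(best_from(0, s0, True) for s0 in range(N_STATES))


# ---------------------------------------------------------------------------
# Study-condition fixtures
# ---------------------------------------------------------------------------

# Five training "individuals" at different heart rates and pathologies,
# mirroring a small mixed training corpus.
TRAIN_CORPUS = (
    dict(seed=10, murmur="none", murmur_ratio=0.0, s2_attenuation_db=0.0, heart_rate_bpm=62.0),
    dict(seed=11, murmur="systolic_diamond", murmur_ratio=0.5, s2_attenuation_db=6.0, heart_rate_bpm=75.0),
    dict(seed=12, murmur="diastolic_decrescendo", murmur_ratio=0.5, s2_attenuation_db=0.0, heart_rate_bpm=68.0),
    dict(seed=13, murmur="none", murmur_ratio=0.0, s2_attenuation_db=0.0, heart_rate_bpm=80.0),
    dict(seed=14, murmur="systolic_diamond", murmur_ratio=0.3, s2_attenuation_db=3.0, heart_rate_bpm=72.0),
)

# Severe aortic stenosis: loud diamond murmur, soft and delayed S2, elderly
# heart-rate variability.
AS_CONDITIONS = dict(
    murmur="systolic_diamond",
    murmur_ratio=1.0,
    s2_attenuation_db=15.0,
    s2_delay_ms=60.0,
    heart_rate_bpm=75.0,
    heart_rate_sd_bpm=5.0,
)


def make_record(duration_s: float = 30.0, **kwargs):
    return generate(SynthConfig(duration_s=duration_s, **kwargs))


@pytest.fixture(scope="session")
def corpus_model():
    """HSMM trained on the five-record mixed corpus (ECG auto-annotated)."""
    records = []
    for spec in TRAIN_CORPUS:
        pcg, ecg, _ = make_record(**spec)
        records.append((pcg, ecg))
    return pipeline.train_model(records)


@pytest.fixture(scope="session")
def clean_model():
    """HSMM trained on three murmur-free records (ground-truth annotations)."""
    records = []
    for seed in (10, 13, 15):
        pcg, _, truth = make_record(seed=seed)
        records.append((pcg, truth.annotations))
    return pipeline.train_model(records)


@pytest.fixture(scope="session")
def clean_record():
    """One held-out murmur-free record with its ground truth."""
    return make_record(seed=20)
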