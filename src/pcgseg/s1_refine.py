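"""S1 onset refinement via the Viola-integral envelope and first-order
average Shannon energy.

Systolic murmurs can drag the HSMM's S1 boundary into the murmur. The fix:
compute a smooth sliding-variance (Viola integral) envelope of the PCG,
transform it with the Shannon energy -x ln x (which favours medium-amplitude
components over both murmur noise floor and dominant peaks), window-average
and standardize it (ASE), then for each decoded S1 interval search backward
from the ASE peak to the last sample at or below 70 % of the peak. The S1
interval is shifted to start there, its end moving symmetrically so the
duration is preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from pcgseg.hsmm_core import Beat, Segmentation
from pcgseg.signal_io import ValidationError, Waveform

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnvelopeSeries:
    """Normalized Viola-integral envelope, full signal length."""

    values: np.ndarray  # E(m) in [0, 1]
    half_window: int  # L_T in samples
    fs: float

    @property
    def M(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class ShannonSeries:
    """Standardized average Shannon energy trace at signal rate."""

    ase: np.ndarray
    window: int  # N in samples
    hop: int
    fs: float


def viola_envelope(pcg: Waveform, s1_scale_s: float = 0.1) -> EnvelopeSeries:
    """Sliding-variance envelope with half-window ``L_T = 0.5 * 0.1 * fs``.

    The window spans ``[m - L_T, m + L_T]``; edges are handled by
    reflect-padding the signal so the output has the signal's length, and the
    result is normalized to unit maximum.
    """
    fs = pcg.fs
    x = pcg.samples
    L = int(round(0.5 * s1_scale_s * fs))
    if L < 1:
        raise ValidationError(f"fs={fs} too low for the Viola window")
    win = 2 * L + 1
    xp = np.pad(x, L, mode="reflect")
    c1 = np.concatenate([[0.0], np.cumsum(xp)])
    c2 = np.concatenate([[0.0], np.cumsum(xp**2)])
    idx = np.arange(x.size)
    s1 = (c1[idx + win] - c1[idx]) / win
    s2 = (c2[idx + win] - c2[idx]) / win
    var = np.maximum(s2 - s1**2, 0.0)
    peak = var.max()
    # threshold relative to signal power: cumsum round-off on a constant
    # signal leaves variance at ~1e-12 x mean-square, never exactly zero
    if peak <= 1e-9 * max(np.mean(xp**2), np.finfo(float).tiny):
        raise ValidationError("degenerate envelope: signal has zero variance everywhere")
    return EnvelopeSeries(values=var / peak, half_window=L, fs=fs)


def first_order_ase(
    env: EnvelopeSeries,
    shannon_scale: float = 0.4,
    window_ms: float = 20.0,
    hop_ms: float = 10.0,
) -> ShannonSeries:
    """Average Shannon energy of the scaled Viola envelope, standardized.

    The envelope is rescaled by ``shannon_scale`` (0.4, which avoids the
    double-peak artefact at S1), transformed sample-wise with -x ln x
    (0 ln 0 := 0), averaged over ``window_ms`` windows hopped at ``hop_ms``,
    linearly interpolated back to sample rate, and standardized to zero
    mean / unit SD.
    """
    fs = env.fs
    x = shannon_scale * env.values
    with np.errstate(divide="ignore", invalid="ignore"):
        shannon = np.where(x > 0, -x * np.log(x), 0.0)
    N = max(1, int(round(window_ms / 1000.0 * fs)))
    hop = max(1, int(round(hop_ms / 1000.0 * fs)))
    n = shannon.size
    if n < N:
        raise ValidationError("signal shorter than the Shannon averaging window")
    starts = np.arange(0, n - N + 1, hop)
    c = np.concatenate([[0.0], np.cumsum(shannon)])
    es = (c[starts + N] - c[starts]) / N
    centers = starts + N // 2
    full = np.interp(np.arange(n), centers, es)
    sd = full.std()
    if sd <= 1e-9 * max(np.max(np.abs(full)), np.finfo(float).tiny):
        raise ValidationError("flat energy: ASE standard deviation is zero")
    ase = (full - full.mean()) / sd
    return ShannonSeries(ase=ase, window=N, hop=hop, fs=fs)


def refine_s1(
    seg: Segmentation,
    ase: ShannonSeries,
    threshold_frac: float = 0.7,
) -> Segmentation:
    """Shift each S1 interval to the backward 70 %-of-peak ASE crossing.

    The search stays inside the decoded S1 interval (so a preceding diastolic
    murmur cannot capture the onset); if no crossing exists, or the ASE peak
    is non-positive, the original boundaries are retained. Duration is always
    preserved and refined intervals are clipped against the neighbouring S2s.
    """
    if not seg.beats:
        raise ValidationError("segmentation has no beats to refine")
    trace = ase.ase
    new_beats: list[Beat] = []
    prev_s2_end = 0
    for i, beat in enumerate(seg.beats):
        a, b = beat.s1
        dur = b - a
        lo, hi = max(0, a), min(trace.size, b)
        new_beat = beat
        if hi - lo >= 2:
            win = trace[lo:hi]
            # the acoustic S1 peak is a *local* maximum inside the interval;
            # a boundary argmax (e.g. ASE still rising into a systolic
            # murmur) is not an S1 peak, so prefer interior local maxima
            interior = np.flatnonzero(
                (win[1:-1] >= win[:-2]) & (win[1:-1] >= win[2:])
            )
            if interior.size:
                t_max = lo + 1 + int(interior[np.argmax(win[interior + 1])])
            else:
                t_max = lo + int(np.argmax(win))
            peak = trace[t_max]
            if peak <= 0:
                log.info("beat %d: non-positive ASE peak, S1 refinement skipped", i)
            else:
                below = np.flatnonzero(trace[lo : t_max + 1] <= threshold_frac * peak)
                if below.size:
                    t_start = lo + int(below[-1])
                    t_start = max(t_start, prev_s2_end)
                    if t_start + dur > beat.s2[0]:
                        t_start = beat.s2[0] - dur
                    if t_start >= prev_s2_end and t_start + dur <= beat.s2[0]:
                        new_beat = Beat(s1=(t_start, t_start + dur), s2=beat.s2)
        new_beats.append(new_beat)
        prev_s2_end = new_beat.s2[1]
    return seg.replace_beats(new_beats)
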