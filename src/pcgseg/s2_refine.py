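"""S2 relocation for beats whose S1-to-S2 interval is statistically abnormal.

In aortic valve disease the HSMM often mistakes systolic murmur energy for
S2, which shortens the apparent S1-to-S2 interval (S12). Each beat's S12 is
tested against a reference Gaussian (learned from the training corpus, or
optionally from the recording itself); beats outside the 95 % confidence
interval are re-examined: a second-order average Shannon energy trace
(computed on x^2 over 20 ms windows with 50 % overlap, mean-centered and
peak-normalized -> NASE) is searched between the current S2 start and the
middle of the diastolic interval for local energy lobes. When at least two
lobes exist, the final (latest) lobe pair is taken as the true S2 — late
diastolic lobes better represent S2 when valve closure is delayed by
stenosis — and the S2 interval is remapped to span them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import norm

from pcgseg.hsmm_core import Beat, Segmentation
from pcgseg.signal_io import ValidationError, Waveform

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class BeatTimingStats:
    """Per-beat S12 intervals and the abnormality flags from the 95 % rule."""

    s12: np.ndarray  # seconds, one per beat
    flags: np.ndarray  # bool, True = abnormal
    mu: float
    sigma: float
    ci_level: float


@dataclass(frozen=True)
class FrameEnergy:
    """Windowed second-order Shannon energy and its normalized form."""

    eprime: np.ndarray
    ase: np.ndarray
    nase: np.ndarray
    centers: np.ndarray  # window-center sample indices
    window: int
    hop: int
    fs: float


def s12_stats(
    seg: Segmentation,
    mu: float | None = None,
    sigma: float | None = None,
    ci_level: float = 0.95,
    min_beats: int = 5,
) -> BeatTimingStats:
    """Flag beats whose S12 (S1 start to S2 start, seconds) leaves the
    reference Gaussian's confidence interval.

    With ``mu``/``sigma`` omitted the reference is fit to the recording's own
    beats (recording-level mode); normally they come from the trained model.
    """
    if len(seg.beats) < min_beats:
        raise ValidationError(f"need at least {min_beats} beats for S12 statistics")
    s12 = np.array([(b.s2[0] - b.s1[0]) / seg.fs for b in seg.beats])
    if mu is None or sigma is None:
        mu = float(np.mean(s12))
        sigma = float(np.std(s12, ddof=1))
    if not sigma > 0:
        raise ValidationError("degenerate reference distribution: sigma must be > 0")
    z = norm.ppf(0.5 + ci_level / 2.0)
    flags = np.abs(s12 - mu) > z * sigma
    return BeatTimingStats(s12=s12, flags=flags, mu=float(mu), sigma=float(sigma), ci_level=ci_level)


def second_order_ase(
    pcg: Waveform,
    window_ms: float = 20.0,
    overlap: float = 0.5,
) -> FrameEnergy:
    """Second-order Shannon energy per window of the normalized band-passed
    PCG: ``E' = -(1/N) sum x^2 ln(x^2)`` with ``0 ln 0 := 0``; ``ASE`` is the
    mean-centered trace and ``NASE = ASE / max |ASE|``."""
    x = pcg.samples
    fs = pcg.fs
    N = max(2, int(round(window_ms / 1000.0 * fs)))
    hop = max(1, int(round(N * (1.0 - overlap))))
    if x.size < N:
        raise ValidationError("record shorter than one analysis window")
    x2 = x**2
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(x2 > 0, -x2 * np.log(x2), 0.0)
    starts = np.arange(0, x.size - N + 1, hop)
    c = np.concatenate([[0.0], np.cumsum(terms)])
    eprime = (c[starts + N] - c[starts]) / N
    if np.all(eprime == 0):
        raise ValidationError("all-zero record: second-order Shannon energy is degenerate")
    ase = eprime - eprime.mean()
    peak = np.max(np.abs(ase))
    nase = ase / peak
    centers = starts + N // 2
    return FrameEnergy(
        eprime=eprime, ase=ase, nase=nase, centers=centers, window=N, hop=hop, fs=fs
    )


def _lobes(segment: np.ndarray, prominence: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Local maxima of a NASE segment with their flanking minima.

    Returns (peak indices, left-minimum indices, right-minimum indices), all
    relative to the segment.
    """
    peaks, _ = find_peaks(segment, prominence=prominence)
    left = np.empty_like(peaks)
    right = np.empty_like(peaks)
    for k, p in enumerate(peaks):
        # nearest adjacent minima: walk downhill until the trace stops
        # falling (derivative sign change), so a lobe's flank ends where the
        # lobe bottoms out instead of at the quietest point of the interval
        i = p
        while i > 0 and segment[i - 1] < segment[i]:
            i -= 1
        left[k] = i
        j = p
        while j < segment.size - 1 and segment[j + 1] < segment[j]:
            j += 1
        right[k] = j
    return peaks, left, right


def relocate_s2(
    seg: Segmentation,
    stats: BeatTimingStats,
    fe: FrameEnergy,
    lobe_prominence: float = 0.1,
) -> Segmentation:
    """Move the S2 of each flagged beat onto the final NASE lobe pair.

    The search window runs from the current S2 start to the center of the
    diastolic interval (S2 end to the next beat's S1 start). Beats that are
    not flagged, have fewer than two candidate lobes, or are the last beat of
    the record (no diastolic endpoint) are left untouched.
    """
    if stats.flags.size != len(seg.beats):
        raise ValidationError("flag vector does not match the number of beats")
    new_beats: list[Beat] = list(seg.beats)
    for i, beat in enumerate(seg.beats):
        if not stats.flags[i]:
            continue
        if i + 1 >= len(seg.beats):
            log.info("beat %d flagged but last in record; S2 left unchanged", i)
            continue
        next_s1_start = seg.beats[i + 1].s1[0]
        t1 = beat.s2[0]
        t2 = (beat.s2[1] + next_s1_start) // 2
        jsel = np.flatnonzero((fe.centers >= t1) & (fe.centers <= t2))
        if jsel.size < 3:
            continue
        segment = fe.nase[jsel[0] : jsel[-1] + 1]
        peaks, left, right = _lobes(segment, lobe_prominence)
        if peaks.size < 2:
            log.info("beat %d: %d NASE lobe(s) found, S2 left unchanged", i, peaks.size)
            continue
        new_start = int(fe.centers[jsel[0] + left[-2]])
        new_end = int(fe.centers[jsel[0] + right[-1]]) + 1
        new_start = max(new_start, beat.s1[1])
        new_end = min(new_end, next_s1_start)
        if new_start >= new_end:
            log.info("beat %d: relocated S2 collapsed after clipping; unchanged", i)
            continue
        new_beats[i] = Beat(s1=beat.s1, s2=(new_start, new_end))
    return seg.replace_beats(new_beats)
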