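"""Reference ECG annotations: R-peak detection and T-wave-end localization.

R-peaks come from a Pan-Tompkins detector (5-15 Hz band-pass, differentiation,
squaring, 150 ms moving-window integration, thresholding with a 200 ms
refractory period). T-wave ends are found by ensemble-averaging R-aligned
beats into a template, locating the template's T-end once with the tangent
method on the T-wave downslope, and transferring that offset to each beat via
local cross-correlation alignment. These annotations serve only as training
labels and as the evaluation reference: the test-time segmenter never sees
the ECG.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import signal

from pcgseg.signal_io import EcgAnnotations, ValidationError, Waveform

log = logging.getLogger(__name__)

REFRACTORY_S = 0.2
EDGE_GUARD_S = 0.1
MIN_TEMPLATE_BEATS = 5
TEMPLATE_XCORR_MIN = 0.8


def _moving_average(x: np.ndarray, win: int) -> np.ndarray:
    win = max(1, int(win))
    kernel = np.ones(win) / win
    return np.convolve(x, kernel, mode="same")


def detect_r_peaks(ecg: Waveform) -> np.ndarray:
    """Detect R-peaks with a Pan-Tompkins style pipeline.

    Returns sorted sample indices. Fewer than two detected beats yields an
    empty array with a warning (downstream stages need >= 2 beats).
    """
    fs = ecg.fs
    x = ecg.samples
    sos = signal.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    sq = deriv**2
    mwi = _moving_average(sq, int(round(0.150 * fs)))
    if np.max(mwi) <= 0:
        log.warning("no QRS energy found; returning no R-peaks")
        return np.array([], dtype=np.int64)

    distance = int(round(REFRACTORY_S * fs))
    cand, _ = signal.find_peaks(mwi, distance=distance)
    if cand.size == 0:
        return np.array([], dtype=np.int64)
    # Global two-pass threshold (translation invariant, robust to a few
    # outlier spikes): seed from a high percentile of candidate heights, then
    # re-derive from the median of the retained QRS-like candidates.
    heights = mwi[cand]
    thr = 0.2 * np.percentile(heights, 98)
    qrs_like = heights[heights > thr]
    if qrs_like.size:
        thr = 0.3 * np.median(qrs_like)
    cand = cand[mwi[cand] > thr]

    # Refine each detection to the local extremum of the band-passed ECG.
    half = int(round(0.075 * fs))
    peaks = []
    for c in cand:
        lo, hi = max(0, c - half), min(len(x), c + half + 1)
        peaks.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    peaks = np.unique(peaks)
    # Enforce refractory period after refinement: keep the larger peak.
    kept: list[int] = []
    for p in peaks:
        if kept and p - kept[-1] < distance:
            if np.abs(bp[p]) > np.abs(bp[kept[-1]]):
                kept[-1] = int(p)
        else:
            kept.append(int(p))
    guard = int(round(EDGE_GUARD_S * fs))
    out = np.array([p for p in kept if guard <= p < len(x) - guard], dtype=np.int64)
    if out.size < 2:
        log.warning("fewer than 2 R-peaks detected (%d)", out.size)
        return np.array([], dtype=np.int64)
    return out


def _tangent_t_end(template: np.ndarray, r_offset: int, fs: float) -> int | None:
    """Locate the T-end on an averaged beat with the tangent method.

    The T-wave extremum is sought 150-450 ms after the R-peak; the tangent at
    the steepest point of its terminal slope is extrapolated to the local
    baseline (the TP-segment level measured after the T-wave — band-pass
    filtering leaves a small offset there, so zero cannot be assumed), and
    its intersection is the T-end.
    """
    lo = r_offset + int(round(0.150 * fs))
    hi = min(len(template), r_offset + int(round(0.450 * fs)))
    if hi - lo < int(round(0.05 * fs)):
        return None
    seg = template[lo:hi]
    t_peak = lo + int(np.argmax(np.abs(seg)))
    sign = np.sign(template[t_peak]) or 1.0
    y = sign * template  # make the T-wave positive
    # Steepest downslope between the T peak and the end of the search span.
    tail_hi = min(len(y) - 1, t_peak + int(round(0.200 * fs)))
    if tail_hi - t_peak < 3:
        return None
    dy = np.gradient(y)
    d_seg = dy[t_peak:tail_hi]
    t_d = t_peak + int(np.argmin(d_seg))
    slope = dy[t_d]
    if slope >= 0:
        return None
    base_lo = min(len(y), t_d + int(round(0.120 * fs)))
    base_hi = min(len(y), t_d + int(round(0.200 * fs)))
    baseline = float(np.median(y[base_lo:base_hi])) if base_hi - base_lo >= 3 else 0.0
    t_end = t_d + (y[t_d] - baseline) / (-slope)
    return int(round(t_end))


def detect_t_ends(ecg: Waveform, r_peaks: np.ndarray) -> np.ndarray:
    """Locate one T-end per beat by template matching.

    Requires at least 5 R-peaks for a stable ensemble average. Beats whose
    normalized cross-correlation with the template falls below 0.8, or whose
    T-wave would extend past the record or the next R-peak, are skipped.
    """
    r_peaks = np.asarray(r_peaks, dtype=np.int64)
    if r_peaks.size < MIN_TEMPLATE_BEATS:
        raise ValidationError(
            f"insufficient beats for template ({r_peaks.size} < {MIN_TEMPLATE_BEATS})"
        )
    fs = ecg.fs
    x = ecg.samples
    pre = int(round(0.100 * fs))
    med_rr = float(np.median(np.diff(r_peaks)))
    post = int(min(0.9 * med_rr, round(0.600 * fs)))
    beats = []
    usable = []
    for r in r_peaks:
        if r - pre < 0 or r + post > len(x):
            continue
        beats.append(x[r - pre : r + post])
        usable.append(r)
    if len(beats) < MIN_TEMPLATE_BEATS:
        raise ValidationError(
            f"insufficient complete beats for template ({len(beats)})"
        )
    template = np.mean(beats, axis=0)
    t_end_tpl = _tangent_t_end(template, pre, fs)
    if t_end_tpl is None:
        log.warning("tangent method failed on the template; no T-ends emitted")
        return np.array([], dtype=np.int64)
    offset = t_end_tpl - pre  # samples after the R-peak

    # Transfer the template offset to each beat by locally aligning the
    # T-wave region (the whole-beat correlation is QRS-dominated and blind
    # to beat-to-beat repolarization shifts).
    max_lag = int(round(0.050 * fs))
    t_lo = max(0, t_end_tpl - int(round(0.150 * fs)))
    t_hi = min(len(template), t_end_tpl + int(round(0.060 * fs)))
    tpl_t = template[t_lo:t_hi] - template[t_lo:t_hi].mean()
    tpl_norm = np.linalg.norm(tpl_t)
    t_ends: list[int] = []
    next_r = {int(r): int(nr) for r, nr in zip(r_peaks[:-1], r_peaks[1:])}
    for r, beat in zip(usable, beats):
        best_lag, best_score = 0, -np.inf
        for lag in range(-max_lag, max_lag + 1):
            a, b = t_lo + lag, t_hi + lag
            if a < 0 or b > len(beat):
                continue
            seg = beat[a:b] - beat[a:b].mean()
            denom = tpl_norm * np.linalg.norm(seg)
            if denom <= 0:
                continue
            score = float(np.dot(seg, tpl_t) / denom)
            if score > best_score:
                best_score, best_lag = score, lag
        if best_score < TEMPLATE_XCORR_MIN:
            log.info("beat at %d skipped: template correlation %.2f", r, best_score)
            continue
        te = int(r) + offset + best_lag
        nr = next_r.get(int(r))
        if te >= len(x) or (nr is not None and te >= nr) or te <= r:
            continue
        t_ends.append(te)
    return np.array(sorted(t_ends), dtype=np.int64)


def annotate(ecg: Waveform) -> EcgAnnotations:
    """Run both detectors and package the result."""
    r = detect_r_peaks(ecg)
    t = detect_t_ends(ecg, r) if r.size >= MIN_TEMPLATE_BEATS else np.array([], dtype=np.int64)
    return EcgAnnotations(r_peaks=r, t_ends=t, fs=ecg.fs)
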