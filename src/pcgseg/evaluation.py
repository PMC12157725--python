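"""ECG-referenced scoring of a segmentation.

A detected S1 is a true positive when its start falls within 100 ms *after*
the matched R-peak; a detected S2 when its interval center falls within
+/-100 ms *around* the matched T-wave end. Matching is greedy
nearest-distance with a one-to-one constraint; unmatched reference events are
false negatives, unmatched detections false positives. Sensitivity, positive
predictive value and F1 (the harmonic mean of the two) follow from the
pooled counts; undefined metrics are reported as NA, never coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pcgseg.hsmm_core import Segmentation
from pcgseg.signal_io import EcgAnnotations

DEFAULT_WINDOW_MS = 100.0


@dataclass(frozen=True)
class DetectionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "DetectionCounts") -> "DetectionCounts":
        return DetectionCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricsReport:
    """Se / PPV / F1 as percentages; None encodes an undefined (NA) metric."""

    se: float | None
    ppv: float | None
    f1: float | None

    def rounded(self, ndigits: int = 2) -> dict[str, float | str]:
        def fmt(v):
            return "NA" if v is None else round(v, ndigits)

        return {"Se": fmt(self.se), "PPV": fmt(self.ppv), "F1": fmt(self.f1)}


def _greedy_match(refs: np.ndarray, dets: np.ndarray, lo_ms: float, hi_ms: float, fs: float) -> int:
    """One-to-one greedy matching by proximity.

    A (ref, det) pair is admissible when ``lo_ms <= (det - ref)/fs*1000 <=
    hi_ms``; admissible pairs are consumed in order of increasing absolute
    offset. Returns the number of matches (TP).
    """
    pairs: list[tuple[float, int, int]] = []
    for i, r in enumerate(refs):
        for j, d in enumerate(dets):
            off_ms = (d - r) / fs * 1000.0
            if lo_ms <= off_ms <= hi_ms:
                pairs.append((abs(off_ms), i, j))
    pairs.sort()
    used_r: set[int] = set()
    used_d: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_r or j in used_d:
            continue
        used_r.add(i)
        used_d.add(j)
        tp += 1
    return tp


def score_s1(
    seg: Segmentation, ann: EcgAnnotations, window_ms: float = DEFAULT_WINDOW_MS
) -> DetectionCounts:
    """Score S1 detections: start within ``window_ms`` after an R-peak."""
    refs = np.asarray(ann.r_peaks, dtype=float)
    dets = np.asarray([b.s1[0] for b in seg.beats], dtype=float)
    tp = _greedy_match(refs, dets, 0.0, window_ms, seg.fs)
    return DetectionCounts(tp=tp, fp=dets.size - tp, fn=refs.size - tp)


def score_s2(
    seg: Segmentation, ann: EcgAnnotations, window_ms: float = DEFAULT_WINDOW_MS
) -> DetectionCounts:
    """Score S2 detections: interval center within +/-``window_ms`` of a
    T-wave end."""
    refs = np.asarray(ann.t_ends, dtype=float)
    dets = np.asarray([(b.s2[0] + b.s2[1]) / 2.0 for b in seg.beats], dtype=float)
    tp = _greedy_match(refs, dets, -window_ms, window_ms, seg.fs)
    return DetectionCounts(tp=tp, fp=dets.size - tp, fn=refs.size - tp)


def metrics(c: DetectionCounts) -> MetricsReport:
    """Sensitivity, positive predictive value and F1 from pooled counts."""
    se = 100.0 * c.tp / (c.tp + c.fn) if c.tp + c.fn > 0 else None
    ppv = 100.0 * c.tp / (c.tp + c.fp) if c.tp + c.fp > 0 else None
    if se is not None and ppv is not None:
        f1 = 0.0 if se + ppv == 0 else 2.0 * ppv * se / (ppv + se)
    else:
        f1 = None
    return MetricsReport(se=se, ppv=ppv, f1=f1)
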