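"""End-to-end orchestration: train from PCG+ECG pairs, segment ECG-free,
evaluate against ECG annotations.

These functions are the library-level face of the train/test workflow; the
command-line interface in :mod:`pcgseg.cli` is a thin wrapper around them.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from pcgseg import ecg_annotation, hsmm_core, s1_refine, s2_refine
from pcgseg.config import DEFAULTS, load_config
from pcgseg.evaluation import DetectionCounts, MetricsReport, metrics, score_s1, score_s2
from pcgseg.hsmm_core import FrameFeatures, HsmmModel, Segmentation
from pcgseg.preprocess import preprocess_ecg, preprocess_pcg
from pcgseg.signal_io import EcgAnnotations, ValidationError, Waveform, WORKING_FS, resample

log = logging.getLogger(__name__)


def prepare_pcg(pcg: Waveform, config: dict | None = None) -> Waveform:
    """Resample to the working rate and band-pass + normalize the PCG."""
    cfg = config or DEFAULTS
    w = resample(pcg, WORKING_FS)
    return preprocess_pcg(
        w,
        band=tuple(cfg["pcg"]["band"]),
        order=cfg["pcg"]["cheby_order"],
        ripple_db=cfg["pcg"]["ripple_db"],
    )


def annotate_ecg(ecg: Waveform, config: dict | None = None) -> EcgAnnotations:
    """Preprocess the ECG and produce R-peak / T-end reference annotations."""
    cfg = config or DEFAULTS
    w = resample(ecg, WORKING_FS)
    clean = preprocess_ecg(
        w,
        mains_hz=cfg["ecg"]["mains_hz"],
        band=tuple(cfg["ecg"]["band"]),
        order=cfg["ecg"]["butter_order"],
    )
    return ecg_annotation.annotate(clean)


def training_example(
    pcg: Waveform, ann: EcgAnnotations, config: dict | None = None
) -> tuple[FrameFeatures, np.ndarray]:
    """One (features, frame labels) pair for supervised HSMM training."""
    cfg = config or DEFAULTS
    clean = prepare_pcg(pcg, cfg)
    feats = hsmm_core.extract_features(
        clean,
        frame_rate=cfg["hsmm"]["frame_rate"],
        kurtosis_win_ms=cfg["hsmm"]["kurtosis_win_ms"],
        kurtosis_hop_ms=cfg["hsmm"]["kurtosis_hop_ms"],
    )
    if ann.fs != clean.fs:
        raise ValidationError(
            f"annotation rate {ann.fs} differs from working rate {clean.fs}"
        )
    labels = hsmm_core.label_frames(
        ann,
        n_frames=feats.n_frames,
        frame_rate=feats.frame_rate,
        s1_win_ms=cfg["hsmm"]["s1_win_ms"],
        s2_win_ms=cfg["hsmm"]["s2_win_ms"],
    )
    return feats, labels


def train_model(
    records: Sequence[tuple[Waveform, EcgAnnotations | Waveform]],
    config: dict | None = None,
) -> HsmmModel:
    """Train the HSMM from (PCG, ECG-or-annotations) pairs.

    An ECG waveform in place of annotations is auto-annotated first.
    """
    cfg = config or DEFAULTS
    examples = []
    for pcg, ref in records:
        ann = ref if isinstance(ref, EcgAnnotations) else annotate_ecg(ref, cfg)
        examples.append(training_example(pcg, ann, cfg))
    model = hsmm_core.train(examples, emission=cfg["hsmm"]["emission"])
    for s in hsmm_core.StateLabel:
        log.info(
            "state %s: duration %.1f +/- %.1f frames",
            s.name,
            model.dur_mean[s],
            model.dur_sd[s],
        )
    return model


def segment(
    pcg: Waveform,
    model: HsmmModel,
    refine: str = "both",
    config: dict | None = None,
) -> Segmentation:
    """ECG-free segmentation of one PCG recording.

    ``refine`` selects the post-processing: ``"none"`` reproduces the plain
    HSMM-with-kurtosis baseline, ``"s1"``/``"s2"`` apply one refinement,
    ``"both"`` the full method.
    """
    if refine not in ("both", "s1", "s2", "none"):
        raise ValidationError(f"unknown refine mode {refine!r}")
    cfg = config or DEFAULTS
    clean = prepare_pcg(pcg, cfg)
    feats = hsmm_core.extract_features(
        clean,
        frame_rate=cfg["hsmm"]["frame_rate"],
        kurtosis_win_ms=cfg["hsmm"]["kurtosis_win_ms"],
        kurtosis_hop_ms=cfg["hsmm"]["kurtosis_hop_ms"],
    )
    seg = hsmm_core.decode(model, feats)

    if refine in ("s1", "both") and seg.beats:
        env = s1_refine.viola_envelope(clean)
        ase = s1_refine.first_order_ase(
            env,
            shannon_scale=cfg["s1"]["shannon_scale"],
            window_ms=cfg["s1"]["ase_window_ms"],
            hop_ms=cfg["s1"]["ase_hop_ms"],
        )
        seg = s1_refine.refine_s1(seg, ase, threshold_frac=cfg["s1"]["threshold_frac"])

    if refine in ("s2", "both") and len(seg.beats) >= 5:
        if cfg["s2"]["reference"] == "recording":
            stats = s2_refine.s12_stats(seg, ci_level=cfg["s2"]["ci_level"])
        else:
            stats = s2_refine.s12_stats(
                seg,
                mu=model.s12_mu,
                sigma=model.s12_sigma,
                ci_level=cfg["s2"]["ci_level"],
            )
        fe = s2_refine.second_order_ase(
            clean, window_ms=cfg["s2"]["window_ms"], overlap=cfg["s2"]["overlap"]
        )
        seg = s2_refine.relocate_s2(
            seg, stats, fe, lobe_prominence=cfg["s2"]["lobe_prominence"]
        )
    return seg


def evaluate(
    seg: Segmentation,
    ann: EcgAnnotations,
    window_ms: float | None = None,
) -> dict[str, dict]:
    """Score one segmentation: counts and metrics per sound type."""
    if ann.fs != seg.fs:
        raise ValidationError(f"annotation fs {ann.fs} != segmentation fs {seg.fs}")
    w = DEFAULTS["eval"]["window_ms"] if window_ms is None else window_ms
    c1 = score_s1(seg, ann, window_ms=w)
    c2 = score_s2(seg, ann, window_ms=w)
    return {
        "s1": {"counts": c1, "metrics": metrics(c1)},
        "s2": {"counts": c2, "metrics": metrics(c2)},
    }


def pool_counts(counts: Iterable[DetectionCounts]) -> DetectionCounts:
    """Pooled TP/FP/FN across records (the tables' group arithmetic)."""
    total = DetectionCounts(0, 0, 0)
    for c in counts:
        total = total + c
    return total
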