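"""Band-pass conditioning of PCG and ECG before feature extraction.

The PCG keeps the 40-450 Hz band where the fundamental heart sounds and
murmurs live (third-order Chebyshev type-I, 1 dB ripple) and is normalized to
unit peak amplitude. The ECG keeps 0.5-100 Hz (second-order Butterworth) and
gets a mains notch. All filters are applied forward-backward: the S1/S2
timings are the measurand, so group delay must not shift events.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from pcgseg.signal_io import ValidationError, Waveform


def _bandpass_pcg_sos(fs: float, band=(40.0, 450.0), order: int = 3, ripple_db: float = 1.0):
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ValidationError(
            f"PCG band {band} invalid at fs={fs} Hz (need 0 < low < high < fs/2)"
        )
    return signal.cheby1(order, ripple_db, [low, high], btype="bandpass", fs=fs, output="sos")


def _bandpass_ecg_sos(fs: float, band=(0.5, 100.0), order: int = 2):
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ValidationError(
            f"ECG band {band} invalid at fs={fs} Hz (need 0 < low < high < fs/2)"
        )
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_pcg(w: Waveform, band=(40.0, 450.0), order: int = 3, ripple_db: float = 1.0) -> Waveform:
    """Zero-phase Chebyshev band-pass of the PCG, without normalization.

    Exposed separately because the refinement stages need the linear (scale-
    equivariant) filter output; :func:`preprocess_pcg` adds the peak
    normalization.
    """
    if w.fs <= 2 * band[1]:
        raise ValidationError(
            f"fs={w.fs} Hz too low for the {band[1]} Hz band edge (Nyquist)"
        )
    sos = _bandpass_pcg_sos(w.fs, band, order, ripple_db)
    out = signal.sosfiltfilt(sos, w.samples)
    return Waveform(out, fs=w.fs, label=w.label or "pcg")


def preprocess_pcg(w: Waveform, band=(40.0, 450.0), order: int = 3, ripple_db: float = 1.0) -> Waveform:
    """Band-pass filter the PCG and normalize to unit peak amplitude."""
    filtered = bandpass_pcg(w, band, order, ripple_db)
    peak = np.max(np.abs(filtered.samples))
    if peak == 0:
        raise ValidationError("cannot normalize silent signal")
    return Waveform(filtered.samples / peak, fs=w.fs, label=filtered.label)


def preprocess_ecg(
    w: Waveform,
    mains_hz: float = 50.0,
    band=(0.5, 100.0),
    order: int = 2,
    notch_q: float = 30.0,
) -> Waveform:
    """Band-pass the ECG and notch out mains interference (and its harmonics
    below the upper band edge)."""
    if w.fs <= 2 * band[1]:
        raise ValidationError(
            f"fs={w.fs} Hz too low for the {band[1]} Hz band edge (Nyquist)"
        )
    sos = _bandpass_ecg_sos(w.fs, band, order)
    out = signal.sosfiltfilt(sos, w.samples)
    harmonic = mains_hz
    while harmonic < min(band[1], w.fs / 2):
        b, a = signal.iirnotch(harmonic, notch_q, fs=w.fs)
        out = signal.filtfilt(b, a, out)
        harmonic += mains_hz
    return Waveform(out, fs=w.fs, label=w.label or "ecg")
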