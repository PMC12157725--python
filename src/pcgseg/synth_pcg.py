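"""Synthetic synchronized PCG + ECG with exact ground truth.

The generator emulates what the segmenter has to cope with in aortic valve
disease: quasi-periodic beats whose S1 and S2 are Gaussian-windowed tones in
the 20-200 Hz fundamental-heart-sound band, an optional diamond-shaped
systolic murmur (aortic stenosis) or decrescendo diastolic murmur (aortic
regurgitation) made of band-passed noise, S2 attenuation down to complete
absence, beat-to-beat heart-rate variability, additive broadband noise, and
a synchronized ECG built from Gaussian P-QRS-T waves whose R-peak and T-end
landmarks are known by construction (the T-end is placed exactly where the
tangent method lands on a Gaussian T-wave: two sigma past its center).

It is a signal-level test harness, not a physiological simulator: waveform
shape defaults (tone frequencies, burst durations, the 30 ms R-to-S1
electromechanical delay) are generator conventions, exposed in the config.
The seed fixes the full output bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sp_signal

from pcgseg.signal_io import EcgAnnotations, ValidationError, Waveform


@dataclass(frozen=True)
class SynthConfig:
    duration_s: float = 30.0
    fs: float = 1000.0
    heart_rate_bpm: float = 70.0
    heart_rate_sd_bpm: float = 2.0
    s1_freq_hz: float = 60.0
    s1_dur_ms: float = 90.0
    s2_freq_hz: float = 85.0
    s2_dur_ms: float = 70.0
    s2_attenuation_db: float = 0.0  # np.inf = absent S2
    s2_split_ms: float = 0.0  # A2-P2 split: 0 = single burst, else two sub-bursts
    murmur: str = "none"  # none | systolic_diamond | diastolic_decrescendo
    murmur_ratio: float = 0.5  # murmur RMS / S1 RMS
    murmur_peak_frac: float = 0.5  # diamond apex position within systole (late-peaking AS > 0.5)
    noise_snr_db: float = 30.0
    seed: int = 0
    r_to_s1_ms: float = 30.0  # electromechanical delay
    t_center_ms: float = 240.0  # T-wave center after R
    t_sigma_ms: float = 40.0  # T-wave Gaussian width; T-end = center + 2 sigma
    s2_delay_ms: float = 0.0  # mechanical S2 delay past the T-end (severe AS)
    timing_jitter_ms: float = 5.0  # per-beat SD on S1 onset and S2 center
    t_jitter_ms: float = 8.0  # per-beat SD on the T-wave center (repolarization)


@dataclass(frozen=True)
class GroundTruth:
    """Per-beat true landmarks, all in samples at the generated rate."""

    r_peaks: np.ndarray
    t_ends: np.ndarray
    s1: np.ndarray  # (n_beats, 2) half-open intervals
    s2: np.ndarray  # (n_beats, 2)
    fs: float

    @property
    def annotations(self) -> EcgAnnotations:
        return EcgAnnotations(r_peaks=self.r_peaks, t_ends=self.t_ends, fs=self.fs)

    @property
    def n_beats(self) -> int:
        return int(self.r_peaks.size)


def _gauss_burst(n: int, fs: float, center: float, dur_s: float, freq: float, phase: float) -> np.ndarray:
    """A Gaussian-windowed tone; window sigma is one sixth of the duration."""
    t = np.arange(n) / fs
    sigma = dur_s / 6.0
    return np.exp(-0.5 * ((t - center) / sigma) ** 2) * np.sin(2 * np.pi * freq * (t - center) + phase)


def generate(cfg: SynthConfig) -> tuple[Waveform, Waveform, GroundTruth]:
    """Generate one synchronized PCG/ECG pair with its ground truth."""
    fs = cfg.fs
    rr_nominal = 60.0 / cfg.heart_rate_bpm
    if cfg.duration_s < 4 * rr_nominal:
        raise ValidationError("duration must cover at least 4 beats")
    beat_span_s = (
        cfg.r_to_s1_ms + cfg.s1_dur_ms + cfg.s2_dur_ms / 2.0
    ) / 1000.0 + (cfg.t_center_ms + 2 * cfg.t_sigma_ms) / 1000.0
    if rr_nominal < beat_span_s * 0.9:
        raise ValidationError(
            f"heart rate {cfg.heart_rate_bpm} bpm leaves no room for S1+S2 "
            f"(beat needs ~{beat_span_s:.2f} s)"
        )
    rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * fs))
    t_end_off = (cfg.t_center_ms + 2 * cfg.t_sigma_ms) / 1000.0  # tangent T-end

    # Beat schedule with Gaussian heart-rate variability.
    r_times: list[float] = []
    t_cursor = 0.5
    margin = t_end_off + cfg.s2_dur_ms / 2000.0 + 0.1
    while t_cursor < cfg.duration_s - margin:
        r_times.append(t_cursor)
        hr = max(30.0, rng.normal(cfg.heart_rate_bpm, cfg.heart_rate_sd_bpm))
        t_cursor += 60.0 / hr
    if len(r_times) < 4:
        raise ValidationError("fewer than 4 beats fit in the requested duration")

    ecg = np.zeros(n)
    pcg = np.zeros(n)
    t_axis = np.arange(n) / fs

    def add_gauss(sig: np.ndarray, amp: float, center: float, sigma_s: float) -> None:
        sig += amp * np.exp(-0.5 * ((t_axis - center) / sigma_s) ** 2)

    r_peaks, t_ends, s1_iv, s2_iv = [], [], [], []
    murmur_sys_ends: list[int] = []
    s2_amp = 0.0 if np.isinf(cfg.s2_attenuation_db) else 10.0 ** (-cfg.s2_attenuation_db / 20.0)
    s1_dur_s = cfg.s1_dur_ms / 1000.0
    s2_dur_s = cfg.s2_dur_ms / 1000.0

    for k_beat, r in enumerate(r_times):
        # ECG: P, Q, R, S, T Gaussian waves.
        add_gauss(ecg, 0.12, r - 0.160, 0.020)
        add_gauss(ecg, -0.10, r - 0.022, 0.006)
        add_gauss(ecg, 1.00, r, 0.008)
        add_gauss(ecg, -0.18, r + 0.026, 0.007)
        # Repolarization tracks the cycle length (Bazett-style sqrt scaling
        # around the nominal rate) with its own beat-to-beat jitter.
        if k_beat + 1 < len(r_times):
            rr_here = r_times[k_beat + 1] - r
        else:
            rr_here = r - r_times[k_beat - 1]
        qt_scale = np.sqrt(max(rr_here, 0.3) / rr_nominal)
        t_center = (
            r
            + cfg.t_center_ms / 1000.0 * qt_scale
            + rng.normal(0.0, cfg.t_jitter_ms / 1000.0)
        )
        t_sigma = cfg.t_sigma_ms / 1000.0
        add_gauss(ecg, 0.28, t_center, t_sigma)
        t_end = t_center + 2 * t_sigma

        jit1, jit2 = rng.normal(0.0, cfg.timing_jitter_ms / 1000.0, size=2)
        s1_start = r + cfg.r_to_s1_ms / 1000.0 + jit1
        s1_center = s1_start + s1_dur_s / 2.0
        s2_center = t_end + cfg.s2_delay_ms / 1000.0 + jit2
        s2_start = s2_center - s2_dur_s / 2.0
        # electrical end of systole: where the murmur must have decayed by
        nominal_s2_start = t_end - s2_dur_s / 2.0

        pcg += _gauss_burst(n, fs, s1_center, s1_dur_s, cfg.s1_freq_hz, rng.uniform(0, 2 * np.pi))
        if s2_amp > 0:
            if cfg.s2_split_ms > 0:
                # aortic and pulmonary components as two narrow sub-bursts
                half_split = cfg.s2_split_ms / 2000.0
                sub_dur = max(s2_dur_s - 2 * half_split, s2_dur_s / 3.0)
                for comp_center in (s2_center - half_split, s2_center + half_split):
                    pcg += s2_amp * _gauss_burst(
                        n, fs, comp_center, sub_dur, cfg.s2_freq_hz, rng.uniform(0, 2 * np.pi)
                    )
            else:
                pcg += s2_amp * _gauss_burst(
                    n, fs, s2_center, s2_dur_s, cfg.s2_freq_hz, rng.uniform(0, 2 * np.pi)
                )

        r_peaks.append(int(round(r * fs)))
        t_ends.append(int(round(t_end * fs)))
        s1_iv.append((int(round(s1_start * fs)), int(round((s1_start + s1_dur_s) * fs))))
        s2_iv.append((int(round(s2_start * fs)), int(round((s2_start + s2_dur_s) * fs))))
        murmur_sys_ends.append(int(round(nominal_s2_start * fs)))

    # Murmurs: band-passed noise shaped by the murmur's amplitude profile.
    if cfg.murmur != "none" and cfg.murmur_ratio > 0:
        sos = sp_signal.butter(4, [80.0, 400.0], btype="bandpass", fs=fs, output="sos")
        raw = sp_signal.sosfiltfilt(sos, rng.standard_normal(n))
        profile = np.zeros(n)
        for k in range(len(r_peaks)):
            if cfg.murmur == "systolic_diamond":
                # the murmur tracks ejection and decays by the *electrical*
                # end of systole, even when valve closure (S2) is delayed
                a = s1_iv[k][1]
                b = min(murmur_sys_ends[k], s2_iv[k][0])
                if b - a > 4:
                    span = b - a
                    apex = np.clip(cfg.murmur_peak_frac, 0.05, 0.95)
                    pos = np.linspace(0.0, 1.0, span)
                    ramp = np.where(pos <= apex, pos / apex, (1.0 - pos) / (1.0 - apex))
                    profile[a:b] = np.maximum(profile[a:b], ramp)
            elif cfg.murmur == "diastolic_decrescendo":
                a = s2_iv[k][1]
                b = r_peaks[k + 1] if k + 1 < len(r_peaks) else n
                if b - a > 4:
                    span = b - a
                    tau = span / 3.0
                    profile[a:b] = np.maximum(profile[a:b], np.exp(-np.arange(span) / tau))
            else:
                raise ValidationError(f"unknown murmur kind {cfg.murmur!r}")
        murmur = raw * profile
        # Scale murmur RMS (over its support) to murmur_ratio x S1 RMS.
        s1_mask = np.zeros(n, dtype=bool)
        for a, b in s1_iv:
            s1_mask[a:b] = True
        s1_rms = np.sqrt(np.mean(pcg[s1_mask] ** 2))
        support = profile > 0.05
        m_rms = np.sqrt(np.mean(murmur[support] ** 2)) if support.any() else 0.0
        if m_rms > 0:
            pcg += murmur * (cfg.murmur_ratio * s1_rms / m_rms)

    # Broadband observation noise at the requested SNR.
    sig_rms = np.sqrt(np.mean(pcg**2))
    if np.isfinite(cfg.noise_snr_db) and sig_rms > 0:
        noise_rms = sig_rms * 10.0 ** (-cfg.noise_snr_db / 20.0)
        pcg = pcg + noise_rms * rng.standard_normal(n)

    truth = GroundTruth(
        r_peaks=np.asarray(r_peaks, dtype=np.int64),
        t_ends=np.asarray(t_ends, dtype=np.int64),
        s1=np.asarray(s1_iv, dtype=np.int64),
        s2=np.asarray(s2_iv, dtype=np.int64),
        fs=fs,
    )
    return (
        Waveform(pcg, fs=fs, label="pcg"),
        Waveform(ecg, fs=fs, label="ecg"),
        truth,
    )
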