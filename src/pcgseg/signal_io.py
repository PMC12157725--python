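"""Reading, writing and resampling of PCG/ECG recordings and ECG annotations.

Recordings arrive as WAV files, one/two-column plain-text dumps, or minimal
PhysioNet-style WFDB header+signal pairs. Everything downstream of this module
works on :class:`Waveform` at a uniform working rate (1000 Hz by default);
windows elsewhere in the pipeline are expressed in milliseconds and converted
through ``fs``, so other rates remain legal.

Sample indexing is 0-based and every interval in the package is half-open
``[start, end)``.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

WORKING_FS = 1000.0
MIN_DURATION_S = 2.0


class ValidationError(ValueError):
    """Input violates a documented contract (distinct from I/O failures)."""


@dataclass(frozen=True)
class Waveform:
    """A uniformly sampled single-channel signal.

    Parameters
    ----------
    samples:
        Signal values in arbitrary units.
    fs:
        Sampling rate in Hz, > 0.
    label:
        Free text, conventionally ``"pcg"`` or ``"ecg"``.
    """

    samples: np.ndarray
    fs: float
    label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise ValidationError("Waveform requires a single channel (1-D samples)")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(samples)):
            raise ValidationError("Waveform contains NaN or Inf samples")
        if samples.size < MIN_DURATION_S * self.fs:
            raise ValidationError(
                f"recording lasts {samples.size / self.fs:.3f} s; only signals "
                f"lasting at least {MIN_DURATION_S:g} s are accepted"
            )

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class EcgAnnotations:
    """R-peak and T-wave-end sample indices used as the timing reference."""

    r_peaks: np.ndarray
    t_ends: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        r = np.asarray(self.r_peaks, dtype=np.int64)
        t = np.asarray(self.t_ends, dtype=np.int64)
        object.__setattr__(self, "r_peaks", r)
        object.__setattr__(self, "t_ends", t)
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        for name, idx in (("r_peaks", r), ("t_ends", t)):
            if idx.size and np.any(np.diff(idx) <= 0):
                raise ValidationError(f"{name} must be strictly increasing")
            if idx.size and idx[0] < 0:
                raise ValidationError(f"{name} contains negative indices")
        # Each T-end must fall strictly inside an RR interval (after its own
        # R-peak, before the next), with at most one T-end per interval.
        if r.size and t.size:
            pos = np.searchsorted(r, t, side="left")
            if np.any(pos == 0):
                bad = t[pos == 0][0]
                raise ValidationError(
                    f"t_end at sample {bad} precedes the first R-peak at {r[0]}"
                )
            if np.any(np.isin(t, r)):
                raise ValidationError("t_end coincides with an R-peak")
            if np.unique(pos).size != pos.size:
                raise ValidationError("multiple t_ends within one RR interval")

    @property
    def n_beats(self) -> int:
        return int(self.r_peaks.size)


def _parse_text(path: Path) -> Waveform:
    """Parse a 1- or 2-column whitespace/comma-separated text dump.

    The dialect is sniffed from the first data line; header lines whose first
    token is not numeric are skipped. A leading time column, when present,
    fixes the sampling rate from its median spacing.
    """
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            tokens = line.replace(",", " ").split()
            try:
                values = [float(tok) for tok in tokens]
            except ValueError:
                if rows:
                    raise ValidationError(
                        f"non-numeric line inside data block of {path}"
                    )
                continue  # header
            rows.append(values)
    if not rows:
        raise ValidationError(f"no numeric data found in {path}")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ValidationError(f"ragged rows in {path}")
    data = np.asarray(rows, dtype=float)
    if ncol == 1:
        return Waveform(data[:, 0], fs=WORKING_FS, label="pcg")
    if ncol == 2:
        dt = np.diff(data[:, 0])
        if np.any(dt <= 0):
            raise ValidationError(f"time column in {path} is not increasing")
        fs = 1.0 / float(np.median(dt))
        return Waveform(data[:, 1], fs=fs, label="pcg")
    raise ValidationError(
        f"{path} has {ncol} columns; expected 1 (values) or 2 (time, values)"
    )


def _parse_wav(path: Path, channel: int) -> Waveform:
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:
        data = data[:, channel]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return Waveform(data.astype(float), fs=float(fs), label="pcg")


def _parse_wfdb(path: Path, channel: int) -> Waveform:
    """Minimal reader for WFDB header+signal pairs (formats 16 and 32 only)."""
    hea = path if path.suffix == ".hea" else path.with_suffix(".hea")
    if not hea.exists():
        raise FileNotFoundError(hea)
    with open(hea) as fh:
        lines = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    head = lines[0].split()
    nsig = int(head[1])
    fs = float(head[2].split("/")[0]) if len(head) > 2 else 250.0
    sig_lines = lines[1 : 1 + nsig]
    fname = sig_lines[0].split()[0]
    fmt = sig_lines[channel].split()[1].split("+")[0].split(":")[0]
    gain_field = sig_lines[channel].split()[2] if len(sig_lines[channel].split()) > 2 else "200"
    gain = float(gain_field.split("(")[0].split("/")[0]) or 200.0
    dtype = {"16": "<i2", "32": "<i4"}.get(fmt)
    if dtype is None:
        raise ValidationError(f"unsupported WFDB signal format {fmt!r} (only 16/32)")
    raw = np.fromfile(hea.parent / fname, dtype=dtype)
    data = raw.reshape(-1, nsig)[:, channel].astype(float) / gain
    return Waveform(data, fs=fs, label="pcg")


def read_recording(path: str | Path, kind: str = "text", channel: int = 0) -> Waveform:
    """Read a PCG or ECG recording at its native rate.

    Parameters
    ----------
    path:
        File to read. For ``kind="wfdb"`` either the ``.hea`` file or the
        record base name.
    kind:
        ``"wav"``, ``"text"`` or ``"wfdb"``.
    channel:
        Channel index for multi-channel inputs.
    """
    path = Path(path)
    if kind not in ("wav", "text", "wfdb"):
        raise ValueError(f"unknown recording kind {kind!r}")
    if kind != "wfdb" and not path.exists():
        raise FileNotFoundError(path)
    if kind == "wav":
        return _parse_wav(path, channel)
    if kind == "wfdb":
        return _parse_wfdb(path, channel)
    return _parse_text(path)


def write_recording(w: Waveform, path: str | Path) -> None:
    """Write a waveform as a two-column ``time value`` text file."""
    t = np.arange(len(w)) / w.fs
    np.savetxt(path, np.column_stack([t, w.samples]), fmt="%.9g")


def resample(w: Waveform, target_fs: float) -> Waveform:
    """Resample to ``target_fs`` with polyphase anti-aliasing filtering.

    Identical rates are a bit-exact pass-through.
    """
    if not target_fs > 0:
        raise ValidationError(f"target_fs must be positive, got {target_fs}")
    if target_fs == w.fs:
        return w
    ratio = Fraction(target_fs) / Fraction(w.fs)
    ratio = ratio.limit_denominator(10_000)
    out = resample_poly(w.samples, ratio.numerator, ratio.denominator)
    return Waveform(out, fs=float(target_fs), label=w.label)


def read_annotations(path: str | Path) -> EcgAnnotations:
    """Read annotations from CSV (header ``index,type,fs``) or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            obj = json.load(fh)
        return EcgAnnotations(
            r_peaks=np.asarray(obj["r_peaks"], dtype=np.int64),
            t_ends=np.asarray(obj["t_ends"], dtype=np.int64),
            fs=float(obj["fs"]),
        )
    r_peaks: list[int] = []
    t_ends: list[int] = []
    fs = None
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            fs = float(row["fs"])
            if row["type"] == "r_peak":
                r_peaks.append(int(row["index"]))
            elif row["type"] == "t_end":
                t_ends.append(int(row["index"]))
            else:
                raise ValidationError(f"unknown annotation type {row['type']!r}")
    if fs is None:
        fs = WORKING_FS
    return EcgAnnotations(np.asarray(r_peaks), np.asarray(t_ends), fs=fs)


def write_annotations(a: EcgAnnotations, path: str | Path) -> None:
    """Write annotations; format chosen by extension (.json or .csv)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(
                {
                    "r_peaks": [int(i) for i in a.r_peaks],
                    "t_ends": [int(i) for i in a.t_ends],
                    "fs": a.fs,
                },
                fh,
                indent=1,
            )
        return
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "type", "fs"])
        events = [(int(i), "r_peak") for i in a.r_peaks]
        events += [(int(i), "t_end") for i in a.t_ends]
        for idx, typ in sorted(events):
            writer.writerow([idx, typ, f"{a.fs:g}"])
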