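"""Four-state hidden semi-Markov model of the cardiac cycle.

The cycle is modelled as the fixed loop S1 -> systole -> S2 -> diastole -> S1
with explicit Gaussian state-duration distributions, so the only free
structure is how long each phase lasts and how likely each frame's features
are under each state. Frame features (50 Hz by default) are

* the smoothed Hilbert envelope of the band-passed PCG,
* the kurtosis of that envelope over a 0.2 s sliding window hopped at 1 ms
  (an impulsiveness measure that spikes at the transient heart sounds), and
* the envelope of the zero-frequency-filtered signal, which emphasizes
  impulse-like events while suppressing oscillatory murmur energy.

Training is fully supervised from ECG-derived frame labels: duration
Gaussians are the sample statistics of labelled state runs, emissions are
one-vs-rest logistic posteriors over standardized features, and systole /
diastole duration means are re-scaled at decode time by the recording's own
RR interval so the model transfers across heart rates.

Decoding is a duration-aware Viterbi pass: for every frame and state it
maximizes over admissible run lengths (mean +/- 3 SD, truncated runs allowed
at the record edges), which forbids the geometric dwell times of a plain HMM.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
from scipy import signal as sp_signal
from scipy.signal import hilbert
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression

from pcgseg.signal_io import ValidationError, Waveform

log = logging.getLogger(__name__)

FEATURE_NAMES = ("hilbert_env", "kurtosis", "zff_env")
DEFAULT_FRAME_RATE = 50.0
DUR_SD_SPAN = 3.0  # duration support = mean +/- 3 SD (frames)


class StateLabel(IntEnum):
    S1 = 0
    SYSTOLE = 1
    S2 = 2
    DIASTOLE = 3

    @property
    def next(self) -> "StateLabel":
        return StateLabel((self + 1) % 4)


N_STATES = len(StateLabel)


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def _moving_average(x: np.ndarray, win: int) -> np.ndarray:
    win = max(1, int(win))
    return np.convolve(x, np.ones(win) / win, mode="same")


def _sliding_kurtosis(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    """Pearson kurtosis (m4/m2^2) of ``x`` over sliding windows via cumsums.

    Returns a full-length trace: window values sit at window centers and the
    edges hold the nearest computed value.
    """
    n = len(x)
    if n < win:
        raise ValidationError(f"signal ({n} samples) shorter than kurtosis window ({win})")
    starts = np.arange(0, n - win + 1, hop)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x**2)])
    c3 = np.concatenate([[0.0], np.cumsum(x**3)])
    c4 = np.concatenate([[0.0], np.cumsum(x**4)])
    ends = starts + win
    s1 = (c1[ends] - c1[starts]) / win
    s2 = (c2[ends] - c2[starts]) / win
    s3 = (c3[ends] - c3[starts]) / win
    s4 = (c4[ends] - c4[starts]) / win
    m2 = s2 - s1**2
    m4 = s4 - 4 * s1 * s3 + 6 * s1**2 * s2 - 3 * s1**4
    with np.errstate(divide="ignore", invalid="ignore"):
        kurt = np.where(m2 > 1e-18, m4 / np.maximum(m2, 1e-18) ** 2, 3.0)
    centers = starts + win // 2
    full = np.empty(n)
    full[: centers[0] + 1] = kurt[0]
    full[centers[-1] :] = kurt[-1]
    full[centers[0] : centers[-1] + 1] = np.interp(
        np.arange(centers[0], centers[-1] + 1), centers, kurt
    )
    return full


def zero_frequency_filter(x: np.ndarray, fs: float, trend_win_ms: float = 122.0) -> np.ndarray:
    """Zero-frequency filtering: two cascaded running-sum integrators followed
    by (repeated) sliding-mean trend removal.

    The trend-removal window defaults to the mean S1 duration so that
    impulse-like events at heart-sound scale survive while the polynomial
    drift introduced by the integrators is cancelled.
    """
    win = max(3, int(round(trend_win_ms / 1000.0 * fs)))
    y = x - np.mean(x)
    y = np.cumsum(y)
    y = np.cumsum(y)
    for _ in range(3):  # repeated mean subtraction kills the residual drift
        y = y - _moving_average(y, win)
    return y


@dataclass(frozen=True)
class FrameFeatures:
    """Per-frame feature matrix for the HSMM (raw, unstandardized)."""

    values: np.ndarray  # (n_frames, n_features)
    frame_rate: float
    fs: float  # signal sampling rate the frames were derived from
    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if not np.all(np.isfinite(v)):
            raise ValidationError("FrameFeatures contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def hop(self) -> int:
        """Samples per frame at the originating signal rate."""
        return int(round(self.fs / self.frame_rate))


def extract_features(
    pcg: Waveform,
    frame_rate: float = DEFAULT_FRAME_RATE,
    kurtosis_win_ms: float = 200.0,
    kurtosis_hop_ms: float = 1.0,
    zff_trend_ms: float = 122.0,
) -> FrameFeatures:
    """Compute the three frame features from a preprocessed PCG."""
    fs = pcg.fs
    x = pcg.samples
    hop = int(round(fs / frame_rate))
    n_frames = len(x) // hop
    if n_frames < 2:
        raise ValidationError("signal too short for feature framing")

    env = np.abs(hilbert(x))
    # Smooth below the frame Nyquist before decimating to the frame grid.
    cutoff = 0.4 * frame_rate
    sos = sp_signal.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    env_smooth = np.maximum(sp_signal.sosfiltfilt(sos, env), 0.0)

    kwin = int(round(kurtosis_win_ms / 1000.0 * fs))
    khop = max(1, int(round(kurtosis_hop_ms / 1000.0 * fs)))
    kurt = _sliding_kurtosis(env, kwin, khop)

    zff = zero_frequency_filter(x, fs, zff_trend_ms)
    zff_env = np.abs(hilbert(zff))
    zff_env = np.maximum(sp_signal.sosfiltfilt(sos, zff_env), 0.0)

    def frame_mean(tr: np.ndarray) -> np.ndarray:
        return tr[: n_frames * hop].reshape(n_frames, hop).mean(axis=1)

    values = np.column_stack([frame_mean(env_smooth), frame_mean(kurt), frame_mean(zff_env)])
    return FrameFeatures(values=values, frame_rate=frame_rate, fs=fs)


# ---------------------------------------------------------------------------
# Supervised labels from ECG annotations
# ---------------------------------------------------------------------------

def label_frames(
    ann,
    n_frames: int,
    frame_rate: float = DEFAULT_FRAME_RATE,
    s1_win_ms: float = 122.0,
    s2_win_ms: float = 92.0,
) -> np.ndarray:
    """Build a per-frame state path from R-peak / T-end annotations.

    S1 occupies ``[R, R + s1_win_ms)``; S2 is centered on the T-end with width
    ``s2_win_ms``; systole fills the gap between them and diastole everything
    else. Beats whose S1 and S2 windows would overlap are skipped.
    """
    r_frames = np.round(np.asarray(ann.r_peaks) / ann.fs * frame_rate).astype(int)
    t_frames = np.round(np.asarray(ann.t_ends) / ann.fs * frame_rate).astype(int)
    if r_frames.size < 2:
        raise ValidationError("need at least 2 beats to label frames")
    frame_ms = 1000.0 / frame_rate
    s1_len = max(1, int(round(s1_win_ms / frame_ms)))
    s2_len = max(1, int(round(s2_win_ms / frame_ms)))

    labels = np.full(n_frames, int(StateLabel.DIASTOLE), dtype=int)
    # Pair each R with the first T-end before the next R.
    for i, r in enumerate(r_frames):
        nxt = r_frames[i + 1] if i + 1 < r_frames.size else n_frames
        cand = t_frames[(t_frames > r) & (t_frames < nxt)]
        if cand.size == 0:
            continue
        te = int(cand[0])
        s1_a, s1_b = r, r + s1_len
        s2_a = int(round(te - s2_win_ms / 2.0 / frame_ms))
        s2_b = s2_a + s2_len
        if s1_b > s2_a:
            log.warning("beat at frame %d skipped: S1/S2 label windows overlap", r)
            continue
        s2_b = min(s2_b, nxt if nxt < n_frames else n_frames)
        if s1_a < 0 or s2_b > n_frames:
            continue
        labels[s1_a:s1_b] = int(StateLabel.S1)
        labels[s1_b:s2_a] = int(StateLabel.SYSTOLE)
        labels[s2_a:s2_b] = int(StateLabel.S2)
    return labels


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class HsmmModel:
    """Trained four-state heart-sound HSMM.

    Duration parameters are in frames; ``rr_train_frames`` is the mean cardiac
    cycle length of the training corpus, against which systole/diastole
    duration means (and SDs, proportionally) are re-scaled at decode time.
    ``s12_mu``/``s12_sigma`` (seconds) form the reference Gaussian of the
    S1-to-S2 interval used by the S2 relocation stage.
    """

    dur_mean: np.ndarray  # (4,) frames
    dur_sd: np.ndarray  # (4,) frames
    feat_mean: np.ndarray  # (n_features,)
    feat_sd: np.ndarray  # (n_features,)
    frame_rate: float
    rr_train_frames: float
    s12_mu: float
    s12_sigma: float
    emission_kind: str = "logistic"
    # logistic: per-state weight vectors (4, n_features) and intercepts (4,)
    emis_weights: np.ndarray | None = None
    emis_intercepts: np.ndarray | None = None
    # gaussian fallback: per-state mean/var (4, n_features)
    emis_mu: np.ndarray | None = None
    emis_var: np.ndarray | None = None
    state_priors: np.ndarray | None = None
    feature_names: tuple[str, ...] = FEATURE_NAMES
    version: str = "pcgseg-hsmm-1"

    # -- serialization ------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        obj = {
            "version": self.version,
            "frame_rate": self.frame_rate,
            "feature_names": list(self.feature_names),
            "dur_mean": self.dur_mean.tolist(),
            "dur_sd": self.dur_sd.tolist(),
            "feat_mean": self.feat_mean.tolist(),
            "feat_sd": self.feat_sd.tolist(),
            "rr_train_frames": self.rr_train_frames,
            "s12_mu": self.s12_mu,
            "s12_sigma": self.s12_sigma,
            "emission_kind": self.emission_kind,
            "emis_weights": None if self.emis_weights is None else self.emis_weights.tolist(),
            "emis_intercepts": None if self.emis_intercepts is None else self.emis_intercepts.tolist(),
            "emis_mu": None if self.emis_mu is None else self.emis_mu.tolist(),
            "emis_var": None if self.emis_var is None else self.emis_var.tolist(),
            "state_priors": None if self.state_priors is None else self.state_priors.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "HsmmModel":
        with open(path) as fh:
            obj = json.load(fh)

        def arr(key):
            return None if obj[key] is None else np.asarray(obj[key], dtype=float)

        return cls(
            dur_mean=np.asarray(obj["dur_mean"], dtype=float),
            dur_sd=np.asarray(obj["dur_sd"], dtype=float),
            feat_mean=np.asarray(obj["feat_mean"], dtype=float),
            feat_sd=np.asarray(obj["feat_sd"], dtype=float),
            frame_rate=float(obj["frame_rate"]),
            rr_train_frames=float(obj["rr_train_frames"]),
            s12_mu=float(obj["s12_mu"]),
            s12_sigma=float(obj["s12_sigma"]),
            emission_kind=obj["emission_kind"],
            emis_weights=arr("emis_weights"),
            emis_intercepts=arr("emis_intercepts"),
            emis_mu=arr("emis_mu"),
            emis_var=arr("emis_var"),
            state_priors=arr("state_priors"),
            feature_names=tuple(obj["feature_names"]),
            version=obj["version"],
        )

    # -- emission posteriors ------------------------------------------------
    def standardize(self, values: np.ndarray) -> np.ndarray:
        sd = np.where(self.feat_sd > 0, self.feat_sd, 1.0)
        return (values - self.feat_mean) / sd

    def emission_posteriors(self, values: np.ndarray) -> np.ndarray:
        """Per-frame state posteriors (rows sum to 1) from raw feature rows."""
        z = self.standardize(values)
        if self.emission_kind == "logistic":
            scores = z @ self.emis_weights.T + self.emis_intercepts
            p = 1.0 / (1.0 + np.exp(-np.clip(scores, -500, 500)))
            p = np.clip(p, 1e-12, 1.0)
        elif self.emission_kind == "gaussian":
            var = np.maximum(self.emis_var, 1e-12)
            loglik = -0.5 * (
                ((z[:, None, :] - self.emis_mu[None]) ** 2 / var[None]).sum(-1)
                + np.log(var).sum(-1)
            )
            loglik += np.log(np.maximum(self.state_priors, 1e-12))
            loglik -= loglik.max(axis=1, keepdims=True)
            p = np.exp(loglik)
        else:
            raise ValueError(f"unknown emission kind {self.emission_kind!r}")
        return p / p.sum(axis=1, keepdims=True)


def train(
    recordings: list[tuple[FrameFeatures, np.ndarray]],
    emission: str = "logistic",
) -> HsmmModel:
    """Fit the HSMM from labelled recordings.

    Duration Gaussians are the sample mean/SD of labelled state run lengths
    (edge-truncated first/last runs excluded). Emissions are one-vs-rest
    logistic posteriors over standardized features. Training is deterministic:
    closed-form sufficient statistics plus a convex logistic fit initialized
    at zero.
    """
    if not recordings:
        raise ValidationError("need at least one labelled recording")
    frame_rate = recordings[0][0].frame_rate

    all_feats = np.vstack([f.values for f, _ in recordings])
    all_labels = np.concatenate([np.asarray(lab, dtype=int) for _, lab in recordings])
    if all_feats.shape[0] != all_labels.shape[0]:
        raise ValidationError("features and labels disagree in frame count")

    feat_mean = all_feats.mean(axis=0)
    feat_sd = all_feats.std(axis=0)

    run_lengths: dict[int, list[int]] = {int(s): [] for s in StateLabel}
    s12_list: list[float] = []
    rr_list: list[float] = []
    for _, labels in recordings:
        labels = np.asarray(labels, dtype=int)
        change = np.flatnonzero(np.diff(labels)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [labels.size]])
        # exclude edge-truncated first and last runs
        for a, b in zip(starts[1:-1], ends[1:-1]):
            run_lengths[int(labels[a])].append(int(b - a))
        s1_starts = [a for a, b in zip(starts, ends) if labels[a] == StateLabel.S1]
        s2_starts = [a for a, b in zip(starts, ends) if labels[a] == StateLabel.S2]
        for a in s1_starts:
            later = [c for c in s2_starts if c > a]
            nxt_s1 = [c for c in s1_starts if c > a]
            if later and (not nxt_s1 or later[0] < nxt_s1[0]):
                s12_list.append((later[0] - a) / frame_rate)
        rr_list.extend(np.diff(s1_starts) / frame_rate)

    dur_mean = np.zeros(N_STATES)
    dur_sd = np.zeros(N_STATES)
    for s in StateLabel:
        runs = run_lengths[int(s)]
        if not runs:
            raise ValidationError(f"state {s.name} never observed in the training labels")
        dur_mean[s] = float(np.mean(runs))
        dur_sd[s] = float(np.std(runs, ddof=1)) if len(runs) > 1 else 1.0
        dur_sd[s] = max(dur_sd[s], 0.5)  # floor: degenerate SDs break the support

    priors = np.array([(all_labels == int(s)).mean() for s in StateLabel])

    model = HsmmModel(
        dur_mean=dur_mean,
        dur_sd=dur_sd,
        feat_mean=feat_mean,
        feat_sd=feat_sd,
        frame_rate=frame_rate,
        rr_train_frames=float(np.mean(rr_list) * frame_rate) if rr_list else float("nan"),
        s12_mu=float(np.mean(s12_list)) if s12_list else float("nan"),
        s12_sigma=float(np.std(s12_list, ddof=1)) if len(s12_list) > 1 else 0.0,
        emission_kind=emission,
        state_priors=priors,
    )

    z = model.standardize(all_feats)
    if emission == "logistic":
        weights = np.zeros((N_STATES, all_feats.shape[1]))
        intercepts = np.zeros(N_STATES)
        # Regularization scaled so the per-average-loss penalty is constant:
        # training is then exactly invariant under duplicating a recording.
        C = 5000.0 / all_feats.shape[0]
        for s in StateLabel:
            y = (all_labels == int(s)).astype(int)
            clf = LogisticRegression(C=C, solver="lbfgs", max_iter=2000, tol=1e-10)
            clf.fit(z, y)
            weights[s] = clf.coef_[0]
            intercepts[s] = clf.intercept_[0]
        model.emis_weights = weights
        model.emis_intercepts = intercepts
    elif emission == "gaussian":
        mu = np.zeros((N_STATES, all_feats.shape[1]))
        var = np.zeros((N_STATES, all_feats.shape[1]))
        for s in StateLabel:
            rows = z[all_labels == int(s)]
            mu[s] = rows.mean(axis=0)
            var[s] = rows.var(axis=0) + 1e-6
        model.emis_mu = mu
        model.emis_var = var
    else:
        raise ValueError(f"unknown emission kind {emission!r}")
    return model


# ---------------------------------------------------------------------------
# Segmentation container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Beat:
    """One cardiac cycle's S1 and S2 intervals, half-open in samples."""

    s1: tuple[int, int]
    s2: tuple[int, int]

    def __post_init__(self) -> None:
        if not (self.s1[0] < self.s1[1] <= self.s2[0] < self.s2[1]):
            raise ValidationError(f"beat intervals out of order: {self.s1}, {self.s2}")


@dataclass(frozen=True)
class Segmentation:
    """Frame-level state path plus per-beat S1/S2 sample intervals."""

    states: np.ndarray  # (n_frames,) ints
    beats: tuple[Beat, ...]
    fs: float
    frame_hop: int  # samples per frame

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", np.asarray(self.states, dtype=int))
        object.__setattr__(self, "beats", tuple(self.beats))
        prev_end = -1
        for b in self.beats:
            if b.s1[0] <= prev_end:
                raise ValidationError("beats overlap or are unordered")
            prev_end = b.s2[1] - 1

    @classmethod
    def from_states(cls, states: np.ndarray, fs: float, frame_hop: int) -> "Segmentation":
        states = np.asarray(states, dtype=int)
        change = np.flatnonzero(np.diff(states)) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [states.size]])
        runs = [(int(states[a]), int(a), int(b)) for a, b in zip(starts, ends)]
        beats: list[Beat] = []
        pending_s1: tuple[int, int] | None = None
        for s, a, b in runs:
            if s == StateLabel.S1:
                pending_s1 = (a * frame_hop, b * frame_hop)
            elif s == StateLabel.S2 and pending_s1 is not None:
                beats.append(Beat(s1=pending_s1, s2=(a * frame_hop, b * frame_hop)))
                pending_s1 = None
        return cls(states=states, beats=tuple(beats), fs=fs, frame_hop=frame_hop)

    def replace_beats(self, beats: list[Beat]) -> "Segmentation":
        return Segmentation(states=self.states, beats=tuple(beats), fs=self.fs, frame_hop=self.frame_hop)


# ---------------------------------------------------------------------------
# Duration-aware Viterbi
# ---------------------------------------------------------------------------

def duration_support(mean: float, sd: float, span: float = DUR_SD_SPAN) -> tuple[int, int]:
    """Admissible interior run lengths: ``[mean - span*SD, mean + span*SD]``
    in frames, floored at 1."""
    lo = max(1, int(round(mean - span * sd)))
    hi = max(lo, int(round(mean + span * sd)))
    return lo, hi


def viterbi_decode(
    log_emit: np.ndarray,
    dur_mean: np.ndarray,
    dur_sd: np.ndarray,
    span: float = DUR_SD_SPAN,
) -> tuple[np.ndarray, float]:
    """Maximum-scoring cyclic state path under explicit duration scoring.

    ``log_emit`` is (n_frames, 4). Every run of state ``s`` with length ``d``
    contributes ``Normal(d; mean_s, sd_s).logpdf`` plus its frames' emission
    scores; interior runs are constrained to the truncated support while the
    first and last runs may be cut short by the record edges (any length from
    1 up to the support maximum). Returns the path and its score.
    """
    T = log_emit.shape[0]
    if T == 0:
        raise ValidationError("empty emission matrix")
    supports = [duration_support(dur_mean[s], dur_sd[s], span) for s in range(N_STATES)]
    cum = np.vstack([np.zeros(N_STATES), np.cumsum(log_emit, axis=0)])  # (T+1, 4)

    def dur_logpdf(s: int, d) -> np.ndarray:
        return norm.logpdf(np.asarray(d, dtype=float), dur_mean[s], max(dur_sd[s], 1e-6))

    NEG = -np.inf
    delta = np.full((T, N_STATES), NEG)
    back = np.full((T, N_STATES), -1, dtype=int)  # chosen duration; -1 = prefix run

    for t in range(T):
        for s in range(N_STATES):
            lo, hi = supports[s]
            best = NEG
            best_d = -2
            # run covering the whole prefix (possibly truncated from the left)
            d = t + 1
            if d <= hi:
                cand = float(dur_logpdf(s, d)) + (cum[t + 1, s] - cum[0, s])
                if cand > best:
                    best, best_d = cand, -1
            # interior run preceded by the cyclic predecessor state
            prev = (s - 1) % N_STATES
            dlo, dhi = lo, min(hi, t)
            if dlo <= dhi:
                ds = np.arange(dlo, dhi + 1)
                cands = (
                    delta[t - ds, prev]
                    + dur_logpdf(s, ds)
                    + (cum[t + 1, s] - cum[t + 1 - ds, s])
                )
                k = int(np.argmax(cands))
                if cands[k] > best:
                    best, best_d = float(cands[k]), int(ds[k])
            delta[t, s] = best
            back[t, s] = best_d

    # Final (possibly right-truncated) run.
    best_score = NEG
    best_sd: tuple[int, int] | None = None
    for s in range(N_STATES):
        hi = supports[s][1]
        prev = (s - 1) % N_STATES
        for d in range(1, min(hi, T) + 1):
            start = T - d
            em = cum[T, s] - cum[start, s]
            if start == 0:
                cand = float(dur_logpdf(s, d)) + em
            else:
                if not np.isfinite(delta[start - 1, prev]):
                    continue
                cand = delta[start - 1, prev] + float(dur_logpdf(s, d)) + em
            if cand > best_score:
                best_score = cand
                best_sd = (s, d)
    if best_sd is None or not np.isfinite(best_score):
        raise ValidationError("duration constraints unsatisfiable")

    # Backtrack.
    path = np.empty(T, dtype=int)
    s, d = best_sd
    t = T - 1
    path[t - d + 1 : t + 1] = s
    t -= d
    while t >= 0:
        s = (s - 1) % N_STATES
        d = back[t, s]
        if d == -1:
            path[: t + 1] = s
            break
        path[t - d + 1 : t + 1] = s
        t -= d
    return path, float(best_score)


def estimate_rr(feats: FrameFeatures, lag_range_s: tuple[float, float] = (0.3, 2.0)) -> float:
    """Heart period estimate (seconds) from the autocorrelation peak of the
    summed, per-column-standardized envelope features."""
    v = feats.values
    z = (v - v.mean(axis=0)) / np.where(v.std(axis=0) > 0, v.std(axis=0), 1.0)
    x = z.sum(axis=1)
    x = x - x.mean()
    ac = np.correlate(x, x, mode="full")[x.size - 1 :]
    lo = max(1, int(round(lag_range_s[0] * feats.frame_rate)))
    hi = min(ac.size - 1, int(round(lag_range_s[1] * feats.frame_rate)))
    if hi <= lo:
        raise ValidationError("record too short for RR estimation")
    lag = lo + int(np.argmax(ac[lo : hi + 1]))
    return lag / feats.frame_rate


def decode(
    model: HsmmModel,
    feats: FrameFeatures,
    rr_estimate_s: float | None = None,
) -> Segmentation:
    """Decode a recording into its maximum-a-posteriori segmentation."""
    if tuple(feats.names) != tuple(model.feature_names):
        raise ValidationError(
            f"feature names {feats.names} do not match the model's {model.feature_names}"
        )
    if rr_estimate_s is None:
        rr_estimate_s = estimate_rr(feats)
    post = model.emission_posteriors(feats.values)
    priors = model.state_priors if model.state_priors is not None else np.full(N_STATES, 0.25)
    log_emit = np.log(np.clip(post, 1e-12, 1.0)) - np.log(np.clip(priors, 1e-12, 1.0))

    dur_mean = model.dur_mean.copy()
    dur_sd = model.dur_sd.copy()
    if np.isfinite(model.rr_train_frames) and model.rr_train_frames > 0:
        rr_frames = rr_estimate_s * model.frame_rate
        factor = float(np.clip(rr_frames / model.rr_train_frames, 0.5, 2.0))
        for s in (StateLabel.SYSTOLE, StateLabel.DIASTOLE):
            dur_mean[s] *= factor
            dur_sd[s] *= factor

    path, _ = viterbi_decode(log_emit, dur_mean, dur_sd)
    return Segmentation.from_states(path, fs=feats.fs, frame_hop=feats.hop)
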