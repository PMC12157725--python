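# Methods

This note records the model, the numerical choices, and the design decisions
behind `pcgseg`, including what the synthetic data generator does and does
not emulate.

## Signal model and preprocessing

All processing runs at a working rate of 1000 Hz; recordings at other rates
are resampled with polyphase anti-aliasing filtering. Window lengths
throughout are specified in milliseconds and converted through the sampling
rate, so other working rates remain legal. Sample indexing is 0-based and
every interval is half-open `[start, end)`.

The PCG is band-passed 40–450 Hz with a third-order Chebyshev type-I filter
(1 dB passband ripple — the type and ripple are fixed here for
reproducibility and exposed in the config) and normalized to unit peak
amplitude. The ECG is band-passed 0.5–100 Hz (second-order Butterworth) with
IIR notches at the mains frequency and its harmonics below the upper band
edge (default 50 Hz, quality factor 30; configurable to 60 Hz). Every filter
is applied forward–backward: S1/S2 *timing* is the measurand, and group
delay would bias the 100 ms evaluation windows.

## ECG reference annotations

R-peaks: Pan–Tompkins stages with the classic parameters (5–15 Hz band-pass,
differentiation, squaring, 150 ms moving-window integration), a 200 ms
refractory period, and a two-pass global threshold (seeded from the 98th
percentile of candidate heights, re-derived from the median of retained
candidates). Global thresholding keeps the detector translation-invariant,
which the annotation-equivariance property test relies on. Detections within
100 ms of the record edges are dropped.

T-wave ends: beats are ensemble-averaged into a template (window −100 ms to
min(0.9·RR, 600 ms) around the R-peak; at least 5 complete beats required).
On the template, the T extremum is sought 150–450 ms after R and the tangent
at the steepest terminal slope is extrapolated to the local baseline — the
TP-segment level measured 120–200 ms after the steepest point, because the
0.5 Hz high-pass leaves a residual offset there and assuming a zero isoline
biases the intersection early by ~15 ms. The template T-end offset is
transferred to each beat by cross-correlating the *T-wave region* only
(whole-beat correlation is QRS-dominated and blind to beat-to-beat
repolarization shifts); beats correlating below 0.8 get no T-end, which
keeps garbage labels out of training.

## The four-state heart-sound HSMM

States follow the fixed cycle S1 → systole → S2 → diastole. Features per
20 ms frame (50 Hz frame rate — chosen to keep state durations well resolved
at reasonable cost):

* **hilbert_env** — magnitude of the analytic signal, zero-phase low-passed
  below the frame Nyquist, mean per frame;
* **kurtosis** — Pearson kurtosis (m₄/m₂²) of the Hilbert envelope over a
  0.2 s window hopped at 1 ms (computed with sliding power sums), mean per
  frame. The 1 ms step is read as the hop of a sliding window; a 1 ms
  *overlap* of 0.2 s windows would leave the trace undersampled;
* **zff_env** — envelope of the zero-frequency-filtered signal: two cascaded
  running-sum integrators followed by repeated sliding-mean trend removal
  (window = 122 ms, the nominal S1 duration), then the analytic magnitude.
  The ZFF accentuates impulse-like events and suppresses oscillatory murmur
  energy.

**Training** is fully supervised from ECG labels: S1 = [R, R+122 ms), S2 =
92 ms centered on the T-end, systole between, diastole elsewhere (the
122/92 ms windows are the nominal mean S1/S2 durations; config-exposed).
Duration Gaussians are the sample mean/SD of interior labelled runs
(edge-truncated runs excluded), with an SD floor of 0.5 frames so a
degenerate corpus cannot collapse the Viterbi support. Emissions are
one-vs-rest logistic fits on standardized features, normalized to per-frame
posteriors; the regularization strength is scaled inversely with the number
of frames so training is exactly invariant under duplicating a recording. A
diagonal-Gaussian emission model is available behind the `hsmm.emission`
config switch. Training is deterministic (sufficient statistics plus a
convex fit initialized at zero).

**Decoding** maximizes path score = Σ frame log-emission (posterior over
prior) + Σ per-run Gaussian duration log-density. Interior runs are
constrained to mean ± 3 SD (floored at 1 frame); the first and last runs may
be cut short by the record edges (1 up to the support maximum). Ties resolve
to the shortest admissible duration, giving the earliest change-point. The
heart-rate conditioning rescales systole/diastole duration means and SDs by
the ratio of the decode-time RR estimate (autocorrelation peak of the summed
standardized features at lags 0.3–2 s) to the training-corpus mean RR,
clipped to [0.5, 2]. Correctness of the decoder is checked against
exhaustive enumeration of all legal cyclic segmentations on instances up to
60 frames.

## S1 onset refinement

Viola-integral envelope: sliding variance with half-window L_T = 0.5 × 0.1 ×
fs (50 samples at 1 kHz, i.e. half the nominal S1 duration), computed via
cumulative sums, edges reflect-padded so the output has signal length,
normalized to unit maximum. First-order average Shannon energy: the envelope
is scaled by 0.4 (avoiding the double-peak artefact at S1), transformed
per-sample with −x ln x (0 ln 0 := 0) — a *single* logarithm; a second
logarithm of an already-signed quantity is undefined — averaged over 20 ms
windows hopped at 10 ms, interpolated back to sample rate, and standardized
to zero mean / unit SD over the record.

For each decoded S1 interval, the anchor is the highest strictly-interior
*local* maximum of the ASE (fallback to the plain argmax when the trace is
monotone over the interval). This matters: with a loud systolic murmur the
ASE rises monotonically across the decoded S1 interval, and anchoring on a
boundary argmax drags onsets ~100 ms into the murmur. The onset moves to the
last sample at or below 70 % of the anchor value, searching only within the
interval (so a preceding diastolic murmur cannot capture it); if no such
sample exists, or the standardized peak is non-positive (a fraction of a
negative peak is meaningless), the boundaries are kept. The interval end
shifts symmetrically to preserve duration, and refined intervals are clipped
against the neighbouring S2s.

## S2 relocation

The S1-to-S2 interval (S12, S1 start to S2 start, seconds) of each beat is
tested against a reference Gaussian; |S12 − μ| > 1.96 σ (95 % CI,
configurable) flags the beat. The reference (μ, σ) is learned from the
training corpus labels and stored in the model file, keeping the test phase
ECG-free and deterministic; a recording-level reference (fit to the
recording's own beats) is available via `s2.reference=recording`.

For flagged beats, the second-order average Shannon energy of the normalized
band-passed PCG is computed per 20 ms window with 50 % overlap:
E′ = −(1/N) Σ x² ln x², mean-centered (ASE) and divided by max |ASE|
(absolute value, so the normalization is well defined when the maximum
deviation is negative). In the window from the current S2 start to the
center of the diastolic interval, candidate lobes are local maxima with
prominence ≥ 0.1 on the NASE scale (the floor suppresses noise
zero-crossings). With at least two candidates, the new S2 spans the final
lobe pair: from the left flank of the second-to-last lobe to the right flank
of the last. Flanks are the *nearest adjacent* local minima, found by
walking downhill from the peak until the derivative changes sign; taking the
deepest minimum between peaks instead would extend spans into quiet
diastole. With fewer than two lobes, or for the last beat of a record (no
diastolic endpoint), the beat is left untouched; relocated intervals are
clipped to end before the next S1. Unflagged beats are never modified.

The lobe-pair selection embodies the hypothesis that late diastolic energy
lobes represent S2 when valve closure is delayed; it is most accurate when
the last two lobes belong to S2 itself (its aortic and pulmonary
components). Against a single compact S2 burst, the pair necessarily spans
murmur tail + S2 and the relocated center lands early by about half their
separation — still inside the ±100 ms scoring window in the cohorts tested.

## Evaluation protocol

S1: detection start within [R, R+100 ms] (one-sided — S1 physiologically
follows the R-peak). S2: detection center within ±100 ms of the T-end
(two-sided). Matching is greedy by absolute offset with a one-to-one
constraint; the window is configurable (e.g. ±50/±75 ms sensitivity
analyses). Pooled cohort metrics are computed over summed counts, which is
also how the published group tables combine records. Undefined metrics
(zero denominators) are reported as NA, never as 0.

## Synthetic data generator

Emulates, per beat: an ECG of Gaussian P-QRS-T waves whose T-end is defined
at center + 2σ_T — exactly where the tangent method lands on a Gaussian
downslope, so the annotation chain can be validated against truth; S1
(90 ms, 60 Hz) starting 30 ms after R; S2 (70 ms, 85 Hz) centered on the
T-end, attenuable down to absence, optionally split into two sub-bursts
(A2–P2) and optionally delayed past the T-end (`s2_delay_ms`) — in severe
aortic stenosis the prolonged ejection delays aortic closure while the
murmur still decays at the *electrical* end of systole, which is exactly the
failure mode the S2 relocation addresses. Murmurs are 80–400 Hz band-passed
noise shaped by a diamond profile over systole (apex position configurable;
late-peaking in severe AS) or an exponential decrescendo over diastole,
scaled to a target murmur-to-S1 RMS ratio. Beat-to-beat variability:
Gaussian heart-rate jitter, Bazett-style sqrt(RR) scaling of the QT
interval plus 8 ms T-center jitter, and 5 ms timing jitter on the acoustic
S1/S2. Broadband noise is added at a configurable SNR. A seed fixes the
output bit-exactly.

Without the beat-level timing variability the label-derived duration SDs
collapse and the duration prior alone pins S2, making the murmur-capture
failure mode impossible; the jitter magnitudes above were chosen once as
physiologically plausible values and define the study conditions.

**What it does not emulate:** respiration (amplitude/split modulation), S3
and S4, ejection clicks, sensor and contact artefacts, non-Gaussian HRV
(extrasystoles, fibrillation), murmur spectra beyond shaped band-passed
noise. Passing tests on this generator therefore demonstrate the mechanics
of the method — training, duration-aware decoding, refinement triggering and
relocation geometry — not clinical-grade performance on real recordings.

## Study conditions used by the tests and the acceptance script

* Training corpus: five 30 s "subjects" at 62–80 bpm — two murmur-free, two
  with moderate systolic murmurs (ratio 0.3–0.5, S2 attenuated 3–6 dB), one
  with a diastolic murmur; mirrors a small mixed-pathology corpus.
* Clean evaluation: train on 3 murmur-free records, score 3 held-out ones.
* Severe-AS cohort: 20 recordings at 75 ± 5 bpm, diamond murmur ratio 1.0,
  S2 attenuated 15 dB and delayed 60 ms. The cohort compares the full
  pipeline to the `refine="none"` baseline.
* Recording length 30 s everywhere, which keeps the full suite and the
  acceptance script to a couple of minutes while providing ~35 beats per
  record.

## Known limitations

* The duration-aware Viterbi is exact but O(T · states · support width); a
  5-minute recording decodes in seconds at 50 Hz frames, but the
  implementation is not streaming.
* The S12 reference Gaussian is learned from training labels; if the
  training corpus's systolic timing differs grossly from the test
  population's, the flag rate will deviate from its nominal 5 %.
* The lobe-pair boundary mapping is one of several defensible readings (the
  relocation literature does not pin down how two lobes map to an interval);
  the nearest-adjacent-minima choice is documented above.
* WFDB support covers plain format-16/32 header+signal pairs only.
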