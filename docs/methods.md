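# Methods

`heartprint` implements a single-heartbeat ECG biometric recognition
pipeline: heartbeat segmentation anchored on fiducial points, a
continuous-wavelet-transform (CWT) scalogram image representation, a
compact residual convolutional classifier, and the identification /
verification evaluation protocol, together with a synthetic ECG
generator that makes the whole chain testable end to end without any
external data. This note records the models, the parameters that
matter, and the design decisions taken where the design was genuinely
open.

## Synthetic ECG model

Each heartbeat is the sum of five Gaussian bumps, one per characteristic
wave w ∈ {P, Q, R, S, T}:

    beat(t) = Σ_w a_w · exp( −(t − t_beat − θ_w)² / (2 b_w²) )

with subject-specific amplitudes `a_w` (mV), widths `b_w` (s), and
offsets `θ_w` (s, relative to the R apex at θ_R = 0). This is a
time-domain additive variant of the ECGSYN idea: rich enough to
reproduce per-subject invariant PQRST morphology and between-subject
morphological differences, while keeping closed-form ground truth — the
exact R and P bump centers are stored with every record, so detectors
can be scored exactly.

Population sampling ranges (uniform, per subject) target a healthy
resting adult on lead i:

| parameter | range | unit |
|---|---|---|
| a_P, a_Q, a_R, a_S, a_T | [0.05, 0.25], [−0.20, −0.05], [0.8, 1.6], [−0.35, −0.10], [0.10, 0.50] | mV |
| b_P, b_Q, b_R, b_S, b_T | [20, 35], [8, 16], [9, 14], [9, 18], [45, 75] | ms |
| θ_P, θ_Q, θ_S, θ_T | [−210, −130], [−45, −25], [25, 45], [220, 300] | ms |
| mean RR | [0.7, 1.1] | s |
| RR jitter SD | 0.04 | s |
| white-noise SD | [0.02, 0.05] | mV |
| wander amplitude / frequency | [0.05, 0.15] mV / [0.15, 0.40] Hz | |
| session drift SD | 0.08 | relative |

Structural invariants: θ_P < θ_Q < 0 < θ_S < θ_T, θ_R − θ_P ≤ 245 ms
(so every P lies inside the detector's search window), and
mean RR > 2 (θ_T − θ_P) so consecutive beats cannot overlap. When a
draw violates the overlap bound, the mean RR interval is raised just
above it rather than reshaping the waves — a slightly slower heart is
physiologically cheaper than a distorted beat. Beat times advance by
`max(0.4 s, RR + N(0, jitter))`; the 0.4 s floor prevents degenerate
overlap under jitter. Beat centers stop 0.2 s before the record end so
the final QRS is never clipped mid-complex.

Sessions are emulated by multiplying amplitudes by `1 + N(0, drift)`,
widths by half that spread, and jittering the non-R offsets by a few
milliseconds, re-drawing if an ordering invariant breaks. Noise is
white Gaussian plus one wander sinusoid; powerline interference is
omitted because the band-pass removes it anyway.

What the generator does **not** emulate: pathological morphologies,
electrode motion artifacts, muscle noise bursts, heart-rate trends
within a record, and respiratory modulation. Tests passing on this
population therefore demonstrate correctness of the pipeline's
mechanics and its ordering properties (e.g. R-centered ≥ blind
segmentation), not field performance on clinical recordings.

## Preprocessing

A zero-phase 4th-order Butterworth band-pass (default 0.5–40 Hz,
`sosfiltfilt`) removes DC, baseline drift and high-frequency noise
without shifting fiducial timing. An isolated symmetric bump moves by
exactly zero samples; on full PQRST morphology the smoothed apex can
move by one sample because the Q and S neighbors are asymmetric. The
filter is idempotent to < 1e−6 of signal range for in-band content away
from the record edges; the 0.5 Hz high-pass leaves edge transients that
decay over roughly 15 s, which is why the R detector discards
candidates within 100 ms of the record ends.

All indices are 0-based, windows half-open `[start, end)`; records are
processed at native sampling rate (`resample_record` harmonizes mixed
corpora when asked).

## Fiducial detection

**R-peaks.** Curvature is the second difference of the signal after a
10 ms moving average; a sharp convex apex is a strong curvature
*minimum*. Candidates are curvature minima below an adaptive threshold
— half the 0.98 quantile of |curvature| over consecutive 2 s windows —
which makes detection invariant to amplitude scale. Each candidate is
refined by a search-back to the amplitude argmax of the preprocessed
signal within ±50 ms, then refractory suppression (default 250 ms)
keeps the larger-amplitude member of any close pair. On noise-free
synthetic records sensitivity and positive predictivity are exactly 1.0
at a ±10 ms tolerance.

**P-peaks.** For each R with at least 245 ms of left context, P is
located inside `[r − 245 ms, r − 90 ms)` as the argmax of the envelope
of the analytic (Hilbert-transformed) signal of the *differentiated*
band-limited record, followed by a ±25 ms search-back to the signal
apex. Three preparation steps matter, and each earned its place against
a measured failure mode:

1. *QRS excision* — samples in `[r − 90 ms, r + 60 ms]` are replaced by
   a linear bridge before filtering. Without it, the low-frequency
   smear of the large QRS (and of deep Q waves, which reach 80–90 ms
   before R) dominates the pre-R window.
2. *Band-pass 1–15 Hz and first derivative* — the heartbeat train has a
   strong fundamental near 1 Hz whose envelope otherwise swamps small P
   waves; differentiation attenuates it proportionally to frequency
   while the P bump, centered near 5–7 Hz, survives.
3. *Hilbert envelope* — the envelope of the analytic signal of a
   differentiated bump peaks at the bump apex (the derivative crosses
   zero there, its Hilbert pair peaks), giving a smooth, sign-free
   locator.

This concrete construction is one reasonable reading of an
"augmented Hilbert transform" P locator; the guard, mask, and band are
exposed as parameters.

## Segmentation and augmentation

Four families: `blind` (consecutive fixed windows from index 0,
remainder dropped), `r_centered` (symmetric ±window/2 around each R;
boundary windows are dropped, not padded — padding would fabricate
morphology), `rr` and `pp` (consecutive fiducial-to-fiducial intervals,
variable length, linearly resampled to the set's median length before
imaging). Augmentation tops each subject up to a target count (default
100) by averaging k = 10 same-subject segments drawn with replacement,
with provenance recorded; originals are never altered or discarded, so
a subject already above the target keeps all of its segments.

## Scalogram images

The CWT

    s_cwt(a, b) = 1/√a ∫ s(t) φ((t − b)/a) dt

uses an analytic Morlet mother wavelet (`cmor1.5-1.0`), 12 voices per
octave, on a dyadic frequency grid from 0.5 Hz to min(40, fs/2) Hz
(matching the preprocessing band). Segments are symmetrically padded by
their own length and cropped after the transform so cone-of-influence
artifacts do not dominate 0.5 s windows. Magnitudes are L1-scale
normalized (divided by √a), so equal-amplitude tones have equal peak
magnitude at every scale and a tone peaks at its own frequency row —
without this, the √a weighting biases the ridge toward low frequencies
by about two voices.

Images: per-image min–max normalization (a constant scalogram maps to
the lowest colormap entry), a fixed 256-entry jet colormap, bilinear
resize to a square; low frequencies sit at the bottom row. The
canonical size is 224 × 224 × 3. The classifier head sits behind global
max pooling, so the learnable parameter count is independent of the
image size; the CPU-scale experiments train at 32 px, and the entropy
analysis uses 64 px images, purely as a problem-size choice.

## Biometric system entropy

BSE is the KL divergence between the density of genuine (same-subject)
and imposter (cross-subject) similarity scores:

    BSE = ∫ f_G(s) · log( f_G(s) / f_I(s) ) ds ≥ 0.

Similarity is the Pearson correlation of flattened representations (the
score function is a pluggable strategy). Pairs are sampled without
duplicates, 9 900 genuine and 9 900 imposter by default, seeded.
Densities are common-grid histograms (100 bins) with an ε = 1e−6 floor
and renormalization, so the integrand stays finite wherever the genuine
density has mass. Natural log by default; bits on request. On the
default 20-subject population the scalogram-image representation
carries strictly more identity information than the raw time-domain
segments — the package asserts the inequality, not any particular
value, since the magnitudes depend on the population and the score
function.

## The small residual CNN

A 27-layer network for square RGB scalogram images: a 7×7/32 stem
(stride 1, pad 3) with 2×2/2 max pooling, an identity residual block at
32 channels, then two strided stages (64 and 128 channels) of two 3×3
stride-2 convolutions whose shortcut is a 1×1 stride-2 projection
convolution followed by a stride-2 max pooling, three addition layers
in total, global max pooling, and a fully connected softmax head.
For 100 classes the learnable parameter count is 324 068 (conv and FC
weights + biases, batch-norm scale + offset) — 324 K.

The published layer table contains internally inconsistent spatial
sizes; the wiring here keeps all printed strides, under which the
downstream sizes (29 → 15 → 8 at 224 px input) are mutually consistent,
and treats the stray 57×57 entries and a "28"-channel figure as
typographical. The parameter count is independent of stride choices,
so this resolution does not affect the 324 K figure. Valid input sizes
must keep the two branch shapes equal at each addition; 224, 64 and
32 px all do, and the network raises a descriptive error otherwise.

Training is mini-batch SGD with momentum 0.9, batch size 150, learning
rate 0.001, cross-entropy loss, for 80 epochs by default (10 in the
scaled experiments); no weight decay and no early stopping, as neither
is part of the stated recipe. The implementation is pure NumPy (NHWC
layout, im2col / shift-and-GEMM convolutions) with analytically
verified gradients (checked against central differences in float64 to
~1e−7), and is bit-deterministic under a fixed seed. A
`Classifier` fit/predict contract is the plug-in point for alternative
backbones (e.g. transfer-learning networks), which are deliberately out
of scope here.

## Evaluation protocol

Phase 1 sweeps segmentation schemes × window lengths (blind 0.5–3 s;
R-centered 0.5/0.75/1 s; R-R; P-P) with stratified k-fold
cross-validation (k = 10 at full scale; the final accuracy is the
unweighted mean of fold accuracies). Phase 2 evaluates the best
segment in single-, mixed-, and multi-session scenarios; multisession
uses a two-way session swap (train on session group A, test on B, then
exchange; final accuracy is the mean of the two folds), and a subject
with only one session has its segments halved at random (seeded).
Phase 3 derives identification statistics (per-subject recall, a
Fisher-Z population summary, the cumulative accuracy distribution) and
verification metrics from the multisession confusion matrix.

Verification is one-vs-rest on classification results — no separate
verification model is trained: TP is the target's diagonal entry,
FN/FP its off-diagonal row/column sums, TN the remainder, pooled over
all targets for table-level rates. Then

    FRR = FN/(FN+TP), FAR = FP/(FP+TN), TAR = 1−FRR, TRR = 1−FAR,
    HTER = (FRR+FAR)/2,

with HTER standing in for the equal error rate, which hard decisions
cannot provide. The McNemar test with Yates continuity correction,
`(|b−c|−1)²/(b+c)` against χ²(1) (statistic 0 when b + c = 0), takes
its discordant counts from the pooled verification confusion as b = FP,
c = FN — a documented interpretation, since the pairing is not
otherwise defined. The Fisher-Z summary clamps accuracies to
`[ε, 1−ε]` (ε = 1e−6) before `atanh` because perfect per-subject
accuracies do occur and would diverge; the mean is reported
back-transformed, the spread in z-space.

## Numerical and scale choices

* Desk-scale experiment sizes: 10 subjects × 100 segments, 32 px
  images, 2-fold CV, 10 epochs for the identification run; 20 subjects
  × 100 segments, 64 px images, 9 900 + 9 900 score pairs for the
  entropy comparison. These sizes exercise every stage of the full
  pipeline; accuracies at this scale are not comparable to full-scale
  (100-subject, 80-epoch, 224 px) results.
* Histogram KL needs both densities strictly positive: ε-floor plus
  renormalization, verified against the closed form
  KL(N(0,1)‖N(1,1)) = 0.5 nat to ±0.01.
* Ties in `predict` resolve to the lowest class index (argmax
  convention); augmentation RNG streams are derived per subject so
  per-subject results do not depend on set ordering.
* WFDB support covers the text-header + 16-bit little-endian subset the
  package itself writes (sufficient for round-tripping synthetic
  corpora and for simple PhysioNet records); other storage formats are
  rejected with a descriptive error.

## Known limitations

* The synthetic population is easier than clinical data; directional
  results (entropy enhancement, R-centered ≥ blind) transfer as
  qualitative claims only.
* The P detector is tuned for healthy morphology; biphasic or absent P
  waves (atrial arrhythmia) will defeat it, as will RR intervals short
  enough to pull the previous T wave into the search window.
* The NumPy network trains at roughly 12 ms per 32 px image-epoch on
  one CPU core; 224 px training at scale calls for a GPU framework
  behind the same `Classifier` contract.
* Blind-segment accuracy at desk scale is much lower than published
  full-scale values because random phase plus few epochs is a harder
  condition; only the ordering relative to R-centered segmentation is
  asserted.
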