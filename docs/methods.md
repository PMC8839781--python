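# Methods

`erdspec` implements an objective EEG methodology for evaluating auditory
discrimination therapy (ADT) in tinnitus: event-related
(de)synchronization (ERD/ERS) mapping of keypress-locked EEG, conversion
of the maps into *deep spectrum features* through a convolutional
backbone, and statistical comparison of tinnitus and control groups
before (S1) and after (S2) an 8-week sound therapy. This note records the
models, the defaults, and the design choices that were genuinely open.

## Synthetic cohort model

Real recordings of this kind are an auditory recognition task: five 1 s
stimuli, each repeated 50 times at a random rate, with the participant
pressing a key on each recognition. The generator reproduces that
structure per recording:

* **Background**: 1/f^α noise (α = 1.0 by default, amplitude scale
  1 µV SD per channel) synthesized by spectral shaping of white Gaussian
  noise, DC removed. No ocular/muscular artifact model is included — the
  burst-rejection tests construct their own artifacts.
* **Events**: 5 stimuli × 50 repetitions (250 keypresses by default).
  Inter-stimulus intervals are uniform in [2.0, 3.0] s; the interval is a
  config knob because the underlying protocol only specifies "random
  rate". Reaction times are uniform in [0, 1] s in S1 and [0, 0.5] s in
  S2 for both groups, reflecting the narrowing of response latency with
  task familiarity.
* **Event-locked responses**: Hann-windowed sinusoids added on every
  channel at a configured latency after each keypress. A windowed
  sinusoid is used because it is band-limited and analytically tractable
  (mean power a²·E[env²]/2 with E[env²] = 3/8 for a Hann envelope), which
  gives the recovery tests a closed-form oracle.
* **Default effect profile** (the qualitative group pattern such studies
  report): controls show an 8–13 Hz ERS burst (4 µV, 0–0.5 s post-event)
  in both sessions; the tinnitus group lacks it in S1, showing instead
  late 25–30 Hz activity (3 µV, 0.5–0.9 s), and gains the alpha ERS in
  S2.
* **Determinism**: each recording draws from an RNG stream spawned from
  the master seed and the (group, session, subject) key, so regenerating
  one cell never changes another and identical configs are bit-identical.

What the generator does *not* emulate: volume conduction and channel
covariance structure, non-stationary background power, eye blinks and
muscle artifacts, inter-subject variability of spectral peaks. Passing
tests therefore demonstrate that the pipeline recovers known injected
effects under realistic 1/f noise — not that it is robust to every
pathology of clinical EEG.

The scalogram-image fixture generator is a separate, much simpler model:
four classes (tinnitus/control × S1/S2, default sizes 801/667/500/500,
2468 total) rendered as distinct horizontal-band patterns plus Gaussian
pixel noise, with a `separation` parameter scaling between-class
contrast. It exists to test the feature-extraction and comparison layers
in isolation from the EEG chain.

## Preprocessing

Band-pass: Butterworth order 6, 0.1–30 Hz, applied forward–backward
(`sosfiltfilt`), so the effective magnitude response is the squared
Butterworth response and phase is zero. Edge transients are handled with
reflective padding of 3 × order samples; note that with a 0.1 Hz low
cutoff the transient is intrinsically long (tens of seconds), which is
why the time-invariance test uses a higher cutoff.

Channel rejection uses three criteria: flat for more than 5 s;
high-frequency noise, operationalized as the SD of the channel's
15–30 Hz component expressed as a robust (median/MAD) z-score across
channels and flagged above 4; and maximum Pearson correlation with the
other channels below 0.8. The HF band and the "all other channels"
neighborhood are config, not claims about any particular study: the
criteria as usually cited come from a tool default without a formula.

Burst rejection is a windowed-RMS thresholder: calibration SD per channel
over the quietest quartile of 0.5 s windows; any window whose RMS
*strictly exceeds* 20 × the calibration SD on any channel is masked and
excluded from epoching. This shares Artifact Subspace Reconstruction's
calibration idea and threshold but masks rather than reconstructs —
a deliberate simplification; independent-component rejection is likewise
out of scope, and the pipeline accepts pre-cleaned input.

## ERD/ERS mapping

Epochs are cut on one channel (default Fz, the clinical recording site
for tinnitus) from 500 ms before to 1 s after each keypress; at 256 Hz
this is exactly 128 + 256 = 384 samples, window half-open, with onsets
rounded to the nearest sample exactly once. Events whose window leaves
the recording or touches a burst mask are dropped and counted.

The CWT uses the complex Gaussian family
f(x) = C_p d^p/dx^p[e^(−ix) e^(−x²)], with C_p fixed numerically so the
sampled wavelet has unit L2 norm. The derivative is exact (polynomial
recurrence P_{p+1} = P_p′ + (−i − 2x)P_p), so no finite-difference error
enters. Choices that the method itself leaves open:

* **Derivative order** p = 4 by default (balanced time–frequency
  localization), configurable 1–8.
* **Scale↔frequency map**: scale = f_c / f with f_c the wavelet's
  spectral-peak frequency measured from its FFT — not a table constant.
* **Frequency grid**: 60 log-spaced frequencies in [0.5, 30] Hz by
  default; a linear option reaches 0.1 Hz, but with 1.5 s epochs
  frequencies below ~0.7 Hz are under-resolved (shown, not truncated).
* **Edges**: each epoch is reflect-padded by one wavelet support per
  scale; no cone-of-influence masking, so maps span the full
  [−0.5, 1.0) s.
* **Ordering**: coefficients are averaged across epochs, rectified
  (`average_then_abs`, emphasizing phase-locked activity), then
  baseline-corrected. The alternative `abs_then_average` (induced power)
  is provided because the two orderings are both defensible and differ
  exactly when phase varies across epochs; per-epoch baseline correction
  is likewise available.

Baseline correction subtracts, per frequency, the mean power over
[−400, −100] ms (endpoints rounded to samples, inclusive), so the
corrected map has zero baseline mean by construction; positive values
are ERS, negative ERD.

Scalograms are rendered with a fixed colormap (viridis), min-max scaled
per map (scaling recorded in a JSON sidecar), drawn at 1200 × 900 and
resized to 160 × 160. The colormap is a feature-affecting choice: a
different map changes the pixel statistics the backbone sees.

## Deep spectrum features

The backbone is a MobileNet-V2-style network implemented in NumPy:
stem 3×3 stride-2 convolution (32 channels), seven inverted-residual
stages (expansion 6, depthwise-separable 3×3, linear bottlenecks,
residual connections at stride 1) reaching total stride 32, then a 1×1
convolution to width 1280 — so a 160 × 160 × 3 image yields a
5 × 5 × 1280 block and global average pooling yields the 1280-vector.
Weights are He-initialized from a seed; externally trained weight arrays
can be passed in for real-data use, but nothing in the package or its
tests requires pretrained weights. Batch normalization is omitted: with
fixed (untrained) weights it is an affine constant, and the head
standardizes features anyway.

The classifier head is a single dense unit (1280 weights + 1 bias = 1281
parameters) trained with Adam (lr 1e-4, batch 32, 25 epochs, dropout 0.2
on the pooled features during training only) on binary cross-entropy of
the logit; positive logits predict class 1 (control), non-positive
class 0 (tinnitus). The 80/20 validation split is stratified by class
and seeded. Features are standardized with training-split statistics and
the transform is folded back into the returned weights. An exhaustive
hyperparameter grid (lr 1e-3..1e-6, dropout 0.1–0.5, epochs 15–100,
batch 25–45) ships as an optional utility and is never run by default.

## Comparison layer

* **Scalar outcome** Y per instance: mean of the 1280 features by
  default. The choice of scalar is genuinely open in this methodology
  (distances to a reference centroid and single named features are
  selectable alternatives); outputs record which was used.
* **Lilliefors test**: statistic max|ECDF − Φ((x−x̄)/s)|; p-values from a
  seeded Monte-Carlo null table (10⁴ draws per sample size, cached), so
  arbitrary n is supported without printed tables.
* **Student's t**: pooled-variance two-sample test; "+" codes p > 0.05
  (significant relationship), "−" codes p < 0.05 (significant
  difference). Two identical zero-variance samples return p = 1. No
  multiple-testing correction is applied across the matrix cells — a
  known limitation, kept for fidelity to the analysis style.
* **Comparison matrices**: the within design emits the six cohort-level
  pairings (T-S1–C-S1 … C-S1–C-S2); the between design emits, per
  tinnitus subject, five pairings of that subject's instances against
  the pooled controls — the only reading consistent with a per-subject
  row structure.
* **DID**: Y = β0 + β1·Time + β2·Intervention + β3·(Time·Intervention)
  + ε, fit by OLS; β3 provably equals the difference of cell-mean
  differences, which the tests assert to 1e-10. Effect label: Positive
  iff β3 > 0. Only the point estimate and sign are reported, no standard
  errors.
* **Centroids/distances**: C_i = (1/p)Σ_j x_ij per cell; per-instance
  Euclidean distances to the control centroids; mean and *population*
  standard deviation (denominator N, not N−1) — the population form is
  part of the method's definition here, and the suite checks it is
  strictly below the sample SD on non-constant data.
* **Box plots**: five-number summaries per cell, quartiles by linear
  interpolation between order statistics.

## Problem sizes and numerical choices

The default pipeline configuration runs a reduced cohort (2 subjects per
group, 5 stimuli × 5 repetitions, 40 analysis frequencies), giving
5 maps and feature instances per recording; the acceptance checks use
1–2 subjects, 3–8 repetitions, and 20–30 frequencies. These sizes were
chosen so the full chain and its determinism can be exercised routinely;
all of them scale up by config. Degenerate inputs raise explicit errors
rather than propagating NaNs (empty cells, all-masked recordings,
zero usable events, collinear DID designs, double baseline correction).
Ties in the burst threshold are resolved by the strict inequality the
criterion states ("exceeded"): a window at exactly 20 × SD survives.

## Known limitations

* The burst rejector masks instead of reconstructing; heavily
  artifacted recordings lose data that ASR proper would repair.
* A random-weights backbone is a random nonlinear projection: it
  preserves gross image structure but its features are not comparable
  across backbone seeds, and reproducing any particular study's
  classification accuracy requires that study's images and weights.
* The synthetic generator's simplifications listed above mean green
  tests bound correctness of the *computation*, not clinical validity.
* Band-resolved (theta/alpha/beta) feature comparisons and multichannel
  topographic maps are out of scope.
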