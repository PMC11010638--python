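# Methods

This note documents the models, numerical choices and limitations of
`musemo`: a pipeline that converts multichannel EEG evoked by emotional
music into per-band differential-entropy (DE) features and classifies
binary valence and arousal with a hybrid CNN / self-attention / BiLSTM
network, together with a synthetic-EEG generator that makes every stage
testable without access to a real corpus.

## Pipeline model

**Preprocessing.** Raw recordings (channels × samples, µV) pass through a
1–45 Hz 3rd-order Butterworth band-pass, downsampling to 128 Hz
(polyphase), baseline correction, and segmentation into non-overlapping
2-s windows (256 samples/channel at 128 Hz). Band decomposition splits
each window into theta (4–8 Hz), alpha (8–13 Hz), beta (13–30 Hz) and
gamma (30–45 Hz) with the same 3rd-order Butterworth design.

All filtering is zero-phase (`sosfiltfilt`, forward + backward). The
filter order names the design order; a tone in the stopband is therefore
attenuated by the *squared* magnitude response, which the tests verify
against `sosfreqz` directly. Zero-phase filtering avoids group-delay
shifts that would move band energy across window boundaries.

Baseline correction subtracts each channel's mean over the first 2 s of
stimulation and then drops that window; correcting in signal space (rather
than subtracting baseline DE features) is a design choice — the
alternative is exposed by computing features on an uncorrected recording
and differencing, but is not the default.

Windows are Hann-tapered by default and rescaled by `1/sqrt(mean(w²))` so
the expected power of stationary signal is preserved (verified by Monte
Carlo to <5%); `taper="none"` is available, and with it segmentation
concatenates back to the trimmed recording exactly.

**Labels.** SAM ratings (1–9) binarize at the scale midpoint 5: below 5 →
0 (low), otherwise → 1 (high). A rating of exactly 5 is labeled *high*;
the reported thresholding rule covers only the strict inequalities, so the tie-break
is a package decision and is recorded in segment metadata. Binarization
is monotone in the rating by construction.

**DE features.** For a zero-mean Gaussian signal with variance σ², the
differential entropy is ½·log(2πeσ²). Band-passed EEG windows are treated
as zero-mean Gaussian, so the feature for one (window, channel, band) is
that closed form at the *unbiased* (n−1) sample variance; with 2-s
windows (T=256) the bias difference is negligible but the convention is
fixed for reproducibility. Log base 2 (bits) is the default; base e is a
switch, and all internal comparisons are base-consistent.

A symmetric two-Gaussian mixture (modes ±μ, common σ, expressible via a
cosh factor) is retained as a *numerical quadrature oracle*: at μ=0 it
reduces exactly to the Gaussian and its entropy exceeds the Gaussian
closed form by a separation term L(μ/σ) that rises from 0 to ln 2. The
closed form is asserted against this oracle to 1e-6 over four decades of
σ. The mixture is not used as the feature: band-passed EEG is zero-mean,
for which the mixture collapses to the Gaussian anyway.

Degenerate inputs: variances below 1e-10 are floored before the log (with
a warning) so constant synthetic channels cannot produce −∞.

**Feature matrix.** Rows are windows, columns are band-major:
`[θ·ch1..chC, α·ch1..chC, β·…, γ·…]`; with 128 channels and 4 bands a row
has 512 entries. The ordering is explicit in the container and its HDF5
serialization because no convention is standard. Band subsetting keeps
the requested band order and the full row metadata.

## Network

The full classifier ("CSBN" = CNN + self-attention + BiLSTM network)
reads the DE vector as a 1-channel sequence:

1. **CNN.** Seven 1-D convolutions (ReLU) with one max- and two
   average-pooling stages, batch normalization and spatial (channel-wise)
   dropout, reducing a 512-long input to a (64, 2) feature map. The
   reference stage table specifies filters, strides and output shapes but
   no kernel sizes; the kernels are derived as the unique no-padding
   sizes that reproduce the stage output lengths (k = 2, 6, 5, 6, 3, 2, then 3 with
   padding 1), with the final pooling stage necessarily size-2/stride-1.
   The symbolic `shape_trace` reproduces the printed output column
   row-for-row and is asserted in the tests.
2. **Multiplicative residuals.** Each consecutive convolution pair (1–2,
   3–4, 5–6) is wrapped as x_{l+1} = h(x_l) ⊙ F(x_l), where F is the
   two-convolution main path and h a 1×1 convolution adjusting the skip
   path's shape. Because no integer stride maps 512 → 126 (or 6 → 3)
   exactly, h uses the largest stride whose output is at least as long as
   the main path — `max(1, floor((L_in−1)/(L_out−1)))` — followed by a
   left-aligned crop (exact for pairs 2 and 3; pair 1 crops 128 → 126).
3. **Self-attention.** The (64, 2) map is read as a length-2 sequence of
   64-dim features (positions as steps, channels as features; the
   sequence axis is an interpretation, since a flat vector admits none).
   Single head, scaled dot-product: weights = softmax(QKᵀ/√d_k), output =
   weights·V, d_k = d_v = 64. Weights are returned for inspection.
4. **BiLSTM.** Three bidirectional layers of 128/64/64 hidden units with
   the conventional forget/input/output gating on [h_{t−1}, x_t]; each
   layer concatenates the forward and backward hidden states per step,
   and the classifier consumes the last layer's concatenated final states
   (a 128-vector).
5. **Softmax head.** A linear map to 2 logits; training minimizes
   categorical cross-entropy on the logits, inference applies a
   numerically stable softmax.

**Ablation variants.** `CNN` = conv stack (with residuals) → flatten →
softmax; `BiLSTM` = input reshaped to a sequence (64-dim × 8 steps for a
512 vector; the layout generalizes to 8/4/2 steps for shorter inputs) →
BiLSTM → softmax; `CNN-BiLSTM` = full model without the attention block.

**Scaled-down specs.** The reference stack is only consistent with input
length 512. For other lengths (band subsets, smaller montages) a generic
constructor applies the same motifs: stride-2 kernel-2 halving
convolutions with residual wraps on consecutive pairs plus batch
norm/dropout, a final stride-1 convolution to length 2, attention width
equal to the final filter count d, and BiLSTM sizes [2d, d, d]. Inputs
shorter than 8 are rejected with an error naming the stage/subset.

**Implementation.** No deep-learning framework is used: the network,
reverse-mode autodiff and Adam are implemented in NumPy (float64,
single-threaded), which keeps runs bitwise reproducible for a fixed seed.
Every primitive's gradient is checked against central finite differences
in the test suite, and a full-model backward pass is checked to reach
every parameter (no dead branches). Weight initialization is
Glorot-uniform from a seeded generator; spatial dropout rate 0.3; batch
norm ε=1e-5, momentum 0.1 (running statistics used at inference). Batch
norm follows pooling and precedes dropout, in the stage order of the
reference table.

## Training and evaluation

Adam (lr 1e-3, β = 0.9/0.999) on categorical cross-entropy. Folds are
**segment-level and stratified** (StratifiedKFold, shuffled, seeded);
per-fold models re-initialize from a seed derived from (run seed, fold
index), so folds are independent yet the whole run reproduces exactly.
Segment-level folds place windows of the same trial on both sides of the
split, so accuracies measure within-trial generalization — a
trial/subject-grouped splitter (`groups=` argument) is provided for
leakage-aware evaluation, and the distinction matters when interpreting
any segment-level number.

Metrics: accuracy; precision and F1 on the positive class (label 1);
AUC as the rank statistic of the positive-class probability. A
single-class test fold reports AUC as missing with a warning. Suite
aggregation reports mean and max over folds (mean ≤ max is asserted as an
invariant).

The ablation suite cross-validates each of the four variants on both
tasks; the band suite cross-validates one variant on each of the 14
singleton/pair/triple band subsets (columns re-selected, model spec
re-derived from the new input length).

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
not real electrophysiology:

- **Background**: 1/f¹ Gaussian noise per channel (spectral shaping of
  white noise; exponent configurable). A 1/f spectrum makes the band
  filters do real work — white noise would make every band equally
  trivial.
- **Rhythms**: narrowband components are band-pass-filtered white noise
  (not sinusoids), so DE features fluctuate across windows instead of
  collapsing to a constant. Component RMS equals the profile amplitude
  exactly.
- **Class signatures**: the four stimulus classes (fear, happy, calm,
  sad) differ in alpha amplitude only — 1, 2, 4, 8 respectively — so each
  class is identifiable from alpha power alone, adjacent classes differ
  by a band-power ratio of 2 (variance ratio 4, i.e. 1 bit of DE), and
  the single-band experiments have a known ground truth: alpha must win.
  Reported per-class band-power statistics do not exist, so these
  amplitudes are free parameters chosen once for clear separation, not
  estimates of any real effect size.
- **Ratings**: per-trial valence/arousal drawn from Normal(class mean,
  class sd), clipped to [1, 9]. The class means/sds are the reported
  stimulus statistics of the music set this pipeline targets (fear
  3.03/7.12, happy 6.98/7.02, calm 5.85/3.56, sad 3.55/2.86; sd ≈ 0.3),
  so binarization at 5 yields the standard quadrant labels (fear → low
  valence/high arousal, etc.). Calm's valence mean (5.85) sits closest
  to the threshold; with sd ≈ 0.25 an occasional trial can legitimately
  flip label, which downstream code must tolerate.
- **Randomness**: every trial draws from a counter-based substream keyed
  by (seed, class, trial), with per-channel and per-band child streams —
  identical specs reproduce byte-identical datasets, different trials
  never share noise, and generation order is irrelevant.
- **Gains**: a small per-channel multiplicative gain (sd 0.05) emulates
  electrode-contact variation.

Not emulated: ocular/muscular artifacts, volume conduction, electrode
geometry, non-stationarity, inter-subject variability. Passing the
synthetic-recovery tests therefore shows the pipeline recovers planted
band-power structure through the full stack; it says nothing about
accuracy on real EEG.

**Scales.** The full-scale spec mirrors the acquisition geometry of the
target corpus: 128 channels at 1024 Hz, 20-s trials. The default
experiment scale used by the test suite and the acceptance script is 8
channels at 128 Hz, 12 trials/class of 20 s — after the 2-s baseline
drop, 9 two-second windows per trial, i.e. 108 segments/class (432
total, 32-dim feature rows). Training runs use 20 epochs at batch 64;
on this data every variant's accuracy plateaus well before that. These
sizes are the package's defaults for self-contained experiments; the
full-scale spec is available through the same API.

## Numerical choices and degenerate inputs

- Quadrature for the mixture entropy integrates over ±(μ + 40σ) with the
  mode locations as split points; convergence is checked against the
  reported absolute error and failure raises with diagnostics.
- Resampling uses polyphase filtering with the rational rate ratio;
  upsampling is rejected (the pipeline only downsamples). Output length
  is `round(n·target/fs)`.
- Recordings shorter than one window segment to an empty list with a
  warning; shorter than the baseline window raise.
- Softmax and cross-entropy are max-shifted; logits of ±1000 do not
  overflow.
- Batch norm needs ≥2 samples; the training loop skips a trailing
  singleton batch.
- The EDF writer quantizes to 16 bits over the per-channel data range
  (standard EDF); round-trip error is bounded by span/65536 and checked
  against an independent EDF reader.

## Known limitations

- Segment-level cross-validation shares trials across folds (see above);
  reported synthetic accuracies are near-ceiling by construction and are
  functional checks, not benchmarks.
- The attention block sees a length-2 sequence in the full architecture;
  with so short a sequence its role is closer to a learned gating of two
  positions than to long-range context integration.
- The ICA artifact-removal stage of real-EEG practice requires manual
  component review and is a pass-through hook here.
- Single-head attention only; no topographic/2-D convolution variants;
  no significance testing between variants.
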