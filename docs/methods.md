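# Methods

## Signal model of the synthetic cohorts

The generator emulates the statistical structure a PPG identification
pipeline relies on, not hemodynamics. Each identity is a parameter
vector: mean and SD of heart rate (beats/min), systolic Gaussian
amplitude and width (s), dicrotic amplitude (fraction of systolic) and
delay (s). A record is

```
x(t) = Σ_k [ A_s exp(−(t−t_k)²/2σ_s²) + A_d exp(−(t−t_k−δ)²/2σ_d²) ] + n(t)
```

with beat times `t_k` spaced by the mean period plus Normal jitter
derived from the heart-rate SD (periods clipped to ±50 % of the mean),
the dicrotic width fixed at 1.5 σ_s, and the first peak half a period in
(so a jitter-free k-period record holds exactly k systolic peaks — the
oracle used in tests). The additive noise `n(t)` has four independent
parts: white Gaussian noise; a low-frequency baseline-wander sinusoid
(default 0.25 Hz, amplitude 0.3); a high-frequency ambient tone (50 Hz,
amplitude 0.05) standing in for mains/ambient-light interference; and
Poisson-arriving motion bursts (2/min), each a Gaussian-windowed 0.2–1 Hz
oscillation of amplitude 1.5 and 0.3–0.8 s width. Identity draws,
beat jitter, and noise use separate seed streams, so every generator is
a pure function of its seeds.

Random identities are drawn from documented resting-state ranges
(HR 55–95 bpm, σ_s 0.08–0.16 s, dicrotic fraction 0.2–0.5, delay
0.20–0.35 s); a `spread` knob scales the inter-identity variance around
the range centers for separability studies. `make_separated_identities`
instead spaces heart rates evenly and cycles the morphology parameters
through distinct values, producing the "well-separated" cohorts used in
the end-to-end experiment.

What the simulator does **not** reproduce: pulse-shape change with
posture or vasomotion, sensor-contact drift, arrhythmia, respiratory
amplitude modulation, or inter-session variability of one person.
Passing the end-to-end test therefore shows the pipeline can recover
identity from systolic/dicrotic geometry and rate under realistic noise;
it does not certify field performance on real sensors.

## Preprocessing

Stages run in a fixed order, each individually addressable, and the
chain equals their composition (tested):

| stage | method | default |
|---|---|---|
| band-pass | Butterworth, forward–backward (zero phase) | 0.5–8 Hz, order 4 |
| baseline | centered moving average, reflection padding, subtracted | 1.0 s window |
| artifacts | epoch-stacked PCA (below) | 1 s epochs, keep 90 % energy |
| normalize | subtract mean, scale peak |x| to 1 | — |
| resample | cubic spline on the time grid | 250 Hz |
| segment | sliding window, trailing remainder dropped | 5 s, 50 % overlap |
| screen | periodogram SNR, in-band/out-of-band | band 0.7–3.5 Hz, ≥ 5 dB |

The band brackets cardiac fundamentals (0.7–1.8 Hz) and their useful
harmonics while removing wander and ambient tones. Segment count obeys
`floor((L−W)/S)+1` with `S = round(W(1−overlap))`.

**PCA artifact removal.** The record is cut into consecutive 1 s epochs,
stacked as matrix rows, and decomposed by SVD of the *uncentered*
matrix; the reconstruction keeps the leading components whose cumulative
energy first reaches the configured fraction. The repeating pulse shape
is (nearly) common to all epochs and dominates the first component,
while a transient burst confined to one epoch loads on trailing
components and is dropped. Column-centering would move the common pulse
into the restored column means and leave the burst as the *leading*
deviation component, which inverts the intended behavior — hence the
uncentered form. `keep = 1.0` reproduces the input exactly. PCA is
applied per record; applying it across records would mix subjects.

SNR is defined as `10 log10(P_in/P_out)` from the periodogram, with
`P_in` the power in the cardiac band (DC excluded) and `P_out` the rest;
an all-in-band segment returns `+inf`. The 5 dB default threshold is a
package choice (no canonical value exists); it admits ≥ 90 % of clean
synthetic segments while rejecting burst-dominated ones.

Trailing partial windows are dropped rather than padded; zero-padding is
reserved for the scalogram stage, which pads short segments to a
configured length before the transform.

## Scalogram

The CWT is evaluated as the Riemann sum of the analysis integral on the
sample grid (Δt = 1/fs) with zero extension beyond the boundaries, using
the non-admissibility-corrected Morlet wavelet with ω₀ = 6 — the
conventional compromise between time and frequency localization. Scale
and frequency are linked by `s = ω₀/(2πf)`. The fast path computes each
scale row by FFT convolution with the conjugated, time-reversed, scaled
wavelet truncated at 8 Gaussian sigmas (envelope ≤ e⁻³² there); a
literal double-loop oracle exists purely as a cross-check, and the two
agree to ~10⁻¹³ relative error.

Frequency grids are linear. The full profile spans 0.5–100 Hz × 128
bins with 128×128 images. The desk profile uses 0.5–25 Hz × 64 bins and
64×64 images: the desk cohort is band-limited to 8 Hz by the band-pass,
so the narrower span spends its bins where the signal lives. Magnitude
matrices are resized by bilinear interpolation (align-corners grid;
resizing to the same size is exact) and min-max scaled to [0, 1] per
image — a required model-input convention; constant images map to zero.

## Hybrid model

Branch conventions follow their respective origins: the CVT
convolutional stage uses conv → ReLU → batch-norm with 3×3 kernels and
evenly interleaved 2×2 stride-2 max-pools; the ConvMixer branch uses
GELU throughout with batch-norm after the activation. The ConvMixer
block is `Z_l = BN(GELU(DW(Z_{l−1}))) + Z_{l−1}` followed by
`Z_{l+1} = BN(GELU(PW(Z_l)))`. The branch output fuses two paths from
the last block — a pointwise path `BN(PW(f))` on the block input `f`
and the batch-normalized depthwise-residual path — by channel
concatenation (width 2h) and GELU, then applies one multi-head
self-attention pass over spatial positions and global average pooling.
Self-attention is applied once after the mixer stack, not per block.

The CVT map is cut into `n_tokens` horizontal strips (zero-padded rows
when indivisible), each linearly embedded, given learned position
embeddings, and passed through one pre-norm transformer encoder block;
tokens are mean-aggregated.

Fusion is `Dense = P_cvt(CVT) + α · P_cm(ConvMixer)` with linear
projections only where dimensions differ and α a learnable scalar
initialized at 1 (fixable for ablations; α = 0 reduces the network
exactly to the CVT path, which is tested). A concatenation mode exists
behind a flag. Then a residual unit `ReLU(x + Wx)`, a
squeeze-excitation channel gate (reduction 4, ReLU between the two FC
layers, sigmoid weights in (0, 1) so the gate never amplifies), and an
MLP softmax head.

Two profiles: **desk** (64×64 input, 6 conv layers 8→64 channels, 3
pools, 4 tokens of dim 64, 4 heads, patch 8, h = 32, depth 4, head
width 128; ≈ 0.18 M parameters) and **paper-full** (128×128 input,
17-layer VGG-like plan to 512 channels, 5 pools, 7 tokens of dim 1024,
8 heads, patch 5, h = 32, depth 7, head width 2048; ≈ 38.5 M
parameters — the convolutional channel plan is an explicit config
because no canonical plan exists at this size). Initialization is He
for conv/ReLU paths and Xavier for linear/attention paths, deterministic
per seed; each component draws from an independent seed stream so
ablated builds share parameters with the full build.

The model runs on an in-package numpy autodiff engine (float32,
im2col + BLAS convolutions, shift-and-add depthwise convolutions, fused
batch-norm). Batch statistics are used in training and running
statistics in evaluation. Every layer is gradient-checked against
central finite differences.

## Training and evaluation

Cross-entropy `−Σ y·log(clip(p, 1e−12, 1))` averaged over the batch is
the default loss (an MSE-on-softmax mode is also exposed); optimizers
are Adam (default, lr 10⁻³) and SGD with momentum. Early stopping
restores the best-validation-loss parameters after a configurable
patience. Desk defaults: batch 32, ≤ 10 epochs, patience 5; full
profile: 100 epochs, patience 50.

All splits are stratified by class and grouped by recording so segments
from one record never straddle a split — without this, overlapping
windows of the same record would inflate accuracy. K-fold
cross-validation holds out each fold once (k = 5 default) and re-splits
the remainder 80/20 for validation; the rotating cross-source protocol
trains on each source and evaluates on the others, with the diagonal
given by within-source k-fold.

Metrics are one-vs-rest per class — sensitivity, specificity,
precision, recall, F1, accuracy — with unweighted macro averages, plus
overall accuracy and macro one-vs-rest ROC AUC (trapezoidal, ties
averaged; verified against a Mann–Whitney pair-counting oracle).
Zero-denominator metrics return 0 with a logged warning.

## Problem sizes and numerical choices

The end-to-end experiment uses 8 well-separated identities × 60
five-second records at 250 Hz (480 segments, one per record), desk
profile, a 64/16/20 record-grouped split, and ≤ 10 epochs; one training
run takes on the order of a minute on a single CPU, and the acceptance
script repeats it once per invocation plus a label-permuted control.
The permuted control typically lands a few points above the 12.5 %
chance floor because a random permutation leaves a fluctuating fraction
of labels self-consistent; it stays far below genuine performance.

Oracle comparisons use relative tolerance 10⁻⁶ (CWT vs double loop),
10⁻⁹ (loss and AUC arithmetic), and exact integer equality for
confusion counts. Degenerate inputs are defined, not special-cased
errors: constant signals normalize to zero, constant scalograms map to
zero images, empty segment lists produce empty outputs, and a signal
shorter than one window yields an empty segment list.

## Known limitations

- The synthetic cohort is easier than clinical data; reported accuracy
  characterizes the pipeline's correctness, not expected field accuracy.
- The PCA stage assumes artifacts are transient and epoch-local;
  sustained corruption violates the variance argument.
- The full-size profile's convolutional channel widths are a package
  design choice (no canonical plan exists at that depth), so its exact
  parameter total is a property of this configuration, not a derived
  quantity.
- The WFDB reader supports single-segment format-16 records only.
- Verification (genuine/imposter) is exposed as one-vs-rest use of the
  softmax scores rather than a dedicated binary head.
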