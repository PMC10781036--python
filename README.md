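# ppg-bioauth

Biometric identification from photoplethysmogram (PPG) signals.

A PPG trace is a quasi-periodic optical record of blood-volume changes:
every cardiac cycle leaves a systolic peak followed by a smaller dicrotic
wave, and the relative geometry of those two features is stable within a
person but varies across people. This package turns that observation into
an identification pipeline:

1. **Preprocessing** — zero-phase Butterworth band-pass (0.5–8 Hz),
   moving-average baseline subtraction, PCA-based motion-artifact
   suppression on an epoch-stacked matrix, peak normalization,
   cubic-spline resampling to a common rate (250 Hz), segmentation into
   5 s windows with 50 % overlap, and spectral-SNR quality screening.
2. **Scalogram imaging** — each segment is transformed with a Morlet
   continuous wavelet transform,

   ```
   W(s, τ) = s^(-1/2) ∫ x(t) ψ*((t − τ)/s) dt,
   ψ(t)    = π^(-1/4) · exp(i ω₀ t) · exp(−t²/2),      ω₀ = 6
   ```

   and the magnitude |W| over a frequency × time grid is resized to a
   square image in [0, 1].
3. **Hybrid CVT-ConvMixer classifier** — two branches share a scalogram
   input: a convolutional vision-transformer branch (3×3 conv stack with
   max-pooling, patch tokens + position embeddings, one transformer
   encoder block) and a ConvMixer branch (patch-embedding stem
   `Z₀ = BN(σ(Conv_h(X, stride=p, kernel=p)))`, depthwise-residual +
   pointwise blocks, two-path batch-normalized fusion with GELU,
   self-attention over spatial positions). The branch vectors are fused
   additively, `Dense = CVT + α · ConvMixer`, refined by a residual unit
   `ReLU(x + transform(x))` and a squeeze-excitation channel gate
   `Features = sigmoid(FC₂(FC₁(pool(x)))) ⊙ x`, and classified with a
   softmax MLP head. Evaluation reports one-vs-rest sensitivity
   TP/(TP+FN), specificity TN/(TN+FP), precision, F1, accuracy, and
   macro ROC AUC.

Because no deep-learning framework is assumed, the model runs on a small
numpy-based reverse-mode autodiff engine that ships with the package
(`ppg_bioauth.nn`); all layers are gradient-checked against finite
differences in the test suite.

A synthetic-cohort generator (`ppg_bioauth.synth`) produces labeled PPG
records with per-identity morphology (two Gaussians per cardiac cycle),
heart-rate variability, baseline wander, broadband noise, an ambient
interference tone, and sparse motion-artifact bursts, so the full
pipeline is testable without any data download.

## Worked example

```python
import numpy as np
from ppg_bioauth.synth import synth_cohort, NoiseConfig
from ppg_bioauth.preprocess import PreprocessConfig
from ppg_bioauth.scalogram import ScalogramConfig
from ppg_bioauth.pipeline import records_to_dataset
from ppg_bioauth.model import desk_config
from ppg_bioauth.train_eval import TrainConfig, identification_experiment

records = synth_cohort(8, 60, 5.0, 250.0, NoiseConfig(), seed=0, separated=True)
scal = ScalogramConfig(n_freq_bins=64, freq_min_hz=0.5, freq_max_hz=25.0,
                       image_side=64)
ds = records_to_dataset(records, PreprocessConfig(), scal)
res = identification_experiment(ds, desk_config(n_classes=8), TrainConfig(),
                                seed=1)
print(f"test accuracy {res['accuracy']:.3f}, macro AUC {res['auc']:.3f}")
```

This simulates 8 identities × 60 five-second records at 250 Hz,
preprocesses and screens them (480 surviving segments), renders 64×64
scalograms, and trains the desk-profile hybrid model (~0.18 M
parameters) on a record-grouped 64/16/20 train/val/test split. It prints

```
test accuracy 0.958, macro AUC 0.999
```

meaning 92 of the 96 held-out segments were attributed to the correct
identity, and a randomly chosen (genuine, imposter) score pair is ranked
correctly 99.9 % of the time. A label-permuted control run collapses to
near the 12.5 % chance level, confirming the accuracy comes from the
waveform morphology and not from leakage.

The same flow is scriptable from the shell:

```bash
ppg-bioauth run-all --profile desk --seed 0 --out runs/demo
ppg-bioauth simulate --identities 8 --records 10 --seed 0 --out runs/sim
ppg-bioauth preprocess --in runs/sim --out runs/pre
ppg-bioauth scalogram --in runs/pre --out runs/scal
ppg-bioauth crossval --mode kfold --out runs/cv
```

Two `run-all` invocations with the same `--seed` produce byte-identical
reports.

The full-size model profile (`--profile paper-full`: 17-layer VGG-like
convolutional stage, 7 patch tokens of dimension 1024, 8 attention
heads, 7 mixer blocks) builds with ≈ 38.5 M trainable parameters and is
intended for real multi-subject waveform datasets read through
`ppg_bioauth.io` (CSV signals or PhysioNet-style format-16 records).

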