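# Methods

This note documents the models, numerical choices, and problem sizes the
package uses, and what its synthetic data can and cannot say about real
EEG.

## Head model and forward projection

The scalp is a single homogeneous conducting sphere (radius R = 85 mm,
conductivity 0.33 S/m). The surface potential of a current dipole at
eccentricity f = r/R is evaluated by the exact Legendre expansion

V ∝ Σₙ (2n+1)/n · fⁿ⁻¹ · [ n·p_r·Pₙ(cos γ) + p_t·Pₙ¹(cos γ) ],

truncated when fⁿ < 1e−12 (≈450 terms at the maximum allowed f = 0.95).
This surrogate keeps the two properties the benchmark needs — spatial
smearing across many electrodes (volume conduction) and exact
left/right mirror symmetry — without any mesh or tissue segmentation. A
realistic lead field (channels × sources HDF5) can be loaded in its
place; nothing downstream changes.

Montage: 62 standard 10-10 sites (a 64-channel actiCAP-style cap minus
the two ear-adjacent electrodes, which realistic forward models
typically omit). Positions are symmetrized across the midline and
projected onto the sphere, so mirror-pair physics tests are exact.
MNI coordinates are mapped into the sphere by dividing by 88 mm
(an approximate MNI head half-width) and rescaling to R; positions
mapping outside 0.95 R are clipped onto that shell. All dipoles are
radially oriented ("perpendicular to the scalp"), which concentrates
each source's scalp projection. Gain columns are average-referenced and
scaled to unit L2 norm, so waveform amplitudes in μV set the scalp
scale; only relative topography matters to any metric.

## Simulated conditions

All epochs are 1 s at 250 Hz × 62 channels. Per epoch, the signal
dipole(s) carry the class-defining waveform; 62 − n_signal brain-noise
dipoles at uniformly random directions on a shell at 0.80 R carry 5 μV
RMS pink noise (1/f amplitude spectrum by FFT shaping, DC removed,
exact RMS rescale); the projected noise is mixed to the target scalp
SNR, defined as the decibel ratio of mean squared amplitude over all
samples and channels, and satisfied exactly (≤1e−6 dB) by scaling the
noise; white sensor noise at 10% of the mixed-epoch RMS (−20 dB) is
added last. The sensor-noise level is a package choice (only
"uncorrelated white noise" is specified by the protocol this emulates)
and is deliberately *relative*: with unit-norm gain columns the
absolute scalp scale is arbitrary, so any fixed absolute noise level
would re-define the effective SNR and take the SNR grid — the
experiment's controlled variable — out of control.

* **Temporal (4 classes, ERP latency).** Gaussian-tapered deflections
  with σ = width/6 (the stated "peak width" is read as the ±3σ support;
  whether it means FWHM is an open choice — σ = width/6 is flagged
  here). Class 1: +peak at 60 ± 8 ms, width 50 ± 2 ms; class 2: +peak at
  900 ± 5 ms, width 100 ± 4 ms; class 3: −peak at 500 ± 8 ms, width
  100 ± 4 ms; class 4 as class 3 with the second half of the source
  table. Amplitudes are drawn per epoch from U(1, 13) μV independently
  per class (classes share the law, not the draws); jitters are uniform
  half-widths. Sources: one of 10 paracentral/cingulate dipoles.
* **Spectral (4 classes, band).** White noise band-passed (4th-order
  Butterworth, zero-phase) to 3–8 / 8–13 / 14–30 / 30–58 Hz, scaled to
  RMS = amplitude U(0.5, 3) μV, under a Gaussian envelope centered at
  U(200, 500) ms with width U(400, 600) ms. Sources: one of 14
  sensorimotor dipoles per epoch.
* **Spatial (2 classes, hemisphere).** Each epoch carries one ERP
  (+peak, 500 ± 8 ms, width 100 ± 4 ms, U(1, 13) μV) and one 8–13 Hz
  burst with the shared burst law, on dipoles drawn independently from
  the left (class 1) or right (class 2) entries of the sensorimotor
  table (the one midline entry belongs to neither pool). Epoch counts
  per class are a config parameter; the protocol prints counts only for
  the ERP condition (10,000/class at full scale).

**Ground truth.** The signal waveform(s) alone are forward-projected
through the same lead field; the absolute projection divided by its
maximum is the relevance map, its support (>1e−12 relative, since
floating-point projection never yields exact zeros) the binary mask.
The channel ground truth is the time-summed absolute relevance,
max-normalized — the same reduction applied to attribution maps, so the
ground truth scores cosine similarity 1 against itself; for
single-source epochs the map is rank-one and any time-collapse gives
the same direction.

## Decoder

Five 5×1 temporal convolutions (32 filters, stride 1, unpadded) with
2×1/stride-2 max-pooling after the first four, a 1×62 spatial
convolution placed last (so the channel axis survives to the final
convolutional block and CAM methods can resolve channels), flatten →
dense(32) → dropout 0.5 → softmax. ReLU everywhere except the output.
Temporal lengths: 250→246→123→119→59→55→27→23→11→7; flatten size 224;
receptive field 1 + Σ(kᵢ−1)Πs = 140 samples ≥ 125 (half the sampling
rate). Training recipe (unspecified in the protocol; a package choice):
Adam, lr 1e−3, batch 64, cross-entropy, early stopping on a 10%
stratified validation split, everything seeded; inputs are divided by
one global standard deviation. Five-fold stratified cross-validation;
accuracy reported on each held-out fold.

Randomization controls: *label* control = labels permuted (a bijection)
within the training split, then full retraining; *weight* control = all
parameters re-drawn from the initializer, no retraining.

The engine is plain numpy (im2col GEMMs with persistent scratch
buffers); forward/backward correctness is pinned to a direct-sum
convolution oracle and central finite differences.

## Attribution methods

All methods differentiate the pre-softmax logit of the target class
(softmax saturation would null gradients). Maps are computed for the
trial's true class; sensitivity metrics use correctly classified trials
only (an explanation of a wrong prediction has no ground-truth class),
robustness metrics use all evaluated trials.

* Saliency |∂y_c/∂x| (the conventional saliency map is the gradient
  magnitude; the signed gradient is available); Input×Gradient;
  Deconvolution (ReLU backward passes positive top-down signal, ignoring
  the forward mask); Guided BP (both masks); max-pool switches are
  respected in every backward variant.
* CAM family targets the ReLU output of the *last temporal convolution*
  (7 × 62 × 32) — the deepest layer that still resolves electrodes —
  and upsamples bilinearly along time only (the channel axis has no
  spatial order). GradCAM: spatially averaged gradients as filter
  weights, final ReLU. GradCAM++: the closed-form pixel weights
  g²/(2g² + ΣA·g³) of the exponential-score formulation. LayerCAM: over
  all five temporal convolutions, per-layer maps max-normalized then
  averaged. ScoreCAM: each filter map upsampled, min–max normalized to
  [0,1] (constant maps degenerate to a zero mask), used to mask the
  input; the softmax score of the masked input is the weight (32
  forward passes per trial, run in float32 — only scores are needed).
  Guided GradCAM is the exact elementwise product of its parents.
* FullGrad: |x ⊙ ∇ₓy_c| plus per-layer |b ⊙ ∇_b y_c| maps, each min–max
  normalized before summation; spatially constant (dense-bias) terms
  normalize to zero. The unnormalized signed decomposition reconstructs
  y_c exactly on this ReLU/max-pool network and is exposed separately
  for verification.
* LRP-ε (ε = 1e−6): R_j = Σ_k a_j w_jk/(z_k + ε·sign z_k) R_k per
  linear layer, winner-take-all through pooling, pass-through at ReLU.
  With only ReLU nonlinearities this approximates Input×Gradient
  (Pearson r ≥ 0.99 on the trained decoder), which the tests assert.
* DeepLift, rescale rule, all-zero reference. Multipliers pass through
  linear layers transposed; ReLUs rescale by Δout/Δin (gradient
  fallback below 1e−10); max-pooling routes the multiplier to the
  in-window position with the largest |Δin|, scaled by Δout/Δin at that
  position — a choice that preserves summation-to-delta exactly
  (Σ R = y_c(x) − y_c(0) to machine precision), which the tests assert
  at 1e−4 relative.

Attribution passes run in float64 (training runs in float32) so the
conservation identities are testable at tight tolerances.

## Metrics and flags

RMA = Σ_mask|R| / Σ|R| (absolute relevance: signed methods carry
negative evidence, mass is magnitude; a zero map scores 0 and is
flagged). Cosine similarity on time-summed, max-normalized channel
vectors. Robustness: |Pearson r| on flattened maps (constant maps are
recorded as missing) and SSIM with Gaussian weighting σ = 1.5, the
standard stability constants, and joint per-pair min–max scaling to
[0, 1]. Summary flags per (method, condition): sensitive if mean
sensitivity > 0.55; "not class-specific" red/orange if the mean of the
label-control |r| and SSIM exceeds 0.5 / lies in (0.3, 0.5]; "not
model-specific" **/* likewise for the weight control. The two
similarity metrics are averaged before thresholding (the flag
definition does not say whether they are judged jointly or separately;
averaging is the package's choice).

## Problem sizes in the test suite

The full protocol (10,000 epochs/class × 5 SNR × 5 folds) is desk-scaled
in the tests, which are sized for a single CPU: the high-SNR (−3.5 dB)
accuracy checks train one 80/20 fold on 250 epochs/class (temporal,
spectral) or 300 (spatial), with per-condition epoch caps and early
stopping; the SNR trend uses {−3.5, −12, −23} dB at 75 epochs/class;
ranking checks score 64 held-out trials per method and robustness
checks 24. At these sizes the decoder reaches
within ~2 percentage points of the full-scale accuracies, and the
method *orderings* (DeepLift/LRP/I×G above the CAM family for temporal
precision; GradCAM above Guided BP/Deconvolution for spatial; low
randomization-similarity for DeepLift/LRP/I×G) are stable, while exact
metric magnitudes are not expected to match figure-scale values.

**A known SSIM limitation.** The sparse, signed maps of the
DeepLift/LRP/Input×Gradient family render, after joint min–max scaling,
as near-constant mid-gray images: their local luminance and contrast
statistics agree between *any* two models, so their SSIM similarity
stays high (~0.8–0.9) even across independently randomized networks,
while their Pearson correlation correctly drops to ~0.06. The
randomization (class-/model-specificity) contrasts in this package are
therefore most meaningful on the correlation measure; SSIM remains
informative for the dense non-negative CAM-family maps.

## What the simulation does not capture

No ocular/muscle/line-noise artifacts, no non-stationarity or
context-dependence, no realistic ERP morphology beyond Gaussian tapers,
no correlated background rhythms, and a spherical rather than realistic
head. Passing benchmarks here certify that an attribution method can
recover a known, isolated feature under volume conduction and noise —
not that it explains any particular real-EEG decoder. The framework is
the point: every stage accepts a user lead field and user-defined class
specifications.
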