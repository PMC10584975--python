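# eegxai

A ground-truth benchmark for attribution ("heatmap") explanation methods
applied to EEG deep-learning decoders.

Deep networks decode scalp EEG well, but the attribution maps used to
explain them — saliency, layer-wise relevance propagation, DeepLift, the
class-activation-map family — are usually judged by eye on real data,
where the true discriminative feature is unknown. This package sidesteps
that by **simulating** scalp EEG whose discriminative feature is known
exactly: dipole sources are forward-projected through a lead field
(volume conduction), pink-noise brain sources and white sensor noise are
mixed in at controlled scalp signal-to-noise ratios, and the projected
signal itself is the ground-truth relevance map. A generic CNN decoder is
trained on three conditions — ERP latency (*temporal*), band-limited
oscillatory bursts (*spectral*), and source hemisphere (*spatial*) — and
twelve backpropagation-based attribution methods are scored for

* **sensitivity** — agreement with the ground truth: relevance mass
  accuracy `RMA = R_within / R_total` (the share of total absolute
  relevance inside the ground-truth support), or, for the spatial
  condition, the cosine similarity `A·B / (‖A‖‖B‖)` between channel
  topographies; and
* **robustness** — dissimilarity (absolute Pearson *r* and SSIM) between
  the original explanation and the explanation after retraining on
  permuted labels (class specificity) or re-initializing the weights
  (model specificity).

The twelve methods: saliency/gradient, Deconvolution, Guided
Backpropagation, Input×Gradient, GradCAM, GradCAM++, Guided GradCAM,
LayerCAM, ScoreCAM, FullGrad, LRP-ε, and DeepLift (rescale rule, zero
reference). The decoder is five 5×1 temporal convolutions (32 filters,
2×1/stride-2 max-pooling after the first four) followed by a 1×62 spatial
convolution, a 32-unit dense layer, dropout 0.5, and a softmax readout;
its final convolutional block spans a 140-sample receptive field (more
than half the 250 Hz sampling rate). The CNN engine, its training loop,
and all twelve backward passes are implemented in numpy inside the
package, which gives the explanation methods direct access to the cached
activations and modified ReLU backward rules they need.

## Worked example

```python
import numpy as np
from sklearn.model_selection import train_test_split
from eegxai import simulate, attribution
from eegxai.decoder import EEGDecoder, receptive_field, ArchitectureSpec
from eegxai.evaluate import relevance_mass_accuracy

print(receptive_field(ArchitectureSpec()))

# 100 trials/class of the 4-class ERP-latency condition at -3.5 dB
epochs, gt = simulate.generate_condition("temporal", -3.5, 100, seed=1)
train, test = train_test_split(np.arange(epochs.n_trials), test_size=0.2,
                               stratify=epochs.labels, random_state=0)
dec = EEGDecoder(max_epochs=10, seed=2).fit(epochs.data[train], epochs.labels[train])
acc = 100 * np.mean(dec.predict(epochs.data[test]) == epochs.labels[test])
print(f"test accuracy: {acc:.1f}%")

maps = attribution.attribute(dec, epochs.data[test], epochs.labels[test], "deeplift")
rma = np.mean([relevance_mass_accuracy(m, k)
               for m, k in zip(maps, gt.mask[test])])
print(f"DeepLift RMA: {rma:.2f}")
```

Output (seeds as above):

```
140
test accuracy: 100.0%
DeepLift RMA: 0.19
```

140 is the receptive field in samples; the accuracy shows the decoder
has learned the latency feature from 320 training trials; the RMA says
19% of DeepLift's absolute relevance falls inside the ground-truth
signal window — the window covers only ~9% of the 1 s × 62-channel
grid, which is what a uniformly spread map would score. At this desk
scale the method *ordering* (DeepLift/LRP/I×G above the CAM family for
temporal precision) is stable even though absolute RMA values sit well
below the full-scale study's.

## Full benchmark runs

```bash
eegxai run-all --config exp.yaml     # simulate -> train -> attribute -> evaluate -> report
eegxai report <artifact-dir>         # re-render summary flags + figures
```

The YAML config mirrors `eegxai.cli.ExperimentConfig` (conditions, SNR
grid, trials per class, folds, methods, seeds, training recipe). The
artifact directory contains `epochs/`, `models/`, `attributions/`,
`metrics/metrics.csv`, `summary.json` (per-method sensitivity/robustness
with the 0.55 / 0.5 / 0.3 traffic-light flags) and `figures/`.

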