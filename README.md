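# histoseg

Lightweight semantic segmentation of H&E-stained breast-histology patches,
for researchers who need tumor masks (and benign/malignant calls) on
commodity CPUs rather than GPU clusters. The model is a depthwise-separable
convolution encoder — the familiar inverted-residual stage table, channels
32→16→24→32→64→96→160→320→1280, condensing a 224×224 patch to a 7×7
bottleneck — with a U-Net decoder over skip connections at strides 2–16.
Its per-pixel probability maps are post-processed by semi-supervised label
propagation on an 8-connected pixel graph:

```
w_ij = exp(−‖I_i−I_j‖²/2σ_I²) · exp(−‖x_i−x_j‖²/2σ_x²)
F(t+1) = α S F(t) + (1−α) Y,   S = D^(−1/2) W D^(−1/2),  α = 0.9
```

which converges to F\* = (1−α)(I−αS)⁻¹Y, spreading confident labels into
uncertain regions and cleaning fragmented predictions. Training minimizes
soft Dice, `1 − (2Σpg+ε)/(Σp+Σg+ε)`, plus class-weighted cross-entropy,
with SGD(momentum 0.9) falling back to Adam on a validation-Dice plateau,
class-balanced mini-batches, and patient-grouped stratified
cross-validation so no patient leaks across folds.

Everything runs on a small in-package numpy autodiff engine — no deep
learning framework required — and a synthetic H&E patch generator (stroma,
elliptical nuclei and basophilic tumor foci composed in Beer–Lambert
optical-density space) makes the entire pipeline testable without
downloading any dataset. Real datasets in BreakHis-style or
class/patient-folder layouts are supported through the same manifest
interface.

## Worked example

```python
import numpy as np
import histoseg as hs

# 200 synthetic labelled patches (100 per class), patient-grouped
params = hs.SyntheticParams(image_size=64)
records = hs.generate_dataset(params, 100, seed=1, out_dir="data")
split = hs.stratified_group_split(records, 0.8, seed=1)
train = [records[i] for i in split.indices(0)]
val = [records[i] for i in split.indices(1)]

# tiny (width 0.25) variant, desk-scale configuration
config = hs.TrainConfig(input_size=64, width_multiplier=0.25,
                        max_epochs=30, sgd_lr=0.01)
model = hs.build_model(hs.EncoderConfig(input_size=64, width_multiplier=0.25), seed=0)
model, history = hs.train(model, train, val, config, seed=0)
print(f"best validation Dice {history.best_val_dice:.4f} "
      f"at epoch {history.best_epoch}")

# refine a degraded probability map by label propagation
sample = hs.generate_sample(hs.SyntheticParams(), "malignant", seed=7)
probs = hs.corrupt_probability_map(sample.mask, flip_rate=0.05, blur_sd=1.0, seed=0)
mask, refined = hs.refine_mask(sample.image, probs)
before = hs.segmentation_metrics(probs.argmax(-1), sample.mask.labels).dice
after = hs.segmentation_metrics(mask.labels, sample.mask.labels).dice
print(f"Dice before refinement {before:.3f}, after {after:.3f}")
```

prints (CPU, about two minutes):

```
best validation Dice 0.9633 at epoch 29
Dice before refinement 0.646, after 1.000
```

The first line says the tiny model recovers the synthetic tumor masks almost
perfectly from 160 training patches; the second shows label propagation
repairing a probability map corrupted with 5% confident pixel flips and
boundary blur — isolated wrong seeds are outvoted by their neighbourhood
during diffusion.

The same pipeline is available from the shell:

```
histoseg generate-data --n 100 --seed 1 --out run/
histoseg train --config config.yaml --data run/data --seed 0 --out run/train
histoseg refine --image patch.png --probs probs.npz --alpha 0.9
histoseg gradcam --model run/train/model --image patch.png --target 1
```

Every run directory contains the resolved YAML config snapshot and a
JSON-lines log, so any result can be reproduced from its seed.

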