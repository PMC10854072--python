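# mducnn

Binary semantic segmentation of biomedical images with a
**multi-dimensional U-CNN**: a U-shaped encoder–decoder whose stages are
multi-scale residual blocks and whose skip connections are chains of
residual convolution units, plus a matched baseline U-Net, the full
training/evaluation protocol (pixelwise binary cross-entropy, Jaccard
index, k-fold cross-validation with best-on-test tracking, ×3
flip/rotation augmentation, ablation variants), and a seeded synthetic
data generator emulating five biomedical imaging challenges
(fluorescence microscopy, endoscopy, dermoscopy, electron microscopy,
multi-channel 3D MRI). Everything runs on a compact numpy
automatic-differentiation engine — no GPU or deep-learning framework
required — and is sized to run on one CPU.

It is written for researchers who want to study *the architecture and the
protocol themselves* — channel bookkeeping, parameter budgets, ablations,
cross-validation arithmetic — at desk scale, with exactly reproducible
seeds.

## The model in brief

Each encoder/decoder level owns a width budget M = β·Fₗ (β = 1.56, Fₗ the
matched U-Net stage width), split ⌊M/6⌋, ⌊M/3⌋, ⌊M/2⌋ across three chained
3×3 convolutions whose outputs are concatenated (approximating parallel
3×3/5×5/7×7 receptive fields) and summed with a 1×1 residual projection of
the block input. Skip connections are chains of residual units — more
units at shallower levels (4, 3, 2, 1) — that narrow the semantic gap
between encoder and decoder features. Training minimizes pixelwise binary
cross-entropy

    CE(A, B, B̂) = Σₚ −(bₚ log b̂ₚ + (1−bₚ) log(1−b̂ₚ)),

and evaluation is the Jaccard index JI = |X∩Y| / |X∪Y| of predicted vs.
true foreground after thresholding at 0.5. The scaling β = 1.56 keeps the
model lighter than the matched U-Net: the built 2D model has **7,420,894**
trainable parameters vs. **7,781,617** for the baseline.

See `docs/methods.md` for the full model description, protocol details and
design decisions.

## Worked example

```python
from mducnn import (OptimizerConfig, ScheduleConfig, SyntheticConfig,
                    build_model, generate, train_model)
from mducnn.models import mdu_config

data = generate(SyntheticConfig.preset("fluorescence", size=(64, 64),
                                       n_images=40, seed=7)).samples
cfg = mdu_config(2, depth=3, schedule=ScheduleConfig(
    mode="formula", base_filters=(8, 16, 32, 64)))   # width-reduced
model = build_model(cfg)
result = train_model(model, data[:32], data[32:],
                     OptimizerConfig(epochs=5, batch_size=8, seed=1))
print(f"best test Jaccard: {result.best_jaccard:.2f}% "
      f"at epoch {result.best_epoch}")
```

prints (≈1 minute on one CPU):

```
best test Jaccard: 68.40% at epoch 5
```

i.e. after five epochs on 32 high-contrast synthetic images the model's
predicted foreground overlaps the true foreground at IoU 0.68 on the 8
held-out images; the desk-scale acceptance run below (120 images, 15
epochs, 5-fold CV) reaches a mean best Jaccard above 90%. The `examples/`
directory has one short narrative script per capability:

| script | shows |
|---|---|
| `01_filter_schedule.py` | the β·F width calculus and the published table |
| `02_models_and_parameters.py` | building 2D/3D models, parameter accounting |
| `03_synthetic_presets.py` | the five imaging-challenge presets |
| `04_train_and_evaluate.py` | training + best-on-test Jaccard |
| `05_cross_validation.py` | k-fold CV and model comparison |

A thin CLI wraps the same library calls, e.g.

```sh
mducnn build --model mdu --summary summary.csv
mducnn synth --preset endoscopy --n 30 --size 48 --seed 7 --out data/
mducnn cv --k 3 --models mdu,unet --data data/manifest.csv --size 48 --epochs 6
```

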