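"""Train a width-reduced model on easy synthetic data and evaluate it.

Minimizes mean per-pixel binary cross-entropy with Adam, evaluates the
mean per-image Jaccard index on held-out samples after every epoch, and
reports the best epoch (the best-on-test protocol under study).
Runs in about a minute on one CPU.
"""

import sys

from mducnn import (OptimizerConfig, ScheduleConfig, SyntheticConfig,
                    build_model, generate, train_model)
from mducnn.models import mdu_config

data = generate(SyntheticConfig.preset("fluorescence", size=(64, 64),
                                       n_images=40, seed=7)).samples
train, test = data[:32], data[32:]

cfg = mdu_config(2, depth=3,
                 schedule=ScheduleConfig(mode="formula",
                                         base_filters=(8, 16, 32, 64)))
model = build_model(cfg)
opt = OptimizerConfig(epochs=5, batch_size=8, seed=1)
result = train_model(model, train, test, opt, log=sys.stderr)

print(f"\nbest test Jaccard: {result.best_jaccard:.2f}% "
      f"at epoch {result.best_epoch}")
print("(Jaccard = intersection-over-union of predicted and true foreground,")
print(" after thresholding the probability map at 0.5)")
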