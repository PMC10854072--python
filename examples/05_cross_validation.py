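"""Compare two models with k-fold cross-validation, study style.

Every sample is tested exactly once; each fold trains a fresh seeded
model; per-fold best test Jaccard percentages are aggregated to
mean +/- sample standard deviation, and the models are compared by the
simple difference of their means ("comparative increase", in percentage
points).  A few minutes on one CPU.
"""

import sys

from mducnn import (OptimizerConfig, ScheduleConfig, SyntheticConfig,
                    compare_models, cross_validate, generate)
from mducnn.models import mdu_config, unet_config

data = generate(SyntheticConfig.preset("endoscopy", size=(48, 48),
                                       n_images=30, seed=5)).samples
opt = OptimizerConfig(epochs=6, batch_size=8, seed=2)

mdu = mdu_config(2, depth=3, schedule=ScheduleConfig(
    mode="formula", base_filters=(8, 16, 32, 64)))
unet = unet_config(2, depth=3, unet_widths=(8, 16, 32, 64))

rep_mdu = cross_validate(mdu, data, k=3, opt=opt, seed=9, name="MDU", log=sys.stderr)
rep_unet = cross_validate(unet, data, k=3, opt=opt, seed=9, name="U-Net", log=sys.stderr)

print(f"\nmulti-dimensional model: {rep_mdu.mean:.2f}% +/- {rep_mdu.std:.2f}")
print(f"baseline U-Net:          {rep_unet.mean:.2f}% +/- {rep_unet.std:.2f}")
cmp = compare_models(rep_mdu, rep_unet)
print(f"comparative increase:    {cmp['comparative_increase']:+.2f} points")
print("(positive favors the multi-dimensional model; at this miniature")
print(" scale — 30 images, 6 epochs — either model can lead, and the")
print(" fold-to-fold spread is large; longer budgets favor the deeper")
print(" multi-scale blocks)")
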