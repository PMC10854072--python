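"""Build the 2D/3D models and compare their parameter budgets.

The multi-dimensional model must stay lighter than the matched baseline
U-Net — that is the point of the beta = 1.56 width scaling.
"""

import numpy as np

from mducnn import (build_baseline_unet, build_mdu_cnn, count_parameters,
                    predict)

mdu2 = build_mdu_cnn()
unet2 = build_baseline_unet()
print("2D multi-dimensional model:", f"{count_parameters(mdu2).total_trainable:,}")
print("2D baseline U-Net:        ", f"{count_parameters(unet2).total_trainable:,}")

mdu3 = build_mdu_cnn(rank=3)
print("3D multi-dimensional model:", f"{count_parameters(mdu3).total_trainable:,}")

s = count_parameters(mdu2)
print(f"\naccounting modes: trainable {s.total_trainable:,}; "
      f"with batch-norm running statistics {s.total_all:,}")

x = np.random.default_rng(0).random((1, 64, 64, 3)).astype(np.float32)
p = predict(mdu2, x)
print(f"\nforward pass: {x.shape} -> {p.shape}, "
      f"probabilities in [{p.min():.3f}, {p.max():.3f}]")
print("(same spatial extents in and out; one sigmoid foreground channel)")
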