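"""Model assembly: the multi-dimensional U-CNN, the baseline U-Net, and the
two ablation hybrids, for spatial rank 2 and 3.

One generic encoder-decoder skeleton (:class:`SegmentationNet`) is
parameterized by the stage type (multi-dimensional block vs. classical
double-conv) and the skip type (residual convolution path vs. plain
shortcut), which yields all four variants of the ablation matrix:

======================  ==============  =============
variant                 stage blocks    skip paths
======================  ==============  =============
``mdu``                 multidim        respath
``unet`` (baseline)     double conv     plain
``blocks_only``         multidim        plain
``paths_only``          double conv     respath
======================  ==============  =============

Decoder upsampling uses a kernel-2/stride-2 transposed convolution whose
output width equals the skip connection's channel count at the target level,
so the decoder always concatenates two equally wide feature maps.  (Routing
the upsample to the level's full schedule sum instead is available via
``up_channels="schedule"`` but makes the 2D model heavier than the matched
baseline U-Net, defeating its design goal.)

The output head is a 1-kernel convolution with a sigmoid, producing one
foreground-probability channel.
"""

from __future__ import annotations

import dataclasses
import io
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import nn
from .blocks import DoubleConv, Downsample, MultiDimBlock, SkipPath, Upsample2x
from .nn import Tensor
from .schedule import (TABLE_PATH_WIDTHS, LevelAllocation, PathPlan,
                       ScheduleConfig, build_schedule, path_plan)

__all__ = [
    "ModelConfig", "SegmentationNet", "ModelSummary",
    "build_mdu_cnn", "build_baseline_unet", "build_model",
    "count_parameters", "predict", "save_weights", "load_weights",
]

_DEFAULT_UNET_WIDTHS_2D = (16, 32, 64, 128, 256, 512)


@dataclass(frozen=True)
class ModelConfig:
    """Recipe for one network.

    ``depth`` counts pooling operations; a model has ``depth + 1`` stage
    levels.  Defaults follow the study setup: 2D multi-dimensional model
    depth 4 with the published (table-literal) schedule; baseline 2D U-Net
    depth 5 with stage widths 16..512; every 3D variant reduces depth by
    one, and the 3D baseline doubles its filters before pooling.
    """

    rank: int = 2
    depth: int = 4
    in_channels: int = 3
    out_classes: int = 1
    blocks: str = "multidim"            # "multidim" | "double"
    skips: str = "respath"              # "respath" | "plain"
    schedule: ScheduleConfig = field(default_factory=ScheduleConfig)
    path_widths: tuple[int, ...] | None = None
    unet_widths: tuple[int, ...] = _DEFAULT_UNET_WIDTHS_2D
    double_before_pool: bool = False
    up_channels: str = "skip"           # "skip" | "schedule"
    batch_norm: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.rank not in (2, 3):
            raise ValueError("rank must be 2 or 3")
        if self.out_classes != 1:
            raise ValueError("only binary segmentation (out_classes=1) is supported")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.blocks not in ("multidim", "double"):
            raise ValueError("blocks must be 'multidim' or 'double'")
        if self.skips not in ("respath", "plain"):
            raise ValueError("skips must be 'respath' or 'plain'")
        if self.up_channels not in ("skip", "schedule"):
            raise ValueError("up_channels must be 'skip' or 'schedule'")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schedule"] = dataclasses.asdict(self.schedule)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        sched = d.pop("schedule", None)
        if isinstance(sched, dict):
            sched = {k: tuple(v) if isinstance(v, list) else v for k, v in sched.items()}
            sched = ScheduleConfig(**sched)
        kw = {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}
        if sched is not None:
            kw["schedule"] = sched
        return cls(**kw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ModelConfig":
        return cls.from_dict(yaml.safe_load(text))


def mdu_config(rank: int = 2, **overrides) -> ModelConfig:
    """Study-default multi-dimensional U-CNN configuration."""
    if rank == 2:
        base = dict(rank=2, depth=4, in_channels=3,
                    schedule=ScheduleConfig(mode="table_literal"))
    else:
        base = dict(rank=3, depth=3, in_channels=4,
                    schedule=ScheduleConfig(mode="formula",
                                            base_filters=(32, 64, 128, 256)))
    base.update(blocks="multidim", skips="respath")
    base.update(overrides)
    return ModelConfig(**base)


def unet_config(rank: int = 2, **overrides) -> ModelConfig:
    """Study-default baseline U-Net configuration."""
    if rank == 2:
        base = dict(rank=2, depth=5, in_channels=3,
                    unet_widths=_DEFAULT_UNET_WIDTHS_2D)
    else:
        base = dict(rank=3, depth=4, in_channels=4,
                    unet_widths=_DEFAULT_UNET_WIDTHS_2D[:5], double_before_pool=True)
    base.update(blocks="double", skips="plain")
    base.update(overrides)
    return ModelConfig(**base)


class SegmentationNet(nn.Module):
    """Generic U-shaped encoder-decoder; see module docstring for variants.

    ``level_channels`` records the per-level channel bookkeeping
    (encoder_out, skip_out, up_out, decoder_in, decoder_out), shallowest
    level first, for inspection and tests.
    """

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        r, d, bn = config.rank, config.depth, config.batch_norm
        levels = d + 1

        if config.blocks == "multidim":
            sched = config.schedule
            if sched.mode == "table_literal" and levels != 5:
                sched = dataclasses.replace(sched, mode="formula")
            allocs = build_schedule(sched, levels)
            enc_out = [a.res1_filters for a in allocs]
        else:
            if len(config.unet_widths) < levels:
                raise ValueError(f"unet_widths has {len(config.unet_widths)} entries, "
                                 f"need {levels}")
            widths = list(config.unet_widths[:levels])
            enc_out = [2 * w if config.double_before_pool else w for w in widths]
            allocs = None

        if config.path_widths is not None:
            pw = list(config.path_widths)
            if len(pw) < d:
                raise ValueError(f"path_widths needs {d} entries")
        elif config.blocks == "multidim":
            if config.schedule.mode == "table_literal" and levels == 5:
                pw = list(TABLE_PATH_WIDTHS)
            else:
                pw = list(config.schedule.base_filters[:d])
        else:
            pw = enc_out[:d]
        self.path_plan: PathPlan = path_plan(d, pw)
        self.allocations: list[LevelAllocation] | None = allocs

        def make_stage(cin, level):
            if config.blocks == "multidim":
                return MultiDimBlock(r, cin, allocs[level], rng, bn)
            w = config.unet_widths[level]
            out = enc_out[level]
            return DoubleConv(r, cin, out, rng, bn,
                              mid_ch=w if config.double_before_pool else None)

        # encoder
        cin = config.in_channels
        for l in range(d):
            setattr(self, f"enc{l + 1}", make_stage(cin, l))
            cin = enc_out[l]
        self.pool = Downsample()
        self.bottleneck = make_stage(cin, d)

        # skip connections
        skip_out = []
        for l in range(d):
            if config.skips == "respath":
                setattr(self, f"skip{l + 1}",
                        SkipPath(r, enc_out[l], self.path_plan.unit_counts[l],
                                 self.path_plan.unit_widths[l], rng, bn))
                skip_out.append(self.path_plan.unit_widths[l])
            else:
                skip_out.append(enc_out[l])

        # decoder (deepest first)
        self.level_channels: list[dict] = []
        cur = enc_out[d]
        dec_in, up_out_rec = [None] * d, [None] * d
        for l in range(d - 1, -1, -1):
            up_out = skip_out[l] if config.up_channels == "skip" else enc_out[l]
            setattr(self, f"up{l + 1}", Upsample2x(r, cur, up_out, rng))
            cat = up_out + skip_out[l]
            setattr(self, f"dec{l + 1}", make_stage(cat, l))
            dec_in[l], up_out_rec[l] = cat, up_out
            cur = enc_out[l]
        self.head = nn.Conv(r, enc_out[0], config.out_classes, 1, rng)

        for l in range(d):
            self.level_channels.append(dict(
                level=l + 1, encoder_out=enc_out[l], skip_out=skip_out[l],
                up_out=up_out_rec[l], decoder_in=dec_in[l], decoder_out=enc_out[l]))
        self.level_channels.append(dict(level=d + 1, encoder_out=enc_out[d],
                                        skip_out=None, up_out=None,
                                        decoder_in=None, decoder_out=None))

    def forward(self, x: Tensor) -> Tensor:
        d = self.config.depth
        self._check_input(x.data.shape)
        skips = []
        for l in range(d):
            x = getattr(self, f"enc{l + 1}")(x)
            skips.append(x)
            x = self.pool(x)
        x = self.bottleneck(x)
        for l in range(d - 1, -1, -1):
            u = getattr(self, f"up{l + 1}")(x)
            s = skips[l]
            if self.config.skips == "respath":
                s = getattr(self, f"skip{l + 1}")(s)
            x = getattr(self, f"dec{l + 1}")(nn.concat([u, s]))
        return nn.sigmoid(self.head(x))

    def _check_input(self, shape) -> None:
        cfg = self.config
        if len(shape) != cfg.rank + 2:
            raise ValueError(f"expected rank-{cfg.rank} batch (B, *spatial, C), got {shape}")
        if shape[-1] != cfg.in_channels:
            raise ValueError(f"expected {cfg.in_channels} channels, got {shape[-1]}")
        div = 2 ** cfg.depth
        for s in shape[1:-1]:
            if s % div:
                raise ValueError(f"spatial extent {s} not divisible by 2^depth = {div}")


def build_mdu_cnn(config: ModelConfig | None = None, **overrides) -> SegmentationNet:
    """Build the multi-dimensional U-CNN (study defaults when no config)."""
    if config is None:
        config = mdu_config(overrides.pop("rank", 2), **overrides)
    if config.blocks != "multidim" or config.skips != "respath":
        raise ValueError("config does not describe a multi-dimensional U-CNN")
    return SegmentationNet(config)


def build_baseline_unet(config: ModelConfig | None = None, **overrides) -> SegmentationNet:
    """Build the matched baseline U-Net (study defaults when no config)."""
    if config is None:
        config = unet_config(overrides.pop("rank", 2), **overrides)
    if config.blocks != "double" or config.skips != "plain":
        raise ValueError("config does not describe a baseline U-Net")
    return SegmentationNet(config)


def build_model(config: ModelConfig) -> SegmentationNet:
    """Build whatever variant ``config`` describes."""
    return SegmentationNet(config)


# ---------------------------------------------------------------------------
# parameter accounting


@dataclass
class ModelSummary:
    """Per-layer parameter accounting.

    ``total_trainable`` counts weights, biases and batch-norm scale/shift;
    ``total_all`` additionally counts the batch-norm running statistics.
    Output spatial extents are input-dependent, so rows report the layer's
    output channel count.
    """

    rows: list[dict]
    total_trainable: int
    total_all: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        doc = {"layers": self.rows, "total_trainable": self.total_trainable,
               "total_all": self.total_all}
        if path is None:
            return json.dumps(doc, indent=2)
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2)

    def __str__(self) -> str:
        buf = io.StringIO()
        buf.write(f"{'layer':40s} {'kind':14s} {'out_ch':>7s} {'trainable':>10s}\n")
        for r in self.rows:
            buf.write(f"{r['name']:40s} {r['kind']:14s} {r['out_channels']:>7d} "
                      f"{r['trainable']:>10d}\n")
        buf.write(f"total trainable: {self.total_trainable:,}\n")
        buf.write(f"total incl. batch-norm running stats: {self.total_all:,}\n")
        return buf.getvalue()


def count_parameters(model: SegmentationNet) -> ModelSummary:
    """Enumerate every layer's parameter arrays and sum their sizes."""
    rows = []
    for name, mod in model.named_modules():
        if isinstance(mod, nn.Conv):
            n = mod.weight.data.size + (mod.bias.data.size if mod.bias is not None else 0)
            kind = "conv" + "x".join([str(mod.kernel)] * mod.rank)
            rows.append(dict(name=name, kind=kind,
                             out_channels=mod.out_channels, trainable=n, total=n))
        elif isinstance(mod, nn.ConvTranspose2x):
            n = mod.weight.data.size + (mod.bias.data.size if mod.bias is not None else 0)
            rows.append(dict(name=name, kind="conv_transpose",
                             out_channels=mod.out_channels, trainable=n, total=n))
        elif isinstance(mod, nn.BatchNorm):
            n = mod.gamma.data.size + mod.beta.data.size
            rows.append(dict(name=name, kind="batch_norm", out_channels=mod.channels,
                             trainable=n, total=n + 2 * mod.channels))
    total_trainable = sum(r["trainable"] for r in rows)
    total_all = sum(r["total"] for r in rows)
    check = sum(p.data.size for p in model.parameters())
    assert total_trainable == check, "registry does not cover every parameter"
    return ModelSummary(rows=rows, total_trainable=total_trainable, total_all=total_all)


# ---------------------------------------------------------------------------
# inference and weight I/O


def predict(model: SegmentationNet, batch: np.ndarray) -> np.ndarray:
    """Run deterministic inference; returns per-pixel probabilities in [0,1]."""
    model.eval()
    with nn.no_grad():
        out = model(Tensor(np.asarray(batch, dtype=np.float32)))
    return out.data


def save_weights(model: SegmentationNet, path) -> None:
    """Write every parameter and buffer plus the embedded config to ``path``
    (a single ``.npz`` archive)."""
    state = {f"param/{k}": v for k, v in model.state_dict().items()}
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_weights(model: SegmentationNet, path) -> SegmentationNet:
    """Load a weight archive into ``model``; the archived config must match."""
    try:
        with np.load(path) as npz:
            stored = {k: npz[k] for k in npz.files}
    except Exception as exc:
        raise IOError(f"cannot read weight archive {path}: {exc}") from exc
    if "__config__" not in stored:
        raise IOError(f"{path} is not a weight archive (missing embedded config)")
    stored_cfg = ModelConfig.from_dict(
        json.loads(bytes(stored.pop("__config__")).decode()))
    if stored_cfg != model.config:
        raise ValueError("archived config does not match the model "
                         f"(archive: rank={stored_cfg.rank}, "
                         f"depth={stored_cfg.depth}; "
                         f"model: rank={model.config.rank}, depth={model.config.depth})")
    state = {k[len("param/"):]: v for k, v in stored.items()}
    model.load_state_dict(state)
    return model
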