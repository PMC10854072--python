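"""Training and evaluation protocol: k-fold cross-validation with
best-on-test tracking, ablation variants, and the augmentation study.

The protocol mirrors the study design: each fold trains a freshly
initialized model by minimizing the mean per-pixel binary cross-entropy
with adaptive-moment gradient descent, evaluates the mean per-image test
Jaccard index (after thresholding at 0.5) at the end of every epoch, and
reports the *best* test Jaccard seen across all epochs.  Note that
best-on-test selection peeks at the test set; it is reproduced here as the
protocol under study and flagged in reports (``protocol="best_on_test"``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import nn
from .data import AugmentConfig, augment_dataset
from .metrics import (SegmentationSample, aggregate_folds, binarize,
                      comparative_increase, jaccard)
from .models import ModelConfig, SegmentationNet, build_model
from .nn import Tensor, bce_loss
from .nn.optim import Adam

__all__ = ["OptimizerConfig", "FoldAssignment", "EpochRecord", "FoldResult",
           "CVReport", "kfold_split", "train_model", "cross_validate",
           "compare_models", "run_variants", "run_augmentation_study"]


@dataclass(frozen=True)
class OptimizerConfig:
    """Adaptive-moment optimizer and training-loop settings.

    ``alpha1``/``alpha2`` are the first/second-moment decay rates.  The
    protocol default is 150 epochs; desk-scale runs pass fewer.
    """

    learning_rate: float = 1e-3
    alpha1: float = 0.9
    alpha2: float = 0.999
    batch_size: int = 8
    epochs: int = 150
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.alpha1 < 1 and 0 < self.alpha2 < 1):
            raise ValueError("moment decay rates must lie in (0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass(frozen=True)
class FoldAssignment:
    """Disjoint test-index sets covering the dataset."""

    k: int
    folds: tuple[tuple[int, ...], ...]
    seed: int

    def train_indices(self, fold: int) -> list[int]:
        return [i for j, f in enumerate(self.folds) if j != fold for i in f]


@dataclass(frozen=True)
class EpochRecord:
    epoch: int
    train_loss: float
    test_jaccard: float


@dataclass
class FoldResult:
    fold: int
    records: list[EpochRecord]
    best_jaccard: float   # percent
    best_epoch: int

    @classmethod
    def from_records(cls, fold: int, records: list[EpochRecord]) -> "FoldResult":
        best = max(records, key=lambda r: r.test_jaccard)
        return cls(fold=fold, records=records,
                   best_jaccard=100.0 * best.test_jaccard, best_epoch=best.epoch)


@dataclass
class CVReport:
    """Per-fold best Jaccard percentages with mean +/- sample std."""

    model: str
    fold_results: list[FoldResult]
    protocol: str = "best_on_test"

    @property
    def per_fold(self) -> list[float]:
        return [f.best_jaccard for f in self.fold_results]

    @property
    def mean(self) -> float:
        return aggregate_folds(self.per_fold)[0]

    @property
    def std(self) -> float:
        return aggregate_folds(self.per_fold)[1]

    def row(self) -> dict:
        row = {"Type": self.model}
        row.update({f"F = {i + 1}": round(v, 4) for i, v in enumerate(self.per_fold)})
        row["Avg"] = round(self.mean, 4)
        return row


def kfold_split(n: int, k: int, seed: int) -> FoldAssignment:
    """Seeded shuffle then contiguous slicing into ``k`` disjoint folds.

    Sizes differ by at most one; the remainder goes to the earliest folds.
    """
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    order = np.random.default_rng(seed).permutation(n)
    base, rem = divmod(n, k)
    folds, start = [], 0
    for j in range(k):
        size = base + (1 if j < rem else 0)
        folds.append(tuple(int(i) for i in order[start:start + size]))
        start += size
    return FoldAssignment(k=k, folds=tuple(folds), seed=seed)


def _stack(samples: list[SegmentationSample]):
    x = np.stack([s.image for s in samples]).astype(np.float32)
    y = np.stack([s.mask for s in samples]).astype(np.float32)[..., None]
    return x, y


def evaluate_jaccard(model: SegmentationNet, samples: list[SegmentationSample],
                     batch_size: int = 8, threshold: float = 0.5) -> float:
    """Mean per-image Jaccard of thresholded predictions (eval mode)."""
    model.eval()
    scores = []
    with nn.no_grad():
        for i in range(0, len(samples), batch_size):
            chunk = samples[i:i + batch_size]
            x, _ = _stack(chunk)
            pred = model(Tensor(x)).data[..., 0]
            for s, p in zip(chunk, pred):
                scores.append(jaccard(binarize(p, threshold), s.mask))
    return float(np.mean(scores))


def train_model(model: SegmentationNet, train: list[SegmentationSample],
                test: list[SegmentationSample], opt: OptimizerConfig,
                fold: int = 0, log=None) -> FoldResult:
    """Train with per-epoch test evaluation and best-on-test tracking."""
    if not train or not test:
        raise ValueError("train and test sets must be non-empty")
    optimizer = Adam(model.parameters(), lr=opt.learning_rate,
                     alpha1=opt.alpha1, alpha2=opt.alpha2)
    rng = np.random.default_rng(opt.seed)
    x_all, y_all = _stack(train)
    records = []
    for epoch in range(1, opt.epochs + 1):
        model.train()
        order = rng.permutation(len(train))
        losses = []
        for i in range(0, len(order), opt.batch_size):
            idx = order[i:i + opt.batch_size]
            loss = bce_loss(model(Tensor(x_all[idx])), y_all[idx], reduction="mean")
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at fold {fold}, epoch {epoch}: {loss.data!r}")
            model.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        test_j = evaluate_jaccard(model, test, opt.batch_size)
        records.append(EpochRecord(epoch=epoch, train_loss=float(np.mean(losses)),
                                   test_jaccard=test_j))
        if log is not None:
            print(f"fold {fold} epoch {epoch:3d} loss {np.mean(losses):.4f} "
                  f"test JI {test_j:.4f}", file=log)
    return FoldResult.from_records(fold, records)


def cross_validate(model_config: ModelConfig, samples: list[SegmentationSample],
                   k: int, opt: OptimizerConfig, seed: int,
                   name: str | None = None, log=None) -> CVReport:
    """k-fold cross-validation: fresh model per fold, every sample tested
    exactly once."""
    if len(samples) < k:
        raise ValueError(f"dataset of {len(samples)} samples cannot be split "
                         f"into {k} folds")
    assignment = kfold_split(len(samples), k, seed)
    results = []
    for j in range(k):
        test_idx = set(assignment.folds[j])
        train_idx = assignment.train_indices(j)
        assert not test_idx.intersection(train_idx), "train/test overlap"
        model = build_model(replace(model_config, seed=model_config.seed + j))
        fold_opt = replace(opt, seed=opt.seed + j)
        try:
            results.append(train_model(
                model, [samples[i] for i in train_idx],
                [samples[i] for i in test_idx], fold_opt, fold=j + 1, log=log))
        except Exception as exc:
            raise RuntimeError(f"fold {j + 1}/{k} failed: {exc}") from exc
    return CVReport(model=name or model_config.blocks, fold_results=results)


def compare_models(proposed: CVReport, traditional: CVReport) -> dict:
    """Study-style comparison row: means +/- std and comparative increase."""
    return {
        "proposed_mean": proposed.mean, "proposed_std": proposed.std,
        "traditional_mean": traditional.mean, "traditional_std": traditional.std,
        "comparative_increase": comparative_increase(proposed.mean, traditional.mean),
    }


# ---------------------------------------------------------------------------
# experiment matrices


ABLATION_VARIANTS = {
    "Traditional U-Net": dict(blocks="double", skips="plain"),
    "Only encoder-decoder path": dict(blocks="double", skips="respath"),
    "Only encoder-decoder convolution block": dict(blocks="multidim", skips="plain"),
    "MDU-CNN": dict(blocks="multidim", skips="respath"),
}


def run_variants(samples: list[SegmentationSample], k: int, opt: OptimizerConfig,
                 base_config: ModelConfig, unet_config: ModelConfig | None = None,
                 seed: int = 0, log=None) -> tuple[pd.DataFrame, dict[str, CVReport]]:
    """Run the four-variant ablation matrix under identical folds.

    ``base_config`` supplies the shared geometry (rank/depth/channels/
    schedule); ``unet_config`` optionally overrides widths for the
    double-conv variants.  Returns a table with one row per variant
    (columns ``F = 1..k`` and ``Avg``) and the underlying reports.
    """
    reports = {}
    for label, combo in ABLATION_VARIANTS.items():
        cfg = base_config if combo["blocks"] == "multidim" else (unet_config or base_config)
        cfg = replace(cfg, **combo)
        reports[label] = cross_validate(cfg, samples, k, opt, seed, name=label, log=log)
    table = pd.DataFrame([r.row() for r in reports.values()])
    return table, reports


def run_augmentation_study(samples: list[SegmentationSample], k: int,
                           opt: OptimizerConfig, mdu_cfg: ModelConfig,
                           unet_cfg: ModelConfig, factor: int = 3,
                           seed: int = 0, log=None) -> tuple[pd.DataFrame, dict]:
    """With/without-augmentation comparison of the two main models.

    Folds are split on the original samples; only each fold's *training*
    half is augmented (x ``factor``), so no augmented copy of a test image
    leaks into training.
    """
    assignment = kfold_split(len(samples), k, seed)
    aug_cfg = AugmentConfig(factor=factor, seed=seed)

    def run(config: ModelConfig, augmented: bool, name: str) -> CVReport:
        results = []
        for j in range(k):
            train = [samples[i] for i in assignment.train_indices(j)]
            test = [samples[i] for i in assignment.folds[j]]
            if augmented:
                train = augment_dataset(train, aug_cfg)
            model = build_model(replace(config, seed=config.seed + j))
            results.append(train_model(model, train, test,
                                       replace(opt, seed=opt.seed + j),
                                       fold=j + 1, log=log))
        return CVReport(model=name, fold_results=results)

    reports = {
        ("Without DA", "Traditional U-Net"): run(unet_cfg, False, "Traditional U-Net"),
        ("Without DA", "MDU-CNN"): run(mdu_cfg, False, "MDU-CNN"),
        ("With DA", "Traditional U-Net"): run(unet_cfg, True, "Traditional U-Net"),
        ("With DA", "MDU-CNN"): run(mdu_cfg, True, "MDU-CNN"),
    }
    rows = []
    for (da, label), rep in reports.items():
        row = rep.row()
        row["Type"] = f"{da} {label}"
        rows.append(row)
    return pd.DataFrame(rows), reports
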