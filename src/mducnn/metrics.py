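"""Training objective, evaluation metric, and report arithmetic.

The objective is pixelwise binary cross-entropy: for an image ``A`` with
binary ground truth ``B`` and predicted probability map ``B-hat``,

    CE(A, B, B-hat) = sum over pixels of -(b log b-hat + (1-b) log(1-b-hat)),

and the batch loss is the arithmetic mean of the per-image CE over the
``m`` images of a batch.  The literal objective is the unnormalized pixel
sum; a per-pixel mean (``reduction="mean"``, scale-stable across image
sizes) is the default for training and equals the sum divided by the pixel
count exactly.

The evaluation metric is the Jaccard index ``|X∩Y| / |X∪Y|`` of the
predicted and ground-truth foreground pixel sets, computed after
thresholding the probability map at 0.5 (ties to foreground).  When both
masks are empty the index is defined as 1.0.

Cross-validation summaries report mean and sample standard deviation
(n-1 denominator) of per-fold best Jaccard percentages, and the
"comparative increase" of a proposed over a traditional model is the simple
difference of their mean percentages, in percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SegmentationSample", "pixel_bce", "batch_loss", "binarize", "jaccard",
    "aggregate_folds", "comparative_increase", "BCE_EPS",
]

BCE_EPS = 1e-7


@dataclass
class SegmentationSample:
    """An intensity image/volume in [0,1] with its binary mask.

    ``image`` is channels-last ``(*spatial, channels)``; ``mask`` is
    ``(*spatial,)`` with values in {0, 1}.  ``meta`` carries provenance
    (file paths, generator parameters).
    """

    image: np.ndarray
    mask: np.ndarray
    meta: dict | None = None

    def __post_init__(self):
        self.image = np.asarray(self.image)
        self.mask = np.asarray(self.mask)
        if self.image.shape[:-1] != self.mask.shape:
            raise ValueError(f"image spatial extents {self.image.shape[:-1]} "
                             f"do not match mask {self.mask.shape}")
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask must be strictly binary")

    @property
    def rank(self) -> int:
        return self.mask.ndim


def _check_pair(target: np.ndarray, pred: np.ndarray) -> None:
    if target.shape != pred.shape:
        raise ValueError(f"shape mismatch: target {target.shape} vs prediction {pred.shape}")


def pixel_bce(target: np.ndarray, pred: np.ndarray, reduction: str = "sum") -> float:
    """Pixelwise binary cross-entropy of one image.

    ``target`` may be a :class:`SegmentationSample` (its mask is used) or a
    binary array.  ``reduction="sum"`` is the literal pixel sum; ``"mean"``
    divides by the pixel count, so ``sum = mean * n_pixels`` exactly.
    Predictions are clamped to ``[BCE_EPS, 1 - BCE_EPS]``.
    """
    if isinstance(target, SegmentationSample):
        target = target.mask
    target = np.asarray(target, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    _check_pair(target, pred)
    if reduction not in ("sum", "mean"):
        raise ValueError("reduction must be 'sum' or 'mean'")
    p = np.clip(pred, BCE_EPS, 1.0 - BCE_EPS)
    total = float(-(target * np.log(p) + (1.0 - target) * np.log1p(-p)).sum())
    return total if reduction == "sum" else total / target.size


def batch_loss(targets: list[np.ndarray], preds: list[np.ndarray],
               reduction: str = "sum") -> float:
    """Mean of the per-image cross-entropies over a batch of ``m`` images."""
    if len(targets) == 0:
        raise ValueError("batch_loss of an empty batch is undefined")
    if len(targets) != len(preds):
        raise ValueError("targets and predictions must align")
    return sum(pixel_bce(t, p, reduction) for t, p in zip(targets, preds)) / len(targets)


def binarize(pred: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold a probability map; ties (== threshold) go to foreground."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    return (np.asarray(pred) >= threshold).astype(np.uint8)


def jaccard(x: np.ndarray, y: np.ndarray) -> float:
    """Intersection-over-union of two binary masks; 1.0 when both empty."""
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    _check_pair(x, y)
    union = np.logical_or(x, y).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(x, y).sum() / union)


def aggregate_folds(values) -> tuple[float, float]:
    """Mean and sample (n-1) standard deviation of per-fold percentages."""
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least two folds to aggregate")
    return float(values.mean()), float(values.std(ddof=1))


def comparative_increase(proposed_mean: float, traditional_mean: float) -> float:
    """Improvement of the proposed over the traditional model, in
    percentage points (simple difference of the mean percentages)."""
    if not (np.isfinite(proposed_mean) and np.isfinite(traditional_mean)):
        raise ValueError("means must be finite")
    return proposed_mean - traditional_mean
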