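"""Dataset handling: manifests, standardization, and flip/rotation
augmentation.

Standardization follows the study protocol: 2D images are divided by 255
(intensities end up in [0,1]) and resized to the dataset's target extents;
3D volumes are min-max scaled per volume.  Masks are resized with the same
interpolation and re-binarized at 0.5 afterwards, so they stay strictly
binary.

Augmentation multiplies a training set by an integer factor using random
horizontal/vertical flips and right-angle rotations (mask-exact transforms);
the identical transform is applied to an image and its mask.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

from .metrics import SegmentationSample

__all__ = ["DatasetManifest", "AugmentConfig", "load_and_standardize",
           "augment_dataset", "save_dataset", "read_manifest_csv"]


@dataclass
class DatasetManifest:
    """A dataset: either in-memory samples or (image, mask) path pairs.

    ``target_size`` is the per-axis spatial extent every sample is brought
    to by :func:`load_and_standardize`.
    """

    rank: int
    target_size: tuple[int, ...]
    channels: int
    samples: list[SegmentationSample] | None = None
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.samples) if self.samples is not None else len(self.pairs)


def _read_image_2d(path: str) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read image {path}: {exc}") from exc
    return np.asarray(arr)


def _read_volume(path: str) -> np.ndarray:
    import nibabel as nib
    try:
        vol = np.asanyarray(nib.load(path).dataobj)
    except Exception as exc:
        raise IOError(f"cannot read volume {path}: {exc}") from exc
    return vol


def _standardize_2d(img: np.ndarray, mask: np.ndarray, target, channels,
                    path: str = "<memory>") -> SegmentationSample:
    img = img.astype(np.float64)
    if img.ndim == 2:
        img = img[..., None]
    if img.shape[-1] == 4:  # drop alpha
        img = img[..., :3]
    img = img / 255.0
    if img.shape[-1] != channels:
        if img.shape[-1] == 1:
            img = img.repeat(channels, axis=-1)
        elif channels == 1:
            img = img.mean(axis=-1, keepdims=True)
        else:
            raise IOError(f"{path}: has {img.shape[-1]} channels, expected {channels}")
    if img.shape[:-1] != tuple(target):
        img = resize(img, tuple(target) + (img.shape[-1],), order=1,
                     anti_aliasing=True, preserve_range=True)
    if mask.ndim == 3:
        mask = mask[..., 0]
    mask = (mask.astype(np.float64) > 0).astype(np.float64)
    if mask.shape != tuple(target):
        mask = resize(mask, tuple(target), order=1, anti_aliasing=False,
                      preserve_range=True)
    mask = (mask >= 0.5).astype(np.uint8)
    return SegmentationSample(image=np.clip(img, 0, 1).astype(np.float32),
                              mask=mask, meta=dict(path=path))


def _standardize_3d(vol: np.ndarray, mask: np.ndarray, target, channels,
                    path: str = "<memory>") -> SegmentationSample:
    vol = vol.astype(np.float64)
    if vol.ndim == 3:
        vol = vol[..., None]
    if vol.shape[-1] != channels:
        raise IOError(f"{path}: has {vol.shape[-1]} channels, expected {channels}")
    # per-volume min-max scaling (per channel)
    for c in range(vol.shape[-1]):
        ch = vol[..., c]
        lo, hi = ch.min(), ch.max()
        vol[..., c] = (ch - lo) / (hi - lo) if hi > lo else 0.0
    if vol.shape[:-1] != tuple(target):
        vol = resize(vol, tuple(target) + (vol.shape[-1],), order=1,
                     anti_aliasing=False, preserve_range=True)
    mask = (mask.astype(np.float64) > 0).astype(np.float64)
    if mask.shape != tuple(target):
        mask = resize(mask, tuple(target), order=1, anti_aliasing=False,
                      preserve_range=True)
    mask = (mask >= 0.5).astype(np.uint8)
    return SegmentationSample(image=np.clip(vol, 0, 1).astype(np.float32),
                              mask=mask, meta=dict(path=path))


def load_and_standardize(manifest: DatasetManifest) -> list[SegmentationSample]:
    """Read, scale, resize and binarize every sample of a manifest."""
    out = []
    if manifest.samples is not None:
        for s in manifest.samples:
            if manifest.rank == 2:
                out.append(_standardize_2d(np.asarray(s.image) * 255.0, s.mask,
                                           manifest.target_size, manifest.channels))
            else:
                out.append(_standardize_3d(np.asarray(s.image), s.mask,
                                           manifest.target_size, manifest.channels))
        return out
    for img_path, mask_path in manifest.pairs:
        if manifest.rank == 2:
            img = _read_image_2d(img_path)
            mask = _read_image_2d(mask_path)
            out.append(_standardize_2d(img, mask, manifest.target_size,
                                       manifest.channels, img_path))
        else:
            vol = _read_volume(img_path)
            mask = _read_volume(mask_path)
            out.append(_standardize_3d(vol, mask, manifest.target_size,
                                       manifest.channels, img_path))
    return out


# ---------------------------------------------------------------------------
# augmentation


@dataclass(frozen=True)
class AugmentConfig:
    """Mask-exact flip/right-angle-rotation augmentation.

    The augmented set contains every original plus ``factor - 1`` randomly
    transformed copies of each, so its size is exactly ``factor`` times the
    original size.
    """

    horizontal_flip: bool = True
    vertical_flip: bool = True
    rotations: tuple[int, ...] = (1, 2, 3)  # multiples of 90 degrees
    factor: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.factor < 1:
            raise ValueError("factor must be >= 1")


def _transform_arrays(img: np.ndarray, mask: np.ndarray, flip_h: bool,
                      flip_v: bool, rot_k: int):
    """Apply one flip/rotation combo identically to image and mask.

    Axes 0/1 are the first two spatial axes (for volumes the rotation is
    in-plane); the image's trailing channel axis is untouched.
    """
    if flip_h:
        img, mask = np.flip(img, axis=1), np.flip(mask, axis=1)
    if flip_v:
        img, mask = np.flip(img, axis=0), np.flip(mask, axis=0)
    if rot_k:
        img = np.rot90(img, k=rot_k, axes=(0, 1))
        mask = np.rot90(mask, k=rot_k, axes=(0, 1))
    return img.copy(), mask.copy()


def augment_dataset(samples: list[SegmentationSample],
                    config: AugmentConfig) -> list[SegmentationSample]:
    """Return originals plus seeded random transformed copies (x factor)."""
    rng = np.random.default_rng(config.seed)
    combos = []
    for fh in ((False, True) if config.horizontal_flip else (False,)):
        for fv in ((False, True) if config.vertical_flip else (False,)):
            for k in (0,) + tuple(config.rotations):
                if fh or fv or k:
                    combos.append((fh, fv, k))
    if config.factor > 1 and not combos:
        raise ValueError("no transforms enabled but factor > 1")
    out = list(samples)
    for s in samples:
        square = s.image.shape[0] == s.image.shape[1]
        usable = [c for c in combos if square or c[2] % 2 == 0]
        if config.factor > 1 and not usable:
            raise ValueError("non-square samples admit no right-angle rotation; "
                             "enable flips or use square images")
        for _ in range(config.factor - 1):
            fh, fv, k = usable[rng.integers(len(usable))]
            img, mask = _transform_arrays(s.image, s.mask, fh, fv, k)
            meta = dict(s.meta or {})
            meta["augment"] = dict(flip_h=fh, flip_v=fv, rot90=k)
            out.append(SegmentationSample(image=img, mask=mask, meta=meta))
    return out


# ---------------------------------------------------------------------------
# on-disk datasets


def save_dataset(manifest: DatasetManifest, out_dir, split: str = "train") -> Path:
    """Write samples to ``out_dir`` (2D: PNG pairs; 3D: NIfTI pairs) plus a
    ``manifest.csv`` with columns image, mask, split.  Returns the CSV path."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(manifest.samples or []):
        if manifest.rank == 2:
            img_path = out_dir / "images" / f"{i:04d}.png"
            mask_path = out_dir / "masks" / f"{i:04d}.png"
            img8 = np.round(np.clip(s.image, 0, 1) * 255).astype(np.uint8)
            iio.imwrite(img_path, img8)
            iio.imwrite(mask_path, (s.mask * 255).astype(np.uint8))
        else:
            import nibabel as nib
            img_path = out_dir / "images" / f"{i:04d}.nii.gz"
            mask_path = out_dir / "masks" / f"{i:04d}.nii.gz"
            nib.save(nib.Nifti1Image(s.image.astype(np.float32), np.eye(4)), img_path)
            nib.save(nib.Nifti1Image(s.mask.astype(np.uint8), np.eye(4)), mask_path)
        rows.append(dict(image=os.fspath(img_path), mask=os.fspath(mask_path),
                         split=split))
    csv_path = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    return csv_path


def read_manifest_csv(csv_path, rank: int, target_size, channels) -> DatasetManifest:
    """Build a path-based manifest from a manifest CSV."""
    df = pd.read_csv(csv_path)
    pairs = list(zip(df["image"].astype(str), df["mask"].astype(str)))
    return DatasetManifest(rank=rank, target_size=tuple(target_size),
                           channels=channels, pairs=pairs)
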