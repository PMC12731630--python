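"""Image loading, preprocessing, splitting, augmentation, two-view batches.

Preprocessing follows the published pipeline: bicubic resize to a uniform
size (default 224x224) and per-image Z-standardization of pixel
intensities.  Splitting is 8:1:1 into train/validation/test, either
stratified per class (default; floor rounding, train filled first) or as
a global floor split of the shuffled pool.  Augmentations are the stated
simple set: 90-degree rotation, horizontal/vertical flips, color jitter,
Gaussian blur and additive Gaussian noise.  Two-view batches duplicate
every sampled image as two independent augmentations so each anchor in a
contrastive batch is guaranteed a positive.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "AugmentationConfig",
    "LabeledImageSet",
    "SplitRatios",
    "augment",
    "export_split_csv",
    "load_dataset",
    "preprocess",
    "split",
    "split_indices",
    "two_view_batch",
]


@dataclass
class LabeledImageSet:
    """Images with integer class labels; the unit of all data flow."""

    images: list
    labels: np.ndarray
    class_names: list[str]

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != self.labels.size:
            raise ValueError("images and labels length mismatch")
        if self.labels.size and self.labels.max() >= len(self.class_names):
            raise ValueError("label outside class_names range")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    @property
    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.num_classes)

    def subset(self, indices) -> "LabeledImageSet":
        indices = np.asarray(indices, dtype=np.int64)
        return LabeledImageSet(images=[self.images[i] for i in indices],
                               labels=self.labels[indices],
                               class_names=list(self.class_names))

    def map_images(self, fn) -> "LabeledImageSet":
        return LabeledImageSet(images=[fn(im) for im in self.images],
                               labels=self.labels.copy(),
                               class_names=list(self.class_names))


@dataclass(frozen=True)
class SplitRatios:
    train: float = 0.8
    val: float = 0.1
    test: float = 0.1

    def __post_init__(self):
        if min(self.train, self.val, self.test) < 0:
            raise ValueError("ratios must be non-negative")
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("split ratios must sum to 1")


@dataclass
class AugmentationConfig:
    rot90: bool = True
    hflip: bool = True
    vflip: bool = True
    jitter: float = 0.2        # brightness/contrast fraction
    blur_sigma: tuple = (0.1, 1.0)
    noise_std: float = 0.05    # in normalized-intensity units
    blur_prob: float = 0.5
    jitter_prob: float = 0.5
    noise_prob: float = 0.5

    def __post_init__(self):
        if self.jitter < 0 or self.noise_std < 0 or min(self.blur_sigma) < 0:
            raise ValueError("augmentation magnitudes must be >= 0")

    @classmethod
    def none(cls) -> "AugmentationConfig":
        return cls(rot90=False, hflip=False, vflip=False, jitter=0.0,
                   blur_sigma=(0.0, 0.0), noise_std=0.0,
                   blur_prob=0.0, jitter_prob=0.0, noise_prob=0.0)

    @classmethod
    def from_yaml(cls, path) -> "AugmentationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "blur_sigma" in data:
            data["blur_sigma"] = tuple(data["blur_sigma"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["blur_sigma"] = list(self.blur_sigma)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


# ----------------------------------------------------------------------

_EXTS = {".png", ".jpg", ".jpeg"}


def load_dataset(root) -> LabeledImageSet:
    """Read a directory-per-class tree of PNG/JPEG images.

    Labels follow the sorted subdirectory names; undecodable files are
    skipped with a warning and empty classes excluded with a warning.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} not found")
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    images, labels, names = [], [], []
    for d in class_dirs:
        loaded = []
        for f in sorted(d.iterdir()):
            if f.suffix.lower() not in _EXTS:
                continue
            try:
                with Image.open(f) as im:
                    im = im.convert("RGB") if im.mode not in ("L", "RGB") else im
                    loaded.append(np.asarray(im))
            except Exception:
                warnings.warn(f"skipping undecodable image {f}")
        if not loaded:
            warnings.warn(f"excluding empty class directory {d.name}")
            continue
        label = len(names)
        names.append(d.name)
        images.extend(loaded)
        labels.extend([label] * len(loaded))
    if not names:
        raise ValueError(f"no class directories with images under {root}")
    return LabeledImageSet(images=images, labels=np.array(labels, dtype=np.int64),
                           class_names=names)


def preprocess(image: np.ndarray, size: tuple[int, int] = (224, 224)) -> np.ndarray:
    """Bicubic resize then per-image Z-standardization.

    Returns a float64 array with mean 0 and unit standard deviation over
    all pixels and channels; a constant image maps to all zeros.
    """
    arr = np.asarray(image)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.ndim == 2:
        arr = arr[..., None]
    if arr.ndim != 3 or arr.shape[2] not in (1, 3):
        raise ValueError("expected an HxW or HxWx{1,3} image")
    h, w = size
    channels = []
    for c in range(arr.shape[2]):
        im = Image.fromarray(arr[..., c].astype(np.float32), mode="F")
        channels.append(np.asarray(im.resize((w, h), Image.Resampling.BICUBIC),
                                   dtype=np.float64))
    out = np.stack(channels, axis=-1)
    if out.shape[2] == 1:
        out = out[..., 0]
    mu, sd = out.mean(), out.std()
    if sd == 0:
        return np.zeros_like(out)
    return (out - mu) / sd


def split_indices(labels, ratios: SplitRatios = SplitRatios(), seed: int = 0,
                  stratified: bool = True):
    """Disjoint, exhaustive train/val/test index partition.

    Stratified mode: per class, ``floor(r_train * n_c)`` to train and
    ``floor(r_val * n_c)`` to val (shuffled within class), remainder to
    test.  Global mode: shuffle the pool and cut at
    ``floor(r_train * n)`` and ``floor(r_val * n)``.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    if stratified:
        tr, va, te = [], [], []
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            rng.shuffle(idx)
            n_tr = int(np.floor(ratios.train * idx.size))
            n_va = int(np.floor(ratios.val * idx.size))
            tr.append(idx[:n_tr])
            va.append(idx[n_tr:n_tr + n_va])
            te.append(idx[n_tr + n_va:])
        parts = [np.sort(np.concatenate(p)) for p in (tr, va, te)]
    else:
        idx = rng.permutation(labels.size)
        n_tr = int(np.floor(ratios.train * labels.size))
        n_va = int(np.floor(ratios.val * labels.size))
        parts = [np.sort(idx[:n_tr]), np.sort(idx[n_tr:n_tr + n_va]),
                 np.sort(idx[n_tr + n_va:])]
    return tuple(parts)


def split(dataset: LabeledImageSet, ratios: SplitRatios = SplitRatios(),
          seed: int = 0, stratified: bool = True):
    """Split a dataset into (train, val, test) ``LabeledImageSet``s."""
    if len(dataset) < dataset.num_classes * 3:
        raise ValueError("dataset too small to split three ways")
    tr, va, te = split_indices(dataset.labels, ratios, seed, stratified)
    return dataset.subset(tr), dataset.subset(va), dataset.subset(te)


def export_split_csv(dataset: LabeledImageSet, parts, path,
                     names=("train", "val", "test")) -> None:
    """Write one row per image: index, label, partition name."""
    partition = np.empty(len(dataset), dtype=object)
    for name, idx in zip(names, parts):
        partition[np.asarray(idx)] = name
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["index", "label", "partition"])
        for i in range(len(dataset)):
            w.writerow([i, int(dataset.labels[i]), partition[i]])


# ----------------------------------------------------------------------

def _jitter(img: np.ndarray, rng: np.random.Generator, frac: float) -> np.ndarray:
    b = 1.0 + rng.uniform(-frac, frac)
    c = 1.0 + rng.uniform(-frac, frac)
    mu = img.mean()
    return (img - mu) * c + mu * b


def augment(image: np.ndarray, cfg: AugmentationConfig,
            seed: int | np.random.Generator = 0) -> np.ndarray:
    """Apply an independent random subset of the enabled transforms.

    Output shape and dtype always equal the input's; uint8 images are
    clipped back to [0, 255].
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    arr = np.asarray(image)
    dtype = arr.dtype
    out = arr.astype(np.float64)
    spatial_sigma = None
    if cfg.rot90:
        k = int(rng.integers(0, 4))
        out = np.rot90(out, k, axes=(0, 1))
    if cfg.hflip and rng.random() < 0.5:
        out = out[:, ::-1]
    if cfg.vflip and rng.random() < 0.5:
        out = out[::-1]
    if cfg.jitter > 0 and rng.random() < cfg.jitter_prob:
        out = _jitter(out, rng, cfg.jitter)
    if max(cfg.blur_sigma) > 0 and rng.random() < cfg.blur_prob:
        sigma = rng.uniform(*cfg.blur_sigma)
        spatial_sigma = (sigma, sigma) + (0,) * (out.ndim - 2)
        out = gaussian_filter(out, sigma=spatial_sigma)
    if cfg.noise_std > 0 and rng.random() < cfg.noise_prob:
        scale = 255.0 if dtype == np.uint8 else 1.0
        out = out + rng.normal(0.0, cfg.noise_std * scale, size=out.shape)
    if dtype == np.uint8:
        out = np.clip(np.round(out), 0, 255)
    return np.ascontiguousarray(out).astype(dtype)


def two_view_batch(dataset: LabeledImageSet, batch_size: int,
                   cfg: AugmentationConfig, seed: int | np.random.Generator = 0):
    """Sample ``batch_size`` images and emit two augmentations of each.

    Returns ``(views, labels)`` with ``2 * batch_size`` entries; every
    label occurs an even number of times, so each anchor of a contrastive
    batch has at least its sibling view as a positive.
    """
    if batch_size < 2:
        raise ValueError("batch_size must be >= 2")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n = len(dataset)
    if batch_size > n:
        warnings.warn("batch size exceeds dataset size; sampling with replacement")
        idx = rng.integers(0, n, size=batch_size)
    else:
        idx = rng.choice(n, size=batch_size, replace=False)
    views, labels = [], []
    for i in idx:
        for _ in range(2):
            views.append(augment(dataset.images[i], cfg, rng))
        labels.extend([dataset.labels[i]] * 2)
    return np.stack(views), np.asarray(labels, dtype=np.int64)
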