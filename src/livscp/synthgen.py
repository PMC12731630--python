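"""Synthetic speckle-textured ultrasound-like image generator.

Real B-mode ultrasound is dominated by multiplicative speckle whose
envelope is well described by a Rayleigh distribution in the
fully-developed case.  The generator builds each image as a smoothed
Rayleigh speckle field scaled by a class gain, with a class-dependent
number of bright oriented bands mimicking septa-like echogenic streaks.
Texture coarseness (smoothing sigma), gain and band count all increase
with class index to emulate coarsening parenchyma across fibrosis
stages; a single ``separation`` scalar in [0, 1] scales the inter-class
spread of all three, with ``separation = 0`` collapsing every class onto
the same distribution.

These images are honest stand-ins for pipeline testing — they are not
claimed to reproduce the appearance of METAVIR-graded scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from scipy.ndimage import gaussian_filter

from .datapipe import LabeledImageSet

__all__ = ["SynthParams", "default_fixture", "generate", "write_dataset"]

# class-count profile of the motivating five-stage dataset
REFERENCE_COUNTS = (2114, 861, 793, 857, 1698)


def _scaled_counts(total: int, ref=REFERENCE_COUNTS) -> list[int]:
    """Largest-remainder apportionment of `total` along `ref` ratios."""
    ref = np.asarray(ref, dtype=np.float64)
    exact = ref / ref.sum() * total
    base = np.floor(exact).astype(int)
    rem = exact - base
    for i in np.argsort(-rem)[: total - base.sum()]:
        base[i] += 1
    return base.tolist()


@dataclass
class SynthParams:
    num_classes: int = 5
    class_counts: list = field(default_factory=lambda: _scaled_counts(1000))
    image_size: int = 64
    speckle_scale: float = 1.0       # Rayleigh mode of the raw speckle field
    base_smooth_sigma: float = 1.0   # texture coarseness at class 0
    smooth_sigma_step: float = 0.8   # added per class index at separation 1
    base_gain: float = 110.0         # mean intensity at class 0
    gain_step: float = 12.0          # added per class index at separation 1
    bands_per_stage: float = 1.0     # echogenic bands per class index at sep. 1
    band_amplitude: float = 50.0
    band_width: float = 1.5
    separation: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if len(self.class_counts) != self.num_classes:
            raise ValueError("class_counts length must equal num_classes")
        if any(c < 1 for c in self.class_counts):
            raise ValueError("all class counts must be >= 1")
        if not 0.0 <= self.separation <= 1.0:
            raise ValueError("separation must lie in [0, 1]")

    def class_profile(self, c: int) -> dict:
        s = self.separation
        return {
            "smooth_sigma": self.base_smooth_sigma + s * c * self.smooth_sigma_step,
            "gain": self.base_gain + s * c * self.gain_step,
            "n_bands": int(round(s * c * self.bands_per_stage)),
        }

    @classmethod
    def from_yaml(cls, path) -> "SynthParams":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)


def _render(rng: np.random.Generator, size: int, profile: dict,
            speckle_scale: float, band_amplitude: float,
            band_width: float) -> np.ndarray:
    speckle = rng.rayleigh(scale=speckle_scale, size=(size, size))
    if profile["smooth_sigma"] > 0:
        speckle = gaussian_filter(speckle, sigma=profile["smooth_sigma"])
    speckle /= speckle.mean()
    img = profile["gain"] * speckle
    if profile["n_bands"] > 0:
        yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
        for _ in range(profile["n_bands"]):
            theta = rng.uniform(0, np.pi)
            offset = rng.uniform(-0.4 * size, 0.4 * size)
            d = ((xx - size / 2) * np.cos(theta)
                 + (yy - size / 2) * np.sin(theta) - offset)
            img = img + band_amplitude * np.exp(-0.5 * (d / band_width) ** 2)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate(params: SynthParams) -> LabeledImageSet:
    """Generate the full imbalanced image set described by ``params``.

    Fully seeded: two calls with equal parameters produce byte-identical
    images.
    """
    root = np.random.SeedSequence(params.seed)
    class_seeds = root.spawn(params.num_classes)
    images, labels = [], []
    for c in range(params.num_classes):
        rng = np.random.default_rng(class_seeds[c])
        profile = params.class_profile(c)
        for _ in range(params.class_counts[c]):
            images.append(_render(rng, params.image_size, profile,
                                  params.speckle_scale, params.band_amplitude,
                                  params.band_width))
            labels.append(c)
    names = [f"F{c}" for c in range(params.num_classes)]
    return LabeledImageSet(images=images, labels=np.asarray(labels),
                           class_names=names)


def default_fixture(scale: str = "small") -> LabeledImageSet:
    """Fixed, fully reproducible fixtures for tests and examples.

    ``small``: 150 images, 32x32, counts (50, 25, 20, 25, 30).
    ``medium``: 1000 images, 64x64, counts at the reference five-stage
    imbalance ratios, separation 0.7.
    """
    if scale == "small":
        params = SynthParams(class_counts=[50, 25, 20, 25, 30],
                             image_size=32, separation=1.0, seed=11)
    elif scale == "medium":
        params = SynthParams(class_counts=_scaled_counts(1000),
                             image_size=64, separation=0.7, seed=23)
    else:
        raise ValueError("scale must be 'small' or 'medium'")
    return generate(params)


def write_dataset(dataset: LabeledImageSet, root) -> None:
    """Write the directory-per-class PNG layout read by ``load_dataset``."""
    root = Path(root)
    counters = {name: 0 for name in dataset.class_names}
    for img, label in zip(dataset.images, dataset.labels):
        name = dataset.class_names[label]
        d = root / name
        d.mkdir(parents=True, exist_ok=True)
        Image.fromarray(img).save(d / f"{name}_{counters[name]:05d}.png")
        counters[name] += 1
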