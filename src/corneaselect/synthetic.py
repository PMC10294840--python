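"""Synthetic inputs with known ground truth.

Two generators stand in for the fluorescein-stained corneal image set so
that every downstream stage (feature pooling, GA selection, SVM
classification, the evaluation protocol) can be exercised without any
download:

* :func:`generate_planted_features` draws a channel-mean feature matrix in
  which a known subset of channels carries a class-mean shift — the
  "planted" informative channels whose identities are returned so that
  selection recovery can be scored.
* :func:`generate_toy_images` draws small grayscale eye-like images: a
  textured bright disc (the stained cornea) with, for the positive class, a
  brighter lesion blob inside it.

Both are fully deterministic for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass

import numpy as np
from PIL import Image

__all__ = [
    "PlantedDesign",
    "ToyImageDesign",
    "generate_planted_features",
    "generate_toy_images",
    "write_planted_table",
    "write_toy_images",
]


@dataclass(frozen=True)
class PlantedDesign:
    """Design of a planted-signal channel-mean dataset.

    Parameters
    ----------
    n_samples : int
        Number of samples (rows).
    n_channels : int
        Number of feature channels ``w`` (columns).
    k_informative : int
        Number of channels carrying class signal; must not exceed
        ``n_channels``.
    effect_size : float
        Class-mean shift of informative channels, in units of ``noise_sd``.
    noise_sd : float
        Standard deviation of the Gaussian channel noise.
    class_balance : float
        Expected fraction of positive (class-1) samples, in (0, 1).
    seed : int
        Seed for the generator.
    """

    n_samples: int = 200
    n_channels: int = 64
    k_informative: int = 8
    effect_size: float = 5.0
    noise_sd: float = 1.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if not 0 <= self.k_informative <= self.n_channels:
            raise ValueError("k_informative must lie in [0, n_channels]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")


@dataclass(frozen=True)
class ToyImageDesign:
    """Design of a toy two-class stained-eye image set.

    Class 1 images contain a bright circular lesion inside a textured
    cornea disc; class 0 images contain the disc only.
    """

    n_samples: int = 20
    image_size: int = 64
    lesion_intensity: float = 0.5
    lesion_radius_range: tuple[int, int] = (4, 8)
    background_texture_sd: float = 0.05
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.lesion_radius_range
        if not 0 < lo <= hi:
            raise ValueError("lesion_radius_range must be positive and ordered")
        # lesion must fit inside the cornea disc (radius ~ 0.4 * image_size)
        if hi >= 0.4 * self.image_size:
            raise ValueError(
                f"image_size {self.image_size} too small for lesion radius {hi}"
            )
        if self.n_samples < 2:
            raise ValueError("n_samples must be at least 2")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")


def _draw_labels(rng: np.random.Generator, n: int, balance: float) -> np.ndarray:
    """Bernoulli labels, resampled until both classes are present."""
    for _ in range(1000):
        labels = (rng.random(n) < balance).astype(np.int64)
        if 0 < labels.sum() < n:
            return labels
    raise ValueError("degenerate design: could not draw both classes")


def generate_planted_features(
    design: PlantedDesign,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw a planted-signal channel-mean matrix.

    Returns
    -------
    values : ndarray of shape (n_samples, n_channels)
        Channel means. Informative channels have class-conditional means
        differing by ``effect_size * noise_sd``; the rest are
        label-independent Gaussian noise.
    labels : ndarray of shape (n_samples,)
        Class labels in {0, 1}.
    informative : ndarray of shape (k_informative,)
        Sorted indices of the planted channels (0-based).
    """
    rng = np.random.default_rng(design.seed)
    labels = _draw_labels(rng, design.n_samples, design.class_balance)
    informative = np.sort(
        rng.choice(design.n_channels, size=design.k_informative, replace=False)
    )
    values = rng.normal(0.0, design.noise_sd, (design.n_samples, design.n_channels))
    shift = design.effect_size * design.noise_sd
    values[np.ix_(labels == 1, informative)] += shift
    return values, labels, informative


def generate_toy_images(
    design: ToyImageDesign,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw toy stained-eye images.

    Returns
    -------
    images : ndarray of shape (n_samples, image_size, image_size), float in [0, 1]
        Grayscale images; replicate to 3 channels for an RGB backbone.
    labels : ndarray of shape (n_samples,)
        1 where a lesion was planted, else 0.
    """
    rng = np.random.default_rng(design.seed)
    n, s = design.n_samples, design.image_size
    labels = _draw_labels(rng, n, design.class_balance)
    yy, xx = np.mgrid[0:s, 0:s]
    images = np.empty((n, s, s), dtype=np.float64)
    for i in range(n):
        img = np.full((s, s), 0.05)
        # cornea disc, slightly jittered centre
        cy, cx = (s / 2 + rng.normal(0, s * 0.02, 2)).tolist()
        disc_r = 0.4 * s
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= disc_r**2
        img[disc] = 0.35
        img += rng.normal(0.0, design.background_texture_sd, (s, s))
        if labels[i] == 1:
            r = rng.integers(design.lesion_radius_range[0], design.lesion_radius_range[1] + 1)
            # lesion centre uniform inside the disc, margin r
            theta = rng.uniform(0, 2 * np.pi)
            rho = (disc_r - r) * np.sqrt(rng.uniform())
            ly, lx = cy + rho * np.sin(theta), cx + rho * np.cos(theta)
            lesion = (yy - ly) ** 2 + (xx - lx) ** 2 <= r**2
            img[lesion] += design.lesion_intensity
        images[i] = np.clip(img, 0.0, 1.0)
    return images, labels


def write_planted_table(path: str | os.PathLike, design: PlantedDesign) -> None:
    """Write a planted feature table as delimited text (channel ids + label)."""
    values, labels, informative = generate_planted_features(design)
    # header ids are 1-based, matching the serialized FeatureTable convention
    header = [f"c{j + 1}" for j in range(design.n_channels)] + ["label"]
    data = np.column_stack([values, labels])
    meta = ",".join(str(int(j) + 1) for j in informative)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write('# {"index_base": 1}\n')
        np.savetxt(
            fh,
            data,
            delimiter="\t",
            header="\t".join(header),
            comments="",
            fmt=["%.10g"] * design.n_channels + ["%d"],
        )
        fh.write(f"# informative_channels_1based: {meta}\n")
        fh.write(f"# design: {dataclasses.asdict(design)}\n")


def write_toy_images(root: str | os.PathLike, design: ToyImageDesign) -> list[str]:
    """Write toy images as PNG under ``class_0/`` and ``class_1/``.

    This is the same directory layout the real-data loader expects.
    Returns the list of file paths written, in generation order.
    """
    images, labels = generate_toy_images(design)
    paths = []
    for cls in (0, 1):
        os.makedirs(os.path.join(root, f"class_{cls}"), exist_ok=True)
    for i, (img, lab) in enumerate(zip(images, labels)):
        arr = (img * 255).round().astype(np.uint8)
        path = os.path.join(root, f"class_{int(lab)}", f"img_{i:04d}.png")
        Image.fromarray(arr, mode="L").save(path)
        paths.append(path)
    return paths
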