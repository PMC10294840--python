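"""Per-layer feature tables: extraction, mean pooling and delimited-text I/O.

Each feature map (channel) of a layer's activation tensor is reduced to
its arithmetic mean over all spatial positions, turning an ``a x b x w``
tensor into a length-``w`` descriptor per image.  A :class:`FeatureTable`
holds those descriptors for a set of images together with binary labels
(class 1 = ulcer present) and the identity of the originating channels.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .resnet import LayerSpec, ResNet18, enumerate_layers

__all__ = [
    "FeatureTable",
    "pool_mean",
    "preprocess_image",
    "extract_layer_features",
    "load_image_folder",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])


@dataclass
class FeatureTable:
    """Samples x channel-means matrix with labels and channel provenance.

    ``channel_ids`` are 0-based internally; serialization writes 1-based
    ids with an explicit ``index_base`` marker.
    """

    values: np.ndarray
    labels: np.ndarray
    channel_ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    layer: LayerSpec | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.channel_ids is None:
            self.channel_ids = np.arange(self.values.shape[1])
        self.channel_ids = np.asarray(self.channel_ids, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x channels)")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must match number of rows")
        if len(self.channel_ids) != self.values.shape[1]:
            raise ValueError("channel_ids length must match number of columns")
        if len(np.unique(self.channel_ids)) != len(self.channel_ids):
            raise ValueError("channel_ids must be distinct")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def select(self, columns: np.ndarray) -> "FeatureTable":
        """Sub-table restricted to the given column positions."""
        columns = np.asarray(columns, dtype=np.int64)
        return FeatureTable(
            self.values[:, columns],
            self.labels,
            self.channel_ids[columns],
            self.layer,
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=[f"c{int(j) + 1}" for j in self.channel_ids]
        )
        df["label"] = self.labels
        return df

    def to_csv(self, path: str | os.PathLike) -> None:
        """Write as TSV: header of 1-based channel ids plus a label column."""
        with open(path, "w", encoding="utf-8") as fh:
            meta = {"index_base": 1}
            if self.layer is not None:
                meta.update(
                    layer_name=self.layer.name,
                    layer_index=self.layer.index,
                    output_shape=list(self.layer.output_shape),
                )
            fh.write(f"# {json.dumps(meta)}\n")
            self.to_dataframe().to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "FeatureTable":
        meta = {}
        with open(path, encoding="utf-8") as fh:
            pos = fh.tell()
            first = fh.readline()
            if first.startswith("# "):
                try:
                    meta = json.loads(first[2:])
                except json.JSONDecodeError:
                    meta = {}
            else:
                fh.seek(pos)
            df = pd.read_csv(fh, sep="\t", comment="#")
        if "label" not in df.columns:
            raise ValueError(f"{path}: missing 'label' column")
        labels = df.pop("label").to_numpy()
        base = int(meta.get("index_base", 1))
        ids = np.array([int(str(c).lstrip("c")) - base for c in df.columns])
        layer = None
        if "layer_name" in meta:
            layer = LayerSpec(
                int(meta["layer_index"]),
                meta["layer_name"],
                tuple(meta["output_shape"]),
            )
        return cls(df.to_numpy(dtype=np.float64), labels, ids, layer)


def pool_mean(activation: np.ndarray) -> np.ndarray:
    """Reduce a ``(C, a, b)`` activation tensor to per-map means ``(C,)``."""
    activation = np.asarray(activation, dtype=np.float64)
    return activation.reshape(activation.shape[0], -1).mean(axis=1)


def preprocess_image(
    image: np.ndarray | str | os.PathLike, input_size: int = 224
) -> np.ndarray:
    """Decode/resize/normalize one image to a ``(3, S, S)`` float tensor.

    Resize to ``input_size`` square (bilinear), scale to [0, 1], replicate
    grayscale to 3 channels, then normalize with the ImageNet channel
    statistics the backbone's canonical weights assume.
    """
    if isinstance(image, (str, os.PathLike)):
        with Image.open(image) as im:
            image = np.asarray(im.convert("RGB"))
    image = np.asarray(image)
    if image.dtype == np.uint8:
        image = image / 255.0
    image = np.asarray(image, dtype=np.float64)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.shape[:2] != (input_size, input_size):
        im = Image.fromarray((np.clip(image, 0, 1) * 255).astype(np.uint8))
        image = np.asarray(im.resize((input_size, input_size), Image.BILINEAR)) / 255.0
    return ((image - IMAGENET_MEAN) / IMAGENET_STD).transpose(2, 0, 1)


def _resolve_layer(layer, backbone_id: str, input_size: int) -> LayerSpec:
    layers = enumerate_layers(backbone_id, input_size)
    if isinstance(layer, LayerSpec):
        name = layer.name
    else:
        name = str(layer)
    for sp in layers:
        if sp.name == name:
            return sp
    raise ValueError(f"layer {name!r} not in backbone {backbone_id!r}")


def extract_layer_features(
    images,
    layer,
    backbone_id: str = "resnet18",
    weights: str = "random",
    labels=None,
    seed: int = 0,
    input_size: int = 224,
    model: ResNet18 | None = None,
) -> FeatureTable:
    """Extract per-map mean descriptors for one layer over an image set.

    Parameters
    ----------
    images : sequence of arrays or paths
        Decodable RGB/grayscale images.
    layer : str or LayerSpec
        The layer to probe.
    labels : sequence of int, optional
        Binary labels; zeros if omitted.
    input_size : int
        Side of the square input fed to the backbone (224 reproduces the
        reference layer shapes; smaller values speed up testing).

    Returns
    -------
    FeatureTable with one row per image and ``w`` columns (the layer's
    channel count); entry (s, j) is the spatial mean of map j for image s.
    """
    spec = _resolve_layer(layer, backbone_id, input_size)
    net = model if model is not None else ResNet18(weights=weights, seed=seed)
    rows = []
    for img in images:
        x = preprocess_image(img, input_size=input_size)
        rows.append(pool_mean(net.activation(x, spec.name)))
    values = np.vstack(rows) if rows else np.empty((0, spec.n_channels))
    if labels is None:
        labels = np.zeros(len(rows), dtype=np.int64)
    return FeatureTable(values, np.asarray(labels), np.arange(spec.n_channels), spec)


def load_image_folder(root: str | os.PathLike) -> tuple[list[Path], np.ndarray]:
    """List images under per-class subfolders (``class_0/``, ``class_1/``).

    Any two sorted subdirectories are accepted; the first maps to label 0.
    Returns (paths, labels) in deterministic sorted order.
    """
    root = Path(root)
    subdirs = sorted(d for d in root.iterdir() if d.is_dir())
    if len(subdirs) != 2:
        raise ValueError(f"{root}: expected exactly 2 class subfolders, found {len(subdirs)}")
    paths: list[Path] = []
    labels: list[int] = []
    for cls, d in enumerate(subdirs):
        files = sorted(
            p for p in d.iterdir() if p.suffix.lower() in {".png", ".jpg", ".jpeg"}
        )
        paths.extend(files)
        labels.extend([cls] * len(files))
    if not paths:
        raise ValueError(f"{root}: no images found in class subfolders")
    return paths, np.asarray(labels, dtype=np.int64)
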