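"""ResNet-18 inference graph in NumPy: layer enumeration and activations.

The classifier probes *intermediate* tensors of a ResNet-18 backbone, so
the contract of this module is twofold:

1. :func:`enumerate_layers` lists, in a fixed order, every tensor-producing
   operation from the first convolution through the final global pooling —
   convolutions, batch-norms, ReLUs, poolings and element-wise residual
   sums — excluding the input and the classification head (fully-connected,
   softmax, output).  For the standard 224x224x3 reference input this yields
   67 candidate layers, named in the conventional ``res<stage><block>_*``
   style (``conv1`` ... ``pool5``).  In downsampling blocks the projection
   shortcut (``res3a_branch1``/``bn3a_branch1``) is enumerated immediately
   after the block's first convolution.

2. :class:`ResNet18` runs the forward pass and records the activation
   tensor at each of those layers.  Weights are seeded random draws by
   default (sufficient for testing the pooling/selection machinery, which
   is weight-agnostic) or can be loaded from an ``.npz`` of named arrays
   for users who have real pretrained parameters.

Convolutions are computed by im2col (``sliding_window_view`` + tensordot);
batch norm runs in inference mode only.  Residual-block training and the
classification head are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "LayerSpec",
    "enumerate_layers",
    "count_layer_attributes",
    "total_attributes",
    "ResNet18",
    "BACKBONES",
]

#: stages: (stage number, blocks, channels, downsample on first block)
_STAGES = (
    (2, ("a", "b"), 64, False),
    (3, ("a", "b"), 128, True),
    (4, ("a", "b"), 256, True),
    (5, ("a", "b"), 512, True),
)

BACKBONES = ("resnet18",)

_BN_EPS = 1e-5


@dataclass(frozen=True)
class LayerSpec:
    """A probe-able layer: 1-based sweep index, name, and output shape.

    ``output_shape`` is (height, width, channels) for the reference input
    size the enumeration was built with.
    """

    index: int
    name: str
    output_shape: tuple[int, int, int]

    @property
    def n_channels(self) -> int:
        return self.output_shape[2]

    @property
    def n_attributes(self) -> int:
        a, b, w = self.output_shape
        return a * b * w


def _conv_out(size: int, kernel: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - kernel) // stride + 1


def _block_layer_names(stage: int, block: str, downsample: bool) -> list[str]:
    p = f"{stage}{block}"
    names = [f"res{p}_branch2a"]
    if downsample:
        names += [f"res{p}_branch1", f"bn{p}_branch1"]
    names += [
        f"bn{p}_branch2a",
        f"res{p}_branch2a_relu",
        f"res{p}_branch2b",
        f"bn{p}_branch2b",
        f"res{p}",
        f"res{p}_relu",
    ]
    return names


def enumerate_layers(
    backbone_id: str = "resnet18", input_size: int = 224
) -> list[LayerSpec]:
    """Ordered list of probe-able layers with output shapes.

    For ``input_size=224`` the list has 67 entries, from ``conv1`` at index
    1 through ``pool5`` at index 67.
    """
    if backbone_id not in BACKBONES:
        raise ValueError(f"unknown backbone_id: {backbone_id!r}")
    specs: list[tuple[str, tuple[int, int, int]]] = []
    s = _conv_out(input_size, 7, 2, 3)
    specs += [(n, (s, s, 64)) for n in ("conv1", "bn_conv1", "conv1_relu")]
    s = _conv_out(s, 3, 2, 1)
    specs.append(("pool1", (s, s, 64)))
    for stage, blocks, channels, downsample in _STAGES:
        for block in blocks:
            ds = downsample and block == "a"
            if ds:
                s = _conv_out(s, 3, 2, 1)
            for name in _block_layer_names(stage, block, ds):
                specs.append((name, (s, s, channels)))
    specs.append(("pool5", (1, 1, 512)))
    return [LayerSpec(i + 1, n, shape) for i, (n, shape) in enumerate(specs)]


def count_layer_attributes(
    layers: list[LayerSpec], shape: tuple[int, int, int]
) -> int:
    """Total activation count over all layers with the given output shape."""
    a, b, w = shape
    return sum(1 for sp in layers if sp.output_shape == tuple(shape)) * a * b * w


def total_attributes(layers: list[LayerSpec]) -> int:
    """Total activation count of the enumeration (~8.23M for ResNet-18)."""
    return sum(sp.n_attributes for sp in layers)


# ---------------------------------------------------------------------------
# forward pass


def _conv2d(x: np.ndarray, w: np.ndarray, stride: int, pad: int) -> np.ndarray:
    """x: (Cin, H, W); w: (Cout, Cin, k, k) -> (Cout, Ho, Wo)."""
    k = w.shape[-1]
    if pad:
        x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    return np.tensordot(w, win, axes=([1, 2, 3], [0, 3, 4]))


def _maxpool(x: np.ndarray, k: int = 3, stride: int = 2, pad: int = 1) -> np.ndarray:
    x = np.pad(x, ((0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
    win = sliding_window_view(x, (k, k), axis=(1, 2))[:, ::stride, ::stride]
    return win.max(axis=(-2, -1))


class ResNet18:
    """NumPy inference-only ResNet-18 feature extractor.

    Parameters
    ----------
    weights : {"random"} or path
        "random" draws seeded He-initialised convolution weights and mildly
        randomised batch-norm affine parameters; a path ending in ``.npz``
        loads named parameter arrays (``<conv>.weight``, ``<bn>.gamma``,
        ``<bn>.beta``, ``<bn>.mean``, ``<bn>.var``).
    seed : int
        Seed for the random weight draw.
    """

    backbone_id = "resnet18"

    def __init__(self, weights: str = "random", seed: int = 0):
        self.weights_mode = weights
        self.seed = seed
        if weights == "random":
            self.params = self._random_params(np.random.default_rng(seed))
        elif str(weights).endswith(".npz"):
            with np.load(weights) as npz:
                self.params = {k: np.asarray(npz[k], dtype=np.float64) for k in npz.files}
        else:
            raise ValueError(f"unknown weights mode: {weights!r}")

    # -- parameters ---------------------------------------------------------

    @staticmethod
    def _conv_param(rng, cout, cin, k):
        std = np.sqrt(2.0 / (cin * k * k))
        return rng.normal(0.0, std, (cout, cin, k, k))

    @staticmethod
    def _bn_param(rng, c):
        return {
            "gamma": rng.uniform(0.8, 1.2, c),
            "beta": rng.normal(0.0, 0.05, c),
            "mean": np.zeros(c),
            "var": np.ones(c),
        }

    def _random_params(self, rng) -> dict[str, np.ndarray]:
        params: dict[str, np.ndarray] = {"conv1.weight": self._conv_param(rng, 64, 3, 7)}
        for key, val in self._bn_param(rng, 64).items():
            params[f"bn_conv1.{key}"] = val
        cin = 64
        for stage, blocks, channels, downsample in _STAGES:
            for block in blocks:
                p = f"{stage}{block}"
                ds = downsample and block == "a"
                params[f"res{p}_branch2a.weight"] = self._conv_param(rng, channels, cin, 3)
                params[f"res{p}_branch2b.weight"] = self._conv_param(rng, channels, channels, 3)
                for bn in (f"bn{p}_branch2a", f"bn{p}_branch2b"):
                    for key, val in self._bn_param(rng, channels).items():
                        params[f"{bn}.{key}"] = val
                if ds:
                    params[f"res{p}_branch1.weight"] = self._conv_param(rng, channels, cin, 1)
                    for key, val in self._bn_param(rng, channels).items():
                        params[f"bn{p}_branch1.{key}"] = val
                cin = channels
        return params

    # -- graph --------------------------------------------------------------

    def _bn(self, name: str, x: np.ndarray) -> np.ndarray:
        g = self.params[f"{name}.gamma"][:, None, None]
        b = self.params[f"{name}.beta"][:, None, None]
        m = self.params[f"{name}.mean"][:, None, None]
        v = self.params[f"{name}.var"][:, None, None]
        return (x - m) / np.sqrt(v + _BN_EPS) * g + b

    def forward(
        self, x: np.ndarray, upto: str | None = None
    ) -> dict[str, np.ndarray]:
        """Run the graph on one image tensor ``(3, H, W)``.

        Returns an ordered dict mapping layer name to activation tensor
        ``(C, h, w)``.  If ``upto`` is given, computation stops as soon as
        that layer has been recorded.
        """
        acts: dict[str, np.ndarray] = {}

        def rec(name: str, t: np.ndarray) -> np.ndarray:
            acts[name] = t
            if name == upto:
                raise _Done
            return t

        try:
            t = rec("conv1", _conv2d(x, self.params["conv1.weight"], 2, 3))
            t = rec("bn_conv1", self._bn("bn_conv1", t))
            t = rec("conv1_relu", np.maximum(t, 0.0))
            t = rec("pool1", _maxpool(t))
            for stage, blocks, _channels, downsample in _STAGES:
                for block in blocks:
                    p = f"{stage}{block}"
                    ds = downsample and block == "a"
                    stride = 2 if ds else 1
                    inp = t
                    t = rec(
                        f"res{p}_branch2a",
                        _conv2d(inp, self.params[f"res{p}_branch2a.weight"], stride, 1),
                    )
                    if ds:
                        sc = rec(
                            f"res{p}_branch1",
                            _conv2d(inp, self.params[f"res{p}_branch1.weight"], 2, 0),
                        )
                        sc = rec(f"bn{p}_branch1", self._bn(f"bn{p}_branch1", sc))
                    else:
                        sc = inp
                    t = rec(f"bn{p}_branch2a", self._bn(f"bn{p}_branch2a", t))
                    t = rec(f"res{p}_branch2a_relu", np.maximum(t, 0.0))
                    t = rec(
                        f"res{p}_branch2b",
                        _conv2d(t, self.params[f"res{p}_branch2b.weight"], 1, 1),
                    )
                    t = rec(f"bn{p}_branch2b", self._bn(f"bn{p}_branch2b", t))
                    t = rec(f"res{p}", t + sc)
                    t = rec(f"res{p}_relu", np.maximum(t, 0.0))
            rec("pool5", t.mean(axis=(1, 2), keepdims=True))
        except _Done:
            pass
        if upto is not None and upto not in acts:
            raise KeyError(f"unknown layer name: {upto!r}")
        return acts

    def activation(self, x: np.ndarray, layer: str) -> np.ndarray:
        """Activation tensor ``(C, h, w)`` of one layer for one image."""
        return self.forward(x, upto=layer)[layer]


class _Done(Exception):
    pass
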