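"""Declarative CNN architecture specs, closed-form parameter counting, and
the weighted categorical cross-entropy loss.

Two architectures are provided:

* ``spec_cnn2d`` - a six-layer 2D conv net (filters 8, 8, 16, 16, 32, 32;
  kernel 3; strides alternating 1/2; SAME padding; ReLU) with a single dense
  softmax head.  On a 128x128x8 input with 3 classes it has exactly 43,123
  trainable parameters (18,544 conv + 24,579 dense).
* ``spec_vgg16_3d`` - a VGG-16 variant with thirteen 3D conv layers in five
  blocks (filters 64,64 | 128,128 | 256,256,256 | 256,256,256 | 512,512,512),
  2x2x2 ceil-mode max pooling after each block so an 8-deep band axis
  survives (8-4-2-1-1-1), He-uniform init, then dense 4096 / dropout 0.5 /
  dense 4096 / dropout 0.5 / softmax.  The hidden dense widths are
  configurable since only the layer count of the head is fixed.

Specs can be instantiated into trainable NumPy networks (``build_model``);
``count_parameters`` is independent of instantiation and is cross-checked
against instantiated networks in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import nn

VALID_KINDS = ("conv2d", "conv3d", "maxpool3d", "flatten", "dense", "dropout",
               "softmax_output")


class ShapeCollapseError(ValueError):
    """A layer schedule reduced some axis to zero."""


@dataclass(frozen=True)
class LayerSpec:
    kind: str
    filters: int | None = None
    units: int | None = None
    kernel: int = 3
    stride: int = 1
    padding: str = "same"
    activation: str = "none"
    init: str = "default"
    rate: float | None = None

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("conv2d", "conv3d") and not self.filters:
            raise ValueError(f"{self.kind} requires filters")
        if self.kind in ("dense", "softmax_output") and not self.units:
            raise ValueError(f"{self.kind} requires units")
        if self.kind == "dropout" and self.rate is None:
            raise ValueError("dropout requires rate")
        if self.kernel < 1 or self.stride < 1:
            raise ValueError("kernel and stride must be >= 1")


@dataclass(frozen=True)
class ArchitectureSpec:
    name: str
    input_shape: tuple[int, ...]
    layers: tuple[LayerSpec, ...]
    class_count: int

    def __post_init__(self):
        last = self.layers[-1]
        if last.kind != "softmax_output" or last.units != self.class_count:
            raise ValueError("last layer must be softmax_output over class_count")
        propagate_shapes(self)   # raises on collapse

    def to_yaml(self) -> str:
        payload = {
            "name": self.name,
            "input_shape": list(self.input_shape),
            "class_count": self.class_count,
            "layers": [
                {k: v for k, v in asdict(layer).items() if v is not None}
                for layer in self.layers],
        }
        return yaml.safe_dump(payload, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ArchitectureSpec":
        data = yaml.safe_load(text)
        return cls(
            name=data["name"], input_shape=tuple(data["input_shape"]),
            layers=tuple(LayerSpec(**layer) for layer in data["layers"]),
            class_count=data["class_count"])

    def describe(self) -> str:
        """Human-readable layer table with per-layer parameter counts."""
        rows = [f"{self.name}  input={self.input_shape}"]
        shape = self.input_shape
        total = 0
        for layer in self.layers:
            new_shape, params = _propagate_one(shape, layer)
            total += params
            rows.append(f"  {layer.kind:<15} out={new_shape!s:<20} params={params}")
            shape = new_shape
        rows.append(f"  total trainable parameters: {total}")
        return "\n".join(rows)


def _ceil_div(a: int, b: int) -> int:
    return -(-a // b)


def _propagate_one(shape: tuple[int, ...], layer: LayerSpec) -> tuple[tuple[int, ...], int]:
    """Return (output shape, trainable parameter count) for one layer."""
    if layer.kind == "conv2d":
        h, w, c = shape
        s = layer.stride
        out = (_ceil_div(h, s), _ceil_div(w, s), layer.filters)
        params = layer.kernel ** 2 * c * layer.filters + layer.filters
    elif layer.kind == "conv3d":
        h, w, d, c = shape
        s = layer.stride
        out = (_ceil_div(h, s), _ceil_div(w, s), _ceil_div(d, s), layer.filters)
        params = layer.kernel ** 3 * c * layer.filters + layer.filters
    elif layer.kind == "maxpool3d":
        h, w, d, c = shape
        p = layer.kernel
        out = (_ceil_div(h, p), _ceil_div(w, p), _ceil_div(d, p), c)
        params = 0
    elif layer.kind == "flatten":
        out = (int(np.prod(shape)),)
        params = 0
    elif layer.kind in ("dense", "softmax_output"):
        (n,) = shape
        out = (layer.units,)
        params = n * layer.units + layer.units
    elif layer.kind == "dropout":
        out = shape
        params = 0
    else:  # pragma: no cover
        raise ValueError(layer.kind)
    if any(x <= 0 for x in out):
        raise ShapeCollapseError(f"{layer.kind} collapsed shape {shape} to {out}")
    return out, params


def propagate_shapes(spec: ArchitectureSpec) -> list[tuple[int, ...]]:
    """Shapes after each layer; raises ShapeCollapseError on a dead axis."""
    shapes = []
    shape = spec.input_shape
    for layer in spec.layers:
        shape, _ = _propagate_one(shape, layer)
        shapes.append(shape)
    return shapes


def count_parameters(spec: ArchitectureSpec) -> int:
    """Closed-form trainable parameter total, layer by layer."""
    total = 0
    shape = spec.input_shape
    for layer in spec.layers:
        shape, params = _propagate_one(shape, layer)
        total += params
    return total


def spec_cnn2d(input_shape: tuple[int, int, int] = (128, 128, 8),
               class_count: int = 3) -> ArchitectureSpec:
    """The six-conv-layer 2D CNN; band axis enters as input channels."""
    if min(input_shape[:2]) < 16:
        raise ValueError("spatial input must be at least 16 px")
    convs = []
    for filters, stride in [(8, 1), (8, 2), (16, 1), (16, 2), (32, 1), (32, 2)]:
        convs.append(LayerSpec(kind="conv2d", filters=filters, kernel=3,
                               stride=stride, activation="relu"))
    layers = (*convs, LayerSpec(kind="flatten"),
              LayerSpec(kind="softmax_output", units=class_count,
                        activation="softmax"))
    return ArchitectureSpec(name="cnn2d", input_shape=tuple(input_shape),
                            layers=layers, class_count=class_count)


VGG_BLOCKS = ((64, 64), (128, 128), (256, 256, 256), (256, 256, 256),
              (512, 512, 512))


def spec_vgg16_3d(input_shape: tuple[int, int, int, int] = (128, 128, 8, 1),
                  class_count: int = 3,
                  dense_units: tuple[int, int] = (4096, 4096),
                  dropout_rate: float = 0.5) -> ArchitectureSpec:
    """VGG-16 with 3D convolutions over the full spectral cube."""
    if len(input_shape) != 4:
        raise ValueError("input_shape must be (H, W, B, channels)")
    if input_shape[2] < 1:
        raise ValueError("band axis must be >= 1")
    layers: list[LayerSpec] = []
    for block in VGG_BLOCKS:
        for filters in block:
            layers.append(LayerSpec(kind="conv3d", filters=filters, kernel=3,
                                    stride=1, activation="relu",
                                    init="he_uniform"))
        layers.append(LayerSpec(kind="maxpool3d", kernel=2, stride=2))
    layers.append(LayerSpec(kind="flatten"))
    for units in dense_units:
        layers.append(LayerSpec(kind="dense", units=units, activation="relu",
                                init="he_uniform"))
        layers.append(LayerSpec(kind="dropout", rate=dropout_rate, units=None))
    layers.append(LayerSpec(kind="softmax_output", units=class_count,
                            activation="softmax", init="he_uniform"))
    return ArchitectureSpec(name="vgg16_3d", input_shape=tuple(input_shape),
                            layers=tuple(layers), class_count=class_count)


@dataclass
class TrainableModel:
    """An instantiated network plus its declarative spec."""

    spec: ArchitectureSpec
    network: nn.Network
    parameter_count: int = field(init=False)

    def __post_init__(self):
        self.parameter_count = self.network.parameter_count
        expected = count_parameters(self.spec)
        if self.parameter_count != expected:
            raise AssertionError(
                f"instantiated count {self.parameter_count} != "
                f"closed form {expected}")

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return self.network.predict_proba(self._shape_input(x))

    def predict_indices(self, x: np.ndarray) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)

    def _shape_input(self, x: np.ndarray) -> np.ndarray:
        """Cubes arrive as (N, H, W, B) or a single (H, W, B); 3D nets need a
        trailing channel axis.  Disambiguated against the spec's input shape."""
        ishape = self.spec.input_shape
        if x.shape == ishape:                                  # single sample
            x = x[None]
        elif x.ndim == 3 and len(ishape) == 4 and x.shape == ishape[:3]:
            x = x[None]
        if len(ishape) == 4 and x.ndim == 4:                   # add channel
            x = x[..., None]
        return x


def build_model(spec: ArchitectureSpec, seed: int = 0) -> TrainableModel:
    """Instantiate the spec as a NumPy network with seeded initialization."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    layers: list[nn.Layer] = []
    shape = spec.input_shape
    for layer in spec.layers:
        if layer.kind == "conv2d":
            init = "he_uniform" if layer.init == "he_uniform" else "glorot_uniform"
            layers.append(nn.Conv2D(shape[-1], layer.filters, layer.kernel,
                                    layer.stride, layer.activation, init, rng))
        elif layer.kind == "conv3d":
            init = "he_uniform" if layer.init == "he_uniform" else "glorot_uniform"
            layers.append(nn.Conv3D(shape[-1], layer.filters, layer.kernel,
                                    layer.stride, layer.activation, init, rng))
        elif layer.kind == "maxpool3d":
            layers.append(nn.MaxPool3D(layer.kernel))
        elif layer.kind == "flatten":
            layers.append(nn.Flatten())
        elif layer.kind == "dense":
            init = "he_uniform" if layer.init == "he_uniform" else "glorot_uniform"
            layers.append(nn.Dense(shape[0], layer.units, layer.activation,
                                   init, rng))
        elif layer.kind == "dropout":
            layers.append(nn.Dropout(layer.rate))
        elif layer.kind == "softmax_output":
            init = "he_uniform" if layer.init == "he_uniform" else "glorot_uniform"
            layers.append(nn.Dense(shape[0], layer.units, "none", init, rng))
        shape, _ = _propagate_one(shape, layer)
    return TrainableModel(spec=spec, network=nn.Network(layers))


LOG_EPS = 1e-7


def weighted_categorical_cross_entropy(truth_onehot: np.ndarray,
                                       scores: np.ndarray,
                                       weights: np.ndarray | None = None) -> float:
    """Batch-mean weighted categorical cross-entropy on softmax scores.

    ``scores`` must already be softmax-normalized (each row summing to one
    within 1e-5); ``weights`` is one loss weight per class.  With unit
    weights this is the plain categorical cross-entropy.
    """
    t = np.atleast_2d(np.asarray(truth_onehot, dtype=float))
    s = np.atleast_2d(np.asarray(scores, dtype=float))
    if t.shape != s.shape:
        raise ValueError("truth and scores must share a shape")
    sums = s.sum(axis=1)
    if np.any(np.abs(sums - 1.0) > 1e-5):
        raise ValueError("scores are not softmax-normalized")
    w = np.ones(s.shape[1]) if weights is None else np.asarray(weights, dtype=float)
    per_sample = -(w * t * np.log(np.maximum(s, LOG_EPS))).sum(axis=1)
    return float(per_sample.mean())
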