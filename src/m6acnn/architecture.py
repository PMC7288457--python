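"""Declarative model specification and a pure shape-inference calculus.

A :class:`ModelSpec` is an ordered list of layer specifications. Shape
inference walks the list applying valid-convolution arithmetic
(``out = floor((L - k) / s) + 1``) and the analogous pooling rule, so a
spec can be checked for feasibility — and its parameter count computed —
without touching any numerical backend. :func:`build_model` turns a spec
into a trainable network.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Union

LayerSpec = Union[
    "ConvLayerSpec",
    "EluSpec",
    "GroupNormSpec",
    "MaxPoolSpec",
    "DropoutSpec",
    "FlattenSpec",
    "DenseSpec",
    "SigmoidSpec",
]


class InfeasibleArchitectureError(ValueError):
    """Shape inference failed (kernel/pool larger than input, bad grouping...)."""


@dataclass(frozen=True)
class ConvLayerSpec:
    """1-D convolution, valid (no-padding) mode."""

    filters: int
    kernel_size: int
    stride: int = 1
    weight_l2: float = 0.0
    bias_l2: float = 0.0


@dataclass(frozen=True)
class EluSpec:
    alpha: float = 1.0


@dataclass(frozen=True)
class GroupNormSpec:
    """Channel group normalization; ``groups`` must divide the channel count."""

    groups: int
    eps: float = 1e-5


@dataclass(frozen=True)
class MaxPoolSpec:
    pool_size: int
    stride: int


@dataclass(frozen=True)
class DropoutSpec:
    rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {self.rate}")


@dataclass(frozen=True)
class FlattenSpec:
    pass


@dataclass(frozen=True)
class DenseSpec:
    units: int
    activation: str | None = None  # one of {"elu", None}
    weight_l2: float = 0.0
    bias_l2: float = 0.0


@dataclass(frozen=True)
class SigmoidSpec:
    pass


@dataclass(frozen=True)
class ModelSpec:
    """Ordered layer stack plus the (length, channels) input shape."""

    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int] = (51, 4)

    def to_dict(self) -> dict:
        entries = []
        for layer in self.layers:
            entry = {"kind": type(layer).__name__}
            entry.update(asdict(layer))
            entries.append(entry)
        return {"input_shape": list(self.input_shape), "layers": entries}

    @classmethod
    def from_dict(cls, data: dict) -> "ModelSpec":
        kinds = {
            c.__name__: c
            for c in (
                ConvLayerSpec,
                EluSpec,
                GroupNormSpec,
                MaxPoolSpec,
                DropoutSpec,
                FlattenSpec,
                DenseSpec,
                SigmoidSpec,
            )
        }
        layers = []
        for entry in data["layers"]:
            entry = dict(entry)
            cls_ = kinds[entry.pop("kind")]
            layers.append(cls_(**entry))
        return cls(layers=tuple(layers), input_shape=tuple(data["input_shape"]))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelSpec":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer and schedule: SGD with momentum, binary cross-entropy loss."""

    learning_rate: float = 0.003
    momentum: float = 0.95
    epochs: int = 100
    batch_size: int = 32
    early_stop_patience: int = 30
    monitor: str = "val_accuracy"  # or "val_loss"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning_rate, epochs, batch_size must be positive")
        if self.early_stop_patience > self.epochs:
            raise ValueError("early_stop_patience must not exceed epochs")
        if self.monitor not in ("val_accuracy", "val_loss"):
            raise ValueError(f"unknown monitor {self.monitor!r}")


def default_model_spec(
    input_shape: tuple[int, int] = (51, 4),
    *,
    conv_l2: float = 0.001,
    dense_l2: float = 0.0001,
    dropout: float = 0.35,
) -> ModelSpec:
    """The reference two-block architecture.

    Input(51,4) -> [Conv1D(16,5,1) -> ELU -> GroupNorm(4) -> MaxPool(4,2)] x2
    -> Flatten -> Dropout(0.35) -> Dense(32, ELU) -> Dense(1) -> Sigmoid,
    with L2 of 0.001 on conv weights and biases and 0.0001 on dense.
    """
    block = (
        ConvLayerSpec(16, 5, 1, weight_l2=conv_l2, bias_l2=conv_l2),
        EluSpec(),
        GroupNormSpec(4),
        MaxPoolSpec(4, 2),
    )
    layers = block + block + (
        FlattenSpec(),
        DropoutSpec(dropout),
        DenseSpec(32, activation="elu", weight_l2=dense_l2, bias_l2=dense_l2),
        DenseSpec(1, activation=None, weight_l2=dense_l2, bias_l2=dense_l2),
        SigmoidSpec(),
    )
    return ModelSpec(layers=layers, input_shape=input_shape)


def conv_output_length(length: int, kernel: int, stride: int) -> int:
    """Valid-mode output length: floor((L - k)/s) + 1."""
    if kernel > length:
        raise InfeasibleArchitectureError(
            f"kernel/pool size {kernel} exceeds input length {length}"
        )
    return (length - kernel) // stride + 1


def infer_shapes(spec: ModelSpec) -> list[tuple[int, ...]]:
    """Per-layer output shapes, one entry per layer in ``spec.layers``.

    Before flattening, entries are (length, channels); after, (units,).
    Raises :class:`InfeasibleArchitectureError` if any layer cannot be
    applied to its incoming shape.
    """
    shape: tuple[int, ...] = tuple(spec.input_shape)
    shapes: list[tuple[int, ...]] = []
    for layer in spec.layers:
        if isinstance(layer, ConvLayerSpec):
            if len(shape) != 2:
                raise InfeasibleArchitectureError("convolution after flatten")
            length = conv_output_length(shape[0], layer.kernel_size, layer.stride)
            shape = (length, layer.filters)
        elif isinstance(layer, MaxPoolSpec):
            if len(shape) != 2:
                raise InfeasibleArchitectureError("pooling after flatten")
            length = conv_output_length(shape[0], layer.pool_size, layer.stride)
            shape = (length, shape[1])
        elif isinstance(layer, GroupNormSpec):
            if len(shape) != 2:
                raise InfeasibleArchitectureError("group norm after flatten")
            if shape[1] % layer.groups != 0:
                raise InfeasibleArchitectureError(
                    f"{layer.groups} groups do not divide {shape[1]} channels"
                )
        elif isinstance(layer, FlattenSpec):
            size = 1
            for dim in shape:
                size *= dim
            shape = (size,)
        elif isinstance(layer, DenseSpec):
            if len(shape) != 1:
                raise InfeasibleArchitectureError("dense layer requires flat input")
            shape = (layer.units,)
        elif isinstance(layer, (EluSpec, DropoutSpec, SigmoidSpec)):
            pass
        else:  # pragma: no cover - exhaustive over LayerSpec
            raise TypeError(f"unknown layer spec {layer!r}")
        shapes.append(shape)
    return shapes


def count_parameters(spec: ModelSpec) -> int:
    """Exact trainable-parameter count.

    Conv: (k * C_in + 1) * f.  GroupNorm: 2 * C (scale + shift).
    Dense: (in + 1) * units.  Other layers have none.
    """
    shape: tuple[int, ...] = tuple(spec.input_shape)
    total = 0
    for layer, out_shape in zip(spec.layers, infer_shapes(spec)):
        if isinstance(layer, ConvLayerSpec):
            total += (layer.kernel_size * shape[1] + 1) * layer.filters
        elif isinstance(layer, GroupNormSpec):
            total += 2 * shape[1]
        elif isinstance(layer, DenseSpec):
            total += (shape[0] + 1) * layer.units
        shape = out_shape
    return total


def build_model(spec: ModelSpec, config: TrainingConfig):
    """Construct a trainable network from a spec (NumPy backend).

    The returned handle exposes ``fit`` / ``predict_proba`` / ``save``; its
    per-layer output shapes match :func:`infer_shapes` exactly.
    """
    from .nn import Network

    infer_shapes(spec)  # fail fast on infeasible specs
    return Network(spec, config)
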