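"""Compact CNN classifiers for optical-flow micro-expression images.

The base network takes a ``C x 75 x 75`` optical-flow image through five
convolutional layers (96, 256, 512, 512, 512 filters), three overlapping
max-pool layers and three dense layers (128, 128, n_classes), ending in a
softmax over the emotion classes (positive / negative / surprise by
default).  The spatial chain on a 75x75 input is fixed by construction:

    Conv1 69 -> Conv2 65 -> Conv3 65 -> Pool3 32 -> Conv4 32
    -> Pool4 16 -> Conv5 16 -> Pool5 8

Variants insert one multi-scale block (SPP or ASPP branches, direct or
waterfall flow; see :mod:`wasppnet.multiscale`) after Conv1 or Conv2; the
following convolution is widened to accept the concatenated channels and
everything else is unchanged.  Named presets cover the SPP-I..VIII and
ASPP-I..VIII grid plus the four flow networks DSPP, WSPP, DASPP, WASPP.

A ``width`` multiplier shrinks every channel/unit count proportionally
for desk-scale experiments; ``width=1`` is the full-size network.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

from . import nn
from .nn import (Conv2d, Dense, Flatten, GeometryError, MaxPool2d, ReLU,
                 Sequential, Softmax, softmax)
from .multiscale import MultiScaleBlock

__all__ = [
    "LayerSpec", "ArchitectureSpec", "ModelSummary", "Network",
    "AssemblyError", "infer_output_side", "build_base_cnn", "build_variant",
    "count_parameters", "summarize", "get_preset", "PRESET_NAMES",
    "save_checkpoint", "load_checkpoint", "INPUT_SIDE",
]

INPUT_SIDE = 75

#: Branch parameter pools: an SPP grid model with m branches uses the
#: first m entries; an ASPP grid model with m branches uses rates 1..m.
SPP_POOL_SET = (2, 4, 6, 8, 10)

#: The four flow networks use these four-branch sets.
FLOW_SPP_POOLS = (4, 6, 8, 10)
FLOW_ASPP_RATES = (2, 3, 4, 5)


class AssemblyError(ValueError):
    """Raised when the constructed layer chain cannot reproduce the
    expected output-shape chain."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class LayerSpec:
    """One row of the base-network table."""
    name: str
    op_kind: str                    # conv | maxpool | avgpool | dense
    kernel: int = 0
    stride: int = 1
    effective_padding: int = 0
    out_channels_or_units: int = 0
    activation: str = "none"        # relu | softmax | none

    def __post_init__(self):
        if self.op_kind not in ("conv", "maxpool", "avgpool", "dense"):
            raise ValueError(f"unknown op_kind {self.op_kind!r}")
        if self.op_kind != "dense" and self.kernel < 1:
            raise ValueError("kernel must be >= 1")
        if self.stride < 1 or self.effective_padding < 0:
            raise ValueError("invalid stride/padding")
        if self.out_channels_or_units < 0:
            raise ValueError("out_channels_or_units must be >= 0")


# The base table.  The printed padding column of the source architecture
# is inconsistent with its printed output sizes; the effective paddings
# below are the unique values reproducing the 69/65/65/32/32/16/16/8
# spatial chain under floor arithmetic, so the output sizes win.
_BASE_ROWS = (
    LayerSpec("Conv1", "conv", 7, 1, 0, 96, "relu"),
    LayerSpec("Conv2", "conv", 5, 1, 0, 256, "relu"),
    LayerSpec("Conv3", "conv", 3, 1, 1, 512, "relu"),
    LayerSpec("Pool3", "maxpool", 3, 2, 0),
    LayerSpec("Conv4", "conv", 3, 1, 1, 512, "relu"),
    LayerSpec("Pool4", "maxpool", 3, 2, 1),
    LayerSpec("Conv5", "conv", 3, 1, 1, 512, "relu"),
    LayerSpec("Pool5", "maxpool", 3, 2, 1),
    LayerSpec("FC1", "dense", out_channels_or_units=128, activation="relu"),
    LayerSpec("FC2", "dense", out_channels_or_units=128, activation="relu"),
    LayerSpec("FC3", "dense", out_channels_or_units=0, activation="softmax"),
)

#: Expected spatial sides after each conv/pool row on a 75x75 input.
EXPECTED_SIDES = {"Conv1": 69, "Conv2": 65, "Conv3": 65, "Pool3": 32,
                  "Conv4": 32, "Pool4": 16, "Conv5": 16, "Pool5": 8}


@dataclasses.dataclass(frozen=True)
class ArchitectureSpec:
    """Complete description of one network variant."""
    module_kind: str = "none"            # none | spp | aspp
    flow: str = "direct"                 # direct | waterfall
    n_branches: int = 0
    branch_params: tuple[int, ...] = ()  # pool sides (spp) / rates (aspp)
    placement: str = "after_conv2"       # after_conv1 | after_conv2
    branch_channels: int = 64
    input_channels: int = 3
    n_classes: int = 3
    width: float = 1.0
    chain_resized: bool = False
    name: str = ""

    def __post_init__(self):
        if self.module_kind not in ("none", "spp", "aspp"):
            raise ValueError(f"unknown module_kind {self.module_kind!r}")
        if self.flow not in ("direct", "waterfall"):
            raise ValueError(f"unknown flow {self.flow!r}")
        if self.placement not in ("after_conv1", "after_conv2"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.width <= 0:
            raise ValueError("width must be > 0")
        if self.module_kind != "none":
            if len(self.branch_params) != self.n_branches:
                raise ValueError("branch_params length must equal n_branches")
            if not 1 <= self.n_branches <= 5:
                raise ValueError("n_branches must be in [1, 5]")
            if list(self.branch_params) != sorted(set(self.branch_params)):
                raise ValueError("branch_params must be strictly increasing")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        d = dict(d)
        d["branch_params"] = tuple(d.get("branch_params", ()))
        return cls(**d)


@dataclasses.dataclass
class ModelSummary:
    layer_names: list[str]
    output_shapes: list[tuple[int, ...]]
    total_parameters: int

    def shape_of(self, name: str) -> tuple[int, ...]:
        return self.output_shapes[self.layer_names.index(name)]

    def to_text(self) -> str:
        rows = [f"{'Layer':<10}{'Size of Output':<20}"]
        rows.append("-" * 30)
        for name, shape in zip(self.layer_names, self.output_shapes):
            pretty = " x ".join(str(s) for s in shape)
            rows.append(f"{name:<10}{pretty:<20}")
        rows.append("-" * 30)
        rows.append(f"Total parameters: {self.total_parameters:,}")
        return "\n".join(rows)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def infer_output_side(input_side: int, kernel: int, stride: int,
                      padding: int, layer_name: str = "layer") -> int:
    """floor((input_side + 2*padding - kernel) / stride) + 1."""
    if min(input_side, kernel) < 0 or padding < 0 or stride < 1:
        raise ValueError("arguments must be non-negative, stride >= 1")
    if input_side < kernel - 2 * padding:
        raise GeometryError(
            f"{layer_name}: kernel {kernel} exceeds padded input "
            f"{input_side + 2 * padding}")
    out = (input_side + 2 * padding - kernel) // stride + 1
    if out < 1:
        raise GeometryError(f"{layer_name}: non-positive output size {out}")
    return out


def _scaled(value: int, width: float, floor: int) -> int:
    return max(floor, int(round(value * width)))


# ---------------------------------------------------------------------------
# Network container
# ---------------------------------------------------------------------------

class Network(Sequential):
    """A named stage chain with an attached :class:`ArchitectureSpec`.

    ``forward`` yields class probabilities (softmax applied);
    ``forward_logits``/``backward_from_logits`` expose the pre-softmax
    path used with the fused cross-entropy loss during training.
    """

    def __init__(self, layers, spec: ArchitectureSpec,
                 input_side: int = INPUT_SIDE) -> None:
        super().__init__(layers)
        self.spec = spec
        self.input_side = input_side

    def forward_logits(self, x, train: bool = False):
        for _, stage in self.layers[:-1]:
            x = stage.forward(x, train=train)
        for _, op in self.layers[-1][1].layers:
            if isinstance(op, Softmax):
                break
            x = op.forward(x, train=train)
        return x

    def backward_from_logits(self, grad):
        last = self.layers[-1][1]
        for _, op in reversed([(n, l) for n, l in last.layers
                               if not isinstance(l, Softmax)]):
            grad = op.backward(grad)
        for _, stage in reversed(self.layers[:-1]):
            grad = stage.backward(grad)
        return grad

    def forward(self, x, train: bool = False):
        return softmax(self.forward_logits(x, train=train))

    predict_proba = forward

    def predict(self, x) -> np.ndarray:
        return self.forward(np.asarray(x, dtype=nn.DTYPE)).argmax(axis=1)


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def _base_rows(spec: ArchitectureSpec) -> list[LayerSpec]:
    rows = []
    for row in _BASE_ROWS:
        if row.op_kind == "conv":
            out = _scaled(row.out_channels_or_units, spec.width, 4)
            rows.append(dataclasses.replace(row, out_channels_or_units=out))
        elif row.op_kind == "dense":
            if row.name == "FC3":
                rows.append(dataclasses.replace(
                    row, out_channels_or_units=spec.n_classes))
            else:
                out = _scaled(row.out_channels_or_units, spec.width, 16)
                rows.append(dataclasses.replace(row,
                                                out_channels_or_units=out))
        else:
            rows.append(row)
    return rows


def build_variant(spec: ArchitectureSpec, seed: int = 0,
                  input_side: int = INPUT_SIDE) -> Network:
    """Assemble the network a spec describes (base model when
    ``module_kind == 'none'``).

    The multi-scale block is inserted immediately after the placement
    layer's activation; the next convolution's input channel count is
    widened to the concatenated channel count.  The spatial chain is
    verified against the expected sides during assembly.
    """
    rng = np.random.default_rng(seed)
    rows = _base_rows(spec)
    insert_after = {"after_conv1": "Conv1",
                    "after_conv2": "Conv2"}[spec.placement]

    stages: list[tuple[str, Sequential | MultiScaleBlock]] = []
    channels = spec.input_channels
    side = input_side
    flat_features = None
    for row in rows:
        if row.op_kind == "conv":
            conv = Conv2d(channels, row.out_channels_or_units, row.kernel,
                          row.stride, row.effective_padding, rng=rng)
            ops: list[tuple[str, nn.Layer]] = [("op", conv)]
            if row.activation == "relu":
                ops.append(("act", ReLU()))
            stages.append((row.name, Sequential(ops)))
            channels = row.out_channels_or_units
            side = infer_output_side(side, row.kernel, row.stride,
                                     row.effective_padding, row.name)
        elif row.op_kind == "maxpool":
            stages.append((row.name, Sequential(
                [("op", MaxPool2d(row.kernel, row.stride,
                                  row.effective_padding))])))
            side = infer_output_side(side, row.kernel, row.stride,
                                     row.effective_padding, row.name)
        else:  # dense
            ops = []
            if flat_features is None:
                flat_features = channels * side * side
                ops.append(("flatten", Flatten()))
                in_features = flat_features
            stages.append((row.name, Sequential(
                ops + [("op", Dense(in_features, row.out_channels_or_units,
                                    rng=rng))]
                + ([("act", ReLU())] if row.activation == "relu" else
                   [("act", Softmax())] if row.activation == "softmax"
                   else []))))
            in_features = row.out_channels_or_units
        if input_side == INPUT_SIDE and row.name in EXPECTED_SIDES:
            if side != EXPECTED_SIDES[row.name]:
                raise AssemblyError(
                    f"{row.name}: expected output side "
                    f"{EXPECTED_SIDES[row.name]}, computed {side}")
        # insert the multi-scale block right after the placement stage
        if spec.module_kind != "none" and row.name == insert_after:
            block = MultiScaleBlock(
                spec.module_kind, spec.flow, list(spec.branch_params),
                channels, side, branch_channels=spec.branch_channels,
                chain_resized=spec.chain_resized, rng=rng)
            stages.append((spec.module_kind.upper(), block))
            channels = block.out_channels
    return Network(stages, spec, input_side)


def build_base_cnn(input_channels: int = 3, n_classes: int = 3,
                   width: float = 1.0, seed: int = 0) -> Network:
    """The five-conv / three-pool / three-dense base classifier."""
    return build_variant(ArchitectureSpec(
        module_kind="none", input_channels=input_channels,
        n_classes=n_classes, width=width, name="base"), seed=seed)


def count_parameters(model: Network) -> int:
    """Total trainable weight and bias element count."""
    return model.n_params()


def summarize(model: Network) -> ModelSummary:
    """Layer-ordered output shapes on a probe input, plus the parameter
    count."""
    x = np.zeros((1, model.spec.input_channels, model.input_side,
                  model.input_side), dtype=nn.DTYPE)
    names, shapes = [], []
    for name, stage in model.layers:
        x = stage.forward(x, train=False)
        names.append(name)
        shapes.append(tuple(x.shape[1:]))
    return ModelSummary(names, shapes, count_parameters(model))


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _grid_presets() -> dict[str, ArchitectureSpec]:
    presets: dict[str, ArchitectureSpec] = {}
    romans = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")
    for idx, roman in enumerate(romans):
        m = 2 + idx % 4
        placement = "after_conv1" if idx < 4 else "after_conv2"
        presets[f"SPP-{roman}"] = ArchitectureSpec(
            "spp", "direct", m, SPP_POOL_SET[:m], placement,
            name=f"SPP-{roman}")
        presets[f"ASPP-{roman}"] = ArchitectureSpec(
            "aspp", "direct", m, tuple(range(1, m + 1)), placement,
            name=f"ASPP-{roman}")
    presets["base"] = ArchitectureSpec(name="base")
    presets["DSPP"] = ArchitectureSpec(
        "spp", "direct", 4, FLOW_SPP_POOLS, "after_conv2", name="DSPP")
    # Waterfall SPP chains from resized stage outputs: raw chaining with
    # these pool sides would shrink the map below one pixel.
    presets["WSPP"] = ArchitectureSpec(
        "spp", "waterfall", 4, FLOW_SPP_POOLS, "after_conv2",
        chain_resized=True, name="WSPP")
    presets["DASPP"] = ArchitectureSpec(
        "aspp", "direct", 4, FLOW_ASPP_RATES, "after_conv2", name="DASPP")
    presets["WASPP"] = ArchitectureSpec(
        "aspp", "waterfall", 4, FLOW_ASPP_RATES, "after_conv2", name="WASPP")
    return presets


_PRESETS = _grid_presets()
PRESET_NAMES = tuple(sorted(_PRESETS))


def get_preset(name: str, width: float = 1.0, input_channels: int = 3,
               n_classes: int = 3) -> ArchitectureSpec:
    """Look up a named preset, optionally width-scaled (branch channel
    width scales along with the trunk)."""
    try:
        spec = _PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose from {PRESET_NAMES}") from None
    branch_channels = (_scaled(spec.branch_channels, width, 2)
                       if spec.module_kind != "none" else spec.branch_channels)
    return dataclasses.replace(
        spec, width=width, branch_channels=branch_channels,
        input_channels=input_channels, n_classes=n_classes)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: Network, path: str | Path) -> None:
    """Write weights to ``<path>`` (npz) and the spec to a JSON sidecar
    ``<path>.json`` so the checkpoint is self-identifying."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(model.spec.to_dict(), indent=2))


def load_checkpoint(path: str | Path) -> Network:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    spec = ArchitectureSpec.from_dict(json.loads(sidecar.read_text()))
    model = build_variant(spec)
    with np.load(path) as archive:
        model.load_state_dict(dict(archive))
    return model
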