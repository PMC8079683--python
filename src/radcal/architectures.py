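"""Declarative architecture specs and builders for the three baseline networks.

Three reference configurations are provided:

* :func:`convnet_spec` — a VGG-style stack of 14 batch-normalized 3x3
  convolutions in pairs of equal width (16..1024), max pooling after each
  pair, then FC(512)/FC(256) and a single logistic output unit.
* :func:`resnet_spec` — 25 full pre-activation residual blocks (identity
  and 1x1-projection types) over 5 width stages, global average pooling
  head.
* :func:`densenet_spec` — the 169-weighted-layer densely connected
  configuration (block sizes 6/12/32/32, growth 32, compression 0.5),
  adapted to single-channel input.

Specs are plain data; :func:`build_model` compiles them into a
:class:`TrainableModel` backed by the NumPy engine in :mod:`radcal.nn`,
and :func:`count_parameters` evaluates the closed-form parameter count
without building anything.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterator

import numpy as np

from . import nn

REFERENCE_INPUT_SHAPE = (256, 256, 1)

CONVNET_WIDTHS = (16, 16, 32, 32, 64, 64, 128, 128, 256, 256, 512, 512, 1024, 1024)


@dataclass(frozen=True)
class LayerSpec:
    """One primitive layer row (kind, output width, stride, kernel size)."""

    kind: str  # conv3x3 | conv1x1 | conv7x7 | maxpool2x2 | avgpool2x2 |
    #            flatten | fully_connected | batch_norm | activation | global_avg_pool
    width: int | None = None
    stride: tuple[int, int] = (1, 1)

    def __post_init__(self):
        if self.kind.startswith("conv") or self.kind == "fully_connected":
            if self.width is None or self.width <= 0:
                raise ValueError(f"{self.kind} requires width > 0")
        if self.kind.startswith("maxpool") and self.width is not None:
            raise ValueError("maxpool carries no width")


@dataclass(frozen=True)
class ResidualBlockSpec:
    """Full pre-activation residual block."""

    block_type: str  # identity_skip | projection_skip
    width: int
    stride: int = 1
    pre_activation: bool = True

    def __post_init__(self):
        if self.block_type not in ("identity_skip", "projection_skip"):
            raise ValueError(f"unknown block_type {self.block_type!r}")
        if self.block_type == "identity_skip" and self.stride != 1:
            raise ValueError("identity_skip blocks cannot change spatial size")


@dataclass(frozen=True)
class DenseBlockSpec:
    n_units: int
    growth: int


@dataclass(frozen=True)
class TransitionSpec:
    compression: float = 0.5


@dataclass(frozen=True)
class ArchitectureSpec:
    name: str
    layers: tuple = ()
    input_shape: tuple[int, int, int] = REFERENCE_INPUT_SHAPE
    head: str = "single logistic unit"

    def conv_layer_count(self) -> int:
        """Number of convolution layers, expanding composite blocks."""
        return sum(1 for kind, *_ in iter_param_layers(self) if kind == "conv")

    def weighted_layer_count(self) -> int:
        """Convolution plus fully-connected layers (the 'depth' in model names)."""
        return sum(1 for kind, *_ in iter_param_layers(self) if kind in ("conv", "dense"))

    def to_dict(self) -> dict:
        def enc(l):
            d = asdict(l)
            d["type"] = type(l).__name__
            return d
        return {
            "name": self.name,
            "input_shape": list(self.input_shape),
            "head": self.head,
            "layers": [enc(l) for l in self.layers],
        }

    @staticmethod
    def from_dict(d: dict) -> "ArchitectureSpec":
        kinds = {
            "LayerSpec": LayerSpec,
            "ResidualBlockSpec": ResidualBlockSpec,
            "DenseBlockSpec": DenseBlockSpec,
            "TransitionSpec": TransitionSpec,
        }
        layers = []
        for e in d["layers"]:
            e = dict(e)
            cls = kinds[e.pop("type")]
            if "stride" in e and isinstance(e["stride"], list):
                e["stride"] = tuple(e["stride"])
            layers.append(cls(**e))
        return ArchitectureSpec(
            name=d["name"],
            layers=tuple(layers),
            input_shape=tuple(d["input_shape"]),
            head=d.get("head", "single logistic unit"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @staticmethod
    def load(path) -> "ArchitectureSpec":
        with open(path) as fh:
            return ArchitectureSpec.from_dict(json.load(fh))


def convnet_spec(input_shape: tuple[int, int, int] = REFERENCE_INPUT_SHAPE) -> ArchitectureSpec:
    """The 14-convolution VGG-style reference stack."""
    layers: list = []
    for i, w in enumerate(CONVNET_WIDTHS):
        layers += [LayerSpec("conv3x3", w), LayerSpec("batch_norm"), LayerSpec("activation")]
        if i % 2 == 1:
            layers.append(LayerSpec("maxpool2x2"))
    layers += [
        LayerSpec("flatten"),
        LayerSpec("fully_connected", 512), LayerSpec("activation"),
        LayerSpec("fully_connected", 256), LayerSpec("activation"),
    ]
    return ArchitectureSpec("convnet", tuple(layers), input_shape)


RESNET_STAGE_WIDTHS = (16, 32, 64, 128, 256)


def resnet_spec(n_blocks: int = 25,
                input_shape: tuple[int, int, int] = REFERENCE_INPUT_SHAPE) -> ArchitectureSpec:
    """Pre-activation residual network with ``n_blocks`` blocks of both types.

    Blocks are spread over (up to) 5 width stages; the first block of each
    stage after the first is a projection block with stride-2 downsampling.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    n_stages = min(5, n_blocks)
    per = [n_blocks // n_stages + (1 if i < n_blocks % n_stages else 0)
           for i in range(n_stages)]
    widths = RESNET_STAGE_WIDTHS[:n_stages]
    layers: list = [LayerSpec("conv3x3", widths[0])]
    for s, (w, count) in enumerate(zip(widths, per)):
        for b in range(count):
            if s > 0 and b == 0:
                layers.append(ResidualBlockSpec("projection_skip", w, stride=2))
            else:
                layers.append(ResidualBlockSpec("identity_skip", w))
    layers += [LayerSpec("batch_norm"), LayerSpec("activation"), LayerSpec("global_avg_pool")]
    return ArchitectureSpec("resnet", tuple(layers), input_shape)


def densenet_spec(input_shape: tuple[int, int, int] = REFERENCE_INPUT_SHAPE) -> ArchitectureSpec:
    """Densely connected configuration with 169 weighted layers.

    1 stem convolution + 2x(6+12+32+32) block convolutions + 3 transition
    convolutions + the classifier = 169, the depth the variant is named
    after.  The stem takes a single grayscale channel directly.
    """
    layers: list = [
        LayerSpec("conv7x7", 64, stride=(2, 2)),
        LayerSpec("batch_norm"), LayerSpec("activation"), LayerSpec("maxpool2x2"),
        DenseBlockSpec(6, 32), TransitionSpec(),
        DenseBlockSpec(12, 32), TransitionSpec(),
        DenseBlockSpec(32, 32), TransitionSpec(),
        DenseBlockSpec(32, 32),
        LayerSpec("batch_norm"), LayerSpec("activation"), LayerSpec("global_avg_pool"),
    ]
    return ArchitectureSpec("densenet", tuple(layers), input_shape)


def tiny_convnet_spec(widths: tuple[int, ...] = (8, 16),
                      input_shape: tuple[int, int, int] = (32, 32, 1),
                      gap_head: bool = True) -> ArchitectureSpec:
    """Small desk-scale stack: conv-BN-ReLU-pool per width, then a GAP or
    flatten head.  Used for fast CPU training in tests and demos."""
    layers: list = []
    for w in widths:
        layers += [LayerSpec("conv3x3", w), LayerSpec("batch_norm"),
                   LayerSpec("activation"), LayerSpec("maxpool2x2")]
    if gap_head:
        layers.append(LayerSpec("global_avg_pool"))
    else:
        layers.append(LayerSpec("flatten"))
    return ArchitectureSpec("tiny", tuple(layers), input_shape)


_KERNELS = {"conv3x3": 3, "conv1x1": 1, "conv7x7": 7}


def iter_param_layers(spec: ArchitectureSpec, include_head: bool = True) -> Iterator[tuple]:
    """Expand a spec (blocks included) into primitive parameterized layers.

    Yields tuples: ``("conv", c_in, c_out, k, stride)``, ``("bn", c)``,
    ``("dense", n_in, n_out)`` plus non-parametric markers ``("relu",)``,
    ``("maxpool",)``, ``("avgpool",)``, ``("gap",)``, ``("flatten",)``.
    The final classifier layer is included.
    """
    h, w, c = spec.input_shape
    for l in spec.layers:
        if isinstance(l, LayerSpec):
            if l.kind in _KERNELS:
                k = _KERNELS[l.kind]
                yield ("conv", c, l.width, k, l.stride[0])
                c = l.width
                h, w = _conv_hw(h, w, k, l.stride[0])
            elif l.kind == "batch_norm":
                yield ("bn", c)
            elif l.kind == "activation":
                yield ("relu",)
            elif l.kind in ("maxpool2x2", "avgpool2x2"):
                if h < 2 or w < 2:
                    raise ValueError(f"pooling exhausts spatial size at {h}x{w}")
                yield ("maxpool",) if l.kind == "maxpool2x2" else ("avgpool",)
                h, w = h // 2, w // 2
            elif l.kind == "global_avg_pool":
                yield ("gap",)
                h = w = 1
            elif l.kind == "flatten":
                yield ("flatten",)
                c, h, w = c * h * w, 1, 1
            elif l.kind == "fully_connected":
                yield ("dense", c, l.width)
                c = l.width
            else:
                raise ValueError(f"unknown layer kind {l.kind!r}")
        elif isinstance(l, ResidualBlockSpec):
            if l.block_type == "identity_skip":
                if l.width != c:
                    raise ValueError("identity_skip must preserve width")
                yield ("bn", c); yield ("relu",)
                yield ("conv", c, c, 3, 1)
                yield ("bn", c); yield ("relu",)
                yield ("conv", c, c, 3, 1)
            else:
                yield ("bn", c); yield ("relu",)
                yield ("conv", c, l.width, 3, l.stride)
                yield ("bn", l.width); yield ("relu",)
                yield ("conv", l.width, l.width, 3, 1)
                yield ("conv", c, l.width, 1, l.stride)  # projection shortcut
                c = l.width
                h, w = _conv_hw(h, w, 3, l.stride)
            if h < 1 or w < 1:
                raise ValueError("block downsampling exhausts spatial size")
        elif isinstance(l, DenseBlockSpec):
            for i in range(l.n_units):
                cin = c + i * l.growth
                yield ("bn", cin); yield ("relu",)
                yield ("conv", cin, 4 * l.growth, 1, 1)
                yield ("bn", 4 * l.growth); yield ("relu",)
                yield ("conv", 4 * l.growth, l.growth, 3, 1)
            c = c + l.n_units * l.growth
        elif isinstance(l, TransitionSpec):
            cout = int(np.floor(c * l.compression))
            yield ("bn", c); yield ("relu",)
            yield ("conv", c, cout, 1, 1)
            yield ("avgpool",)
            c = cout
            h, w = h // 2, w // 2
        else:
            raise TypeError(f"unknown spec element {type(l).__name__}")
    # classifier head: single logistic unit on whatever the body produced
    if include_head:
        n_in = c if h == 1 and w == 1 else c * h * w
        yield ("dense", n_in, 1)


def _conv_hw(h: int, w: int, k: int, s: int) -> tuple[int, int]:
    p = k // 2
    return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1


def count_parameters(spec: ArchitectureSpec,
                     include: tuple[str, ...] = ("conv", "bn", "dense"),
                     include_head: bool = False) -> int:
    """Closed-form parameter count over the spec's declared layers.

    conv k x k, c_in -> c_out: ``k*k*c_in*c_out + c_out``; batch norm:
    ``4*c`` (scale, shift, running mean/var); dense: ``n_in*n_out + n_out``.
    ``include`` restricts the sum, e.g. ``("conv",)`` counts the
    convolutional stack alone; ``include_head`` adds the implicit
    single-unit classifier.
    """
    total = 0
    for entry in iter_param_layers(spec, include_head=include_head):
        kind = entry[0]
        if kind not in include:
            continue
        if kind == "conv":
            _, cin, cout, k, _ = entry
            total += k * k * cin * cout + cout
        elif kind == "bn":
            total += 4 * entry[1]
        elif kind == "dense":
            total += entry[1] * entry[2] + entry[2]
    return total


def feature_map_side(spec: ArchitectureSpec) -> int:
    """Spatial side length of the final convolutional feature maps."""
    h, w, c = spec.input_shape
    for l in spec.layers:
        if isinstance(l, LayerSpec):
            if l.kind in _KERNELS:
                h, w = _conv_hw(h, w, _KERNELS[l.kind], l.stride[0])
            elif l.kind in ("maxpool2x2", "avgpool2x2"):
                h, w = h // 2, w // 2
            elif l.kind in ("flatten", "global_avg_pool"):
                return h
        elif isinstance(l, ResidualBlockSpec):
            h, w = _conv_hw(h, w, 3, l.stride)
        elif isinstance(l, TransitionSpec):
            h, w = h // 2, w // 2
    return h


class TrainableModel:
    """Uniform wrapper over a built network.

    ``forward`` maps a preprocessed image batch (n, H, W) or (n, 1, H, W)
    to positive-class probabilities in [0, 1].  ``feature_tap`` exposes the
    final convolutional feature maps; when the head is global-average-pool
    followed by the single logistic unit, ``head_weights`` returns the
    classifier weight vector acting on those maps (classic CAM wiring).
    """

    def __init__(self, spec: ArchitectureSpec, layers: list[nn.Layer], tap: int) -> None:
        self.spec = spec
        self.layers = layers
        self.tap = tap  # index of the layer producing the final conv features

    # -- inference ---------------------------------------------------------
    def _as_nchw(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=np.float64)
        if x.ndim == 2:
            x = x[None]
        if x.ndim == 3:
            x = x[:, None]
        return x

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = self._as_nchw(x)
        self._tap_act = None
        for i, l in enumerate(self.layers):
            x = l.forward(x, training)
            if i == self.tap:
                self._tap_act = x
        return x.reshape(-1)

    predict = forward

    def backward(self, dprob: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(probability); returns gradient at input."""
        g = np.asarray(dprob, dtype=np.float64).reshape(-1, 1)
        for l in reversed(self.layers):
            g = l.backward(g)
        return g

    def feature_tap(self, x: np.ndarray) -> np.ndarray:
        self.forward(x, training=False)
        return self._tap_act

    def grad_at_tap(self, x: np.ndarray, target_class: int = 1) -> tuple[np.ndarray, np.ndarray]:
        """(feature maps, gradient of the target-class score at the tap)."""
        self.forward(x, training=False)
        feats = self._tap_act
        sign = 1.0 if target_class == 1 else -1.0
        g = np.full((feats.shape[0] if feats is not None else 1, 1), sign)
        for l in reversed(self.layers[self.tap + 1:]):
            g = l.backward(g)
        return feats, g

    def head_weights(self) -> np.ndarray | None:
        """Classifier weights over feature-map channels, if CAM-compatible."""
        rest = self.layers[self.tap + 1:]
        kinds = [type(l).__name__ for l in rest]
        if kinds == ["GlobalAvgPool", "Dense", "Sigmoid"] and rest[1].n_out == 1:
            return rest[1].w.value[:, 0].copy()
        return None

    # -- parameters --------------------------------------------------------
    def parameters(self) -> list[nn.Param]:
        return [p for l in self.layers for p in l.params()]

    @property
    def parameter_count(self) -> int:
        n = 0
        for l in self.layers:
            n += sum(p.value.size for p in l.params())
            for bn in _batchnorms_of(l):
                n += bn.running_mean.size + bn.running_var.size
        return n

    def get_state(self) -> list[np.ndarray]:
        state = [p.value.copy() for p in self.parameters()]
        for l in self.layers:
            for bn in _batchnorms_of(l):
                state += [bn.running_mean.copy(), bn.running_var.copy()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        for p, v in zip(params, state):
            p.value = v.copy()
        i = len(params)
        for l in self.layers:
            for bn in _batchnorms_of(l):
                bn.running_mean = state[i].copy()
                bn.running_var = state[i + 1].copy()
                i += 2

    def save(self, path) -> None:
        np.savez(path, *self.get_state())

    def load_weights(self, path) -> None:
        with np.load(path) as z:
            self.set_state([z[k] for k in z.files])


def _batchnorms_of(layer: nn.Layer) -> list[nn.BatchNorm2D]:
    out = []
    if isinstance(layer, nn.BatchNorm2D):
        out.append(layer)
    for attr in ("layers", "units"):
        for sub in getattr(layer, attr, []):
            out.extend(_batchnorms_of(sub))
    for attr in ("branch", "pre", "proj", "chain"):
        sub = getattr(layer, attr, None)
        if sub is not None:
            out.extend(_batchnorms_of(sub))
    return out


def build_model(spec: ArchitectureSpec, seed: int = 0) -> TrainableModel:
    """Compile a spec into a runnable model with seeded initialization."""
    rng = np.random.default_rng(seed)
    h, w, c = spec.input_shape
    layers: list[nn.Layer] = []
    for l in spec.layers:
        if isinstance(l, LayerSpec):
            if l.kind in _KERNELS:
                k = _KERNELS[l.kind]
                layers.append(nn.Conv2D(c, l.width, k, l.stride[0], rng))
                c = l.width
                h, w = _conv_hw(h, w, k, l.stride[0])
            elif l.kind == "batch_norm":
                layers.append(nn.BatchNorm2D(c))
            elif l.kind == "activation":
                layers.append(nn.ReLU())
            elif l.kind == "maxpool2x2":
                if h < 2 or w < 2:
                    raise ValueError(f"pooling exhausts spatial size at {h}x{w}")
                layers.append(nn.MaxPool2())
                h, w = h // 2, w // 2
            elif l.kind == "avgpool2x2":
                layers.append(nn.AvgPool2())
                h, w = h // 2, w // 2
            elif l.kind == "global_avg_pool":
                layers.append(nn.GlobalAvgPool())
                h = w = 1
            elif l.kind == "flatten":
                layers.append(nn.Flatten())
                c, h, w = c * h * w, 1, 1
            elif l.kind == "fully_connected":
                layers.append(nn.Dense(c, l.width, rng))
                c, h, w = l.width, 1, 1
        elif isinstance(l, ResidualBlockSpec):
            if l.block_type == "identity_skip":
                if l.width != c:
                    raise ValueError("identity_skip must preserve width")
                layers.append(nn.PreActIdentityBlock(c, rng))
            else:
                layers.append(nn.PreActProjectionBlock(c, l.width, l.stride, rng))
                c = l.width
                h, w = _conv_hw(h, w, 3, l.stride)
        elif isinstance(l, DenseBlockSpec):
            blk = nn.DenseBlock(c, l.n_units, l.growth, rng)
            layers.append(blk)
            c = blk.c_out
        elif isinstance(l, TransitionSpec):
            tr = nn.Transition(c, l.compression, rng)
            layers.append(tr)
            c = tr.c_out
            h, w = h // 2, w // 2
        else:
            raise TypeError(f"unknown spec element {type(l).__name__}")
        if h < 1 or w < 1:
            raise ValueError("spec exhausts the spatial extent before the head")

    # locate the feature tap: last layer whose output is still spatial
    tap = -1
    for i, l in enumerate(layers):
        if isinstance(l, (nn.GlobalAvgPool, nn.Flatten, nn.Dense)):
            break
        tap = i

    # classifier head: single logistic unit; a spec that never flattened or
    # pooled its features gets an implicit flatten first.
    if h != 1 or w != 1:
        layers.append(nn.Flatten())
        c, h, w = c * h * w, 1, 1
    layers.append(nn.Dense(c, 1, rng))
    layers.append(nn.Sigmoid())
    return TrainableModel(spec, layers, tap)
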