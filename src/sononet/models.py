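"""Declarative architecture specs and executable networks.

The family shares one VGG16-derived trunk: 13 convolutions in 2-2-3-3-3
blocks interleaved with 4 max-poolings, every convolution followed by batch
normalisation and ReLU, and an adaptation head of two pointwise convolutions
replacing the fully connected layers, finished by global average pooling and
softmax.  The variants differ only in how each trunk convolution is realised:

* ``2d``    — 1x3x3 kernels on single frames;
* ``3d``    — 3x3x3 kernels on clips;
* ``2p1d``  — each 3x3x3 convolution factorised into a 1x3x3 spatial
  convolution followed by a 3x1x1 temporal convolution, with (optionally
  batch-normalised) ReLU in between; the intermediate width equals the
  output width;
* ``2p1d_star`` — same factorisation, but the intermediate width is chosen
  so the block's parameter count approximates the unfactorised 3D block.

``build_model`` returns both the executable network and the flat
:class:`LayerSpec` list, which the audit module consumes; the two are built
from the same spec so parameter accounting cannot drift from the runtime
weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from ._errors import InvalidConfigError
from .config import ModelConfig

__all__ = [
    "LayerSpec",
    "STBlockSpec",
    "plan_channels",
    "midplanes_star",
    "make_st_block",
    "build_adaptation",
    "build_feature_extractor",
    "build_layer_specs",
    "build_model",
]

#: convolutions per trunk block (VGG16 layout with the last block un-widened)
BLOCK_SIZES = (2, 2, 3, 3, 3)


@dataclass(frozen=True)
class LayerSpec:
    """One layer of an architecture, as data.

    ``kind`` is one of conv/bn/relu/pool/avgpool/softmax.  Kernels, strides
    and paddings are (time, height, width) triplets; non-conv/pool layers
    keep the neutral (1, 1, 1).
    """

    kind: str
    in_channels: int = 0
    out_channels: int = 0
    kernel: tuple[int, int, int] = (1, 1, 1)
    stride: tuple[int, int, int] = (1, 1, 1)
    padding: tuple[int, int, int] = (0, 0, 0)
    has_bias: bool = False

    def __post_init__(self) -> None:
        if min(self.kernel) < 1:
            raise InvalidConfigError(f"kernel entries must be >= 1, got {self.kernel}")
        if self.kind == "conv" and self.has_bias:
            # batch norm supplies the shift everywhere in this family
            raise InvalidConfigError("conv layers in this family are bias-free")

    @property
    def param_count(self) -> int:
        if self.kind == "conv":
            kt, kh, kw = self.kernel
            n = kt * kh * kw * self.in_channels * self.out_channels
            return n + (self.out_channels if self.has_bias else 0)
        if self.kind == "bn":
            return 2 * self.out_channels
        return 0

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "in_channels": self.in_channels,
            "out_channels": self.out_channels,
            "kernel": list(self.kernel),
            "stride": list(self.stride),
            "padding": list(self.padding),
            "has_bias": self.has_bias,
            "params": self.param_count,
        }


def _conv(n_in: int, n_out: int, kernel: tuple[int, int, int]) -> LayerSpec:
    pad = tuple(k // 2 for k in kernel)
    return LayerSpec("conv", n_in, n_out, kernel, (1, 1, 1), pad)  # type: ignore[arg-type]


def _bn(channels: int) -> LayerSpec:
    return LayerSpec("bn", channels, channels)


def _relu() -> LayerSpec:
    return LayerSpec("relu")


def _pool(kernel: tuple[int, int, int]) -> LayerSpec:
    return LayerSpec("pool", kernel=kernel, stride=kernel)


def plan_channels(base_filters: int, in_channels: int = 1) -> list[tuple[int, int]]:
    """The 13 (in, out) channel pairs of the trunk.

    Widths follow the halved-VGG16 plan B, B | 2B, 2B | 4B, 4B, 4B |
    8B, 8B, 8B | 8B, 8B, 8B: the width doubles after each of the first three
    poolings and stays at 8B in the final block.
    """
    if base_filters < 1:
        raise InvalidConfigError("base_filters must be >= 1")
    if in_channels < 1:
        raise InvalidConfigError("in_channels must be >= 1")
    b = base_filters
    widths = [b, b, 2 * b, 2 * b, 4 * b, 4 * b, 4 * b] + [8 * b] * 6
    pairs = []
    prev = in_channels
    for w in widths:
        pairs.append((prev, w))
        prev = w
    return pairs


def midplanes_star(n_in: int, n_out: int, k_t: int = 3, k_h: int = 3, k_w: int = 3) -> int:
    """Intermediate width matching a factorised block's parameters to the
    corresponding full 3D convolution: floor(kt*kh*kw*n_in*n_out /
    (kh*kw*n_in + kt*n_out))."""
    if min(n_in, n_out, k_t, k_h, k_w) < 1:
        raise InvalidConfigError("channel counts and kernel sizes must be >= 1")
    m = (k_t * k_h * k_w * n_in * n_out) // (k_h * k_w * n_in + k_t * n_out)
    return max(m, 1)


@dataclass(frozen=True)
class STBlockSpec:
    """A factorised spatio-temporal convolution block.

    Spatial 1x(kh)x(kw) convolution ``n_in -> mid_channels``, optional batch
    norm, ReLU, then temporal (kt)x1x1 convolution ``mid_channels -> n_out``.
    No convolution biases.
    """

    n_in: int
    n_out: int
    mid_channels: int
    mid_bn: bool = True
    spatial_kernel: tuple[int, int, int] = (1, 3, 3)
    temporal_kernel: tuple[int, int, int] = (3, 1, 1)

    def __post_init__(self) -> None:
        if self.mid_channels < 1:
            raise InvalidConfigError("mid_channels must be >= 1")

    def to_layers(self) -> list[LayerSpec]:
        layers = [_conv(self.n_in, self.mid_channels, self.spatial_kernel)]
        if self.mid_bn:
            layers.append(_bn(self.mid_channels))
        layers.append(_relu())
        layers.append(_conv(self.mid_channels, self.n_out, self.temporal_kernel))
        return layers

    @property
    def param_count(self) -> int:
        return sum(l.param_count for l in self.to_layers())


def make_st_block(
    n_in: int, n_out: int, mid_rule: str = "plain", mid_bn: bool = True
) -> STBlockSpec:
    if min(n_in, n_out) < 1:
        raise InvalidConfigError("channel counts must be >= 1")
    if mid_rule == "plain":
        mid = n_out
    elif mid_rule == "star":
        mid = midplanes_star(n_in, n_out)
    else:
        raise InvalidConfigError(f"unknown mid_rule {mid_rule!r}")
    return STBlockSpec(n_in, n_out, mid, mid_bn=mid_bn)


def build_feature_extractor(config: ModelConfig) -> list[LayerSpec]:
    """The trunk: 13 convolutions (each followed by BN + ReLU) and 4 poolings."""
    pairs = plan_channels(config.base_filters, config.in_channels)
    schedule = config.resolved_pool_schedule()
    conv_kernel = (1, 3, 3) if config.variant == "2d" else (3, 3, 3)
    mid_rule = {"2p1d": "plain", "2p1d_star": "star"}.get(config.variant)

    layers: list[LayerSpec] = []
    i = 0
    for block_idx, block_size in enumerate(BLOCK_SIZES):
        for _ in range(block_size):
            n_in, n_out = pairs[i]
            if mid_rule is None:
                layers.append(_conv(n_in, n_out, conv_kernel))
            else:
                st = make_st_block(n_in, n_out, mid_rule, mid_bn=config.mid_bn)
                layers.extend(st.to_layers())
            layers.append(_bn(n_out))
            layers.append(_relu())
            i += 1
        if block_idx < 4:
            layers.append(_pool(schedule[block_idx]))
    return layers


def build_adaptation(base_filters: int, num_classes: int, dims: int = 2) -> list[LayerSpec]:
    """The head: two pointwise convolutions (8B -> 4B -> C, each with BN),
    global average pooling, softmax.  Pointwise kernels are dimension-free,
    so ``dims`` only documents intent."""
    if base_filters < 1 or num_classes < 1:
        raise InvalidConfigError("base_filters and num_classes must be >= 1")
    if dims not in (2, 3):
        raise InvalidConfigError("dims must be 2 or 3")
    b8, b4 = 8 * base_filters, 4 * base_filters
    one = (1, 1, 1)
    return [
        _conv(b8, b4, one),
        _bn(b4),
        _relu(),
        _conv(b4, num_classes, one),
        _bn(num_classes),
        LayerSpec("avgpool"),
        LayerSpec("softmax"),
    ]


def build_layer_specs(config: ModelConfig) -> list[LayerSpec]:
    dims = 2 if config.variant == "2d" else 3
    return build_feature_extractor(config) + build_adaptation(
        config.base_filters, config.num_classes, dims
    )


def _materialise(spec: LayerSpec, rng: np.random.Generator, pool_idx: int) -> nn.Layer:
    if spec.kind == "conv":
        return nn.Conv3d(spec.in_channels, spec.out_channels, spec.kernel, rng, bias=spec.has_bias)
    if spec.kind == "bn":
        return nn.BatchNorm(spec.out_channels)
    if spec.kind == "relu":
        return nn.ReLU()
    if spec.kind == "pool":
        return nn.MaxPool3d(spec.kernel, name=f"pool{pool_idx}")
    if spec.kind == "avgpool":
        return nn.GlobalAvgPool()
    raise InvalidConfigError(f"unknown layer kind {spec.kind!r}")


def build_model(config: ModelConfig, seed: int = 0) -> tuple[nn.Network, list[LayerSpec]]:
    """Build the executable network and its declarative spec.

    The returned network maps (batch, in_channels, H, W) [2d] or
    (batch, in_channels, N, H, W) [3d / (2+1)d] to (batch, num_classes)
    probabilities.  Weight initialisation is controlled by ``seed``.
    """
    specs = build_layer_specs(config)
    rng = np.random.default_rng(seed)
    layers: list[nn.Layer] = []
    pool_idx = 0
    for spec in specs:
        if spec.kind == "softmax":
            continue  # applied by Network.__call__
        if spec.kind == "pool":
            pool_idx += 1
        layers.append(_materialise(spec, rng, pool_idx))
    return nn.Network(layers, config.num_classes, config.is_spatial_only), specs
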