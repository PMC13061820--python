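"""Parameter and MAC/FLOP accounting for the architecture family.

Two independent routes to the parameter count are kept deliberately separate:
a closed-form sum over the declarative layer specs, and an enumeration of the
built network's trainable tensors.  The FLOP convention is 1 MAC = 2 FLOPs
with pooling, batch norm and activations counted as free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from ._errors import InvalidConfigError, ShapeError
from .config import ModelConfig
from .models import LayerSpec, build_layer_specs, build_model
from .nn import Network

__all__ = [
    "AuditReport",
    "count_params_closed_form",
    "count_params_enumerate",
    "estimate_macs",
    "audit_model",
]

_COUNTED = {"conv", "bn"}
_FREE = {"relu", "pool", "avgpool", "softmax"}


def count_params_closed_form(layers: list[LayerSpec]) -> int:
    """Sum of per-layer parameter counts from the spec list alone."""
    total = 0
    for layer in layers:
        if layer.kind not in _COUNTED and layer.kind not in _FREE:
            raise InvalidConfigError(f"unknown layer kind {layer.kind!r}")
        total += layer.param_count
    return total


def count_params_enumerate(network: Network) -> int:
    """Sum of the sizes of all trainable tensors of a built network."""
    return network.num_params()


def estimate_macs(layers: list[LayerSpec], input_shape: tuple[int, ...]) -> int:
    """Multiply-accumulates for one input of ``input_shape``.

    ``input_shape`` is (channels, T, H, W); a (channels, H, W) shape is
    promoted with T = 1.  Convolutions are stride-1 same-padded, so each
    contributes weight_count x output positions; pooling shrinks the grid by
    floor division.
    """
    if len(input_shape) == 3:
        c, (t, h, w) = input_shape[0], (1, *input_shape[1:])
    elif len(input_shape) == 4:
        c, t, h, w = input_shape
    else:
        raise ShapeError(f"input_shape must be (C, H, W) or (C, T, H, W), got {input_shape}")

    macs = 0
    for layer in layers:
        if layer.kind == "conv":
            if layer.in_channels != c:
                raise ShapeError(
                    f"conv expects {layer.in_channels} channels, input has {c}"
                )
            kt, kh, kw = layer.kernel
            macs += kt * kh * kw * layer.in_channels * layer.out_channels * t * h * w
            c = layer.out_channels
        elif layer.kind == "pool":
            kt, kh, kw = layer.kernel
            t, h, w = t // kt, h // kh, w // kw
            if t == 0 or h == 0 or w == 0:
                raise ShapeError(f"input collapses to zero at pooling kernel {layer.kernel}")
        elif layer.kind == "avgpool":
            t = h = w = 1
        elif layer.kind not in _FREE and layer.kind != "bn":
            raise InvalidConfigError(f"unknown layer kind {layer.kind!r}")
    return macs


@dataclass(frozen=True)
class AuditReport:
    config: ModelConfig
    param_count_closed: int
    param_count_enumerated: int
    macs: int
    input_shape: tuple[int, ...]

    @property
    def gflops(self) -> float:
        return 2.0 * self.macs / 1e9

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "param_count_closed": self.param_count_closed,
            "param_count_enumerated": self.param_count_enumerated,
            "macs": self.macs,
            "gflops": self.gflops,
            "input_shape": list(self.input_shape),
        }

    def to_json(self, path, layers: list[LayerSpec] | None = None) -> None:
        d = self.to_dict()
        if layers is not None:
            d["layers"] = [l.to_dict() for l in layers]
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)


def audit_model(
    config: ModelConfig, input_hw: tuple[int, int] = (64, 64), seed: int = 0
) -> tuple[AuditReport, list[LayerSpec]]:
    """Build, count both ways, and estimate MACs at the stated input size."""
    network, layers = build_model(config, seed=seed)
    t = 1 if config.is_spatial_only else config.clip_len
    shape = (config.in_channels, t, *input_hw)
    report = AuditReport(
        config=config,
        param_count_closed=count_params_closed_form(layers),
        param_count_enumerated=count_params_enumerate(network),
        macs=estimate_macs(layers, shape),
        input_shape=shape,
    )
    return report, layers
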