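"""Model configuration: a small declarative record that fully determines an
architecture in the family (2D, 3D, and the two factorised spatio-temporal
variants)."""

from __future__ import annotations

from dataclasses import dataclass, field

from ._errors import InvalidConfigError

VARIANTS = ("2d", "3d", "2p1d", "2p1d_star")

#: pooling kernels (time, height, width) for the four pooling stages; the
#: first stage keeps the temporal extent so a 10-frame clip survives as
#: 10 -> 5 -> 2 -> 1 under floor division.
DEFAULT_POOL_SCHEDULE = ((1, 2, 2), (2, 2, 2), (2, 2, 2), (2, 2, 2))

POOL_SCHEDULE_2D = ((1, 2, 2), (1, 2, 2), (1, 2, 2), (1, 2, 2))


@dataclass(frozen=True)
class ModelConfig:
    """Everything needed to build (and audit) one network.

    ``clip_len`` is ignored by the 2D variant; ``mid_bn`` only affects the
    factorised (2+1)D variants, where it toggles the batch normalisation
    between the spatial and temporal convolutions.
    """

    variant: str = "2d"
    base_filters: int = 32
    num_classes: int = 7
    in_channels: int = 1
    clip_len: int = 10
    mid_bn: bool = True
    pool_schedule: tuple[tuple[int, int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise InvalidConfigError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if self.base_filters < 1:
            raise InvalidConfigError("base_filters must be >= 1")
        if self.num_classes < 1:
            raise InvalidConfigError("num_classes must be >= 1")
        if self.in_channels < 1:
            raise InvalidConfigError("in_channels must be >= 1")
        if self.variant != "2d" and self.clip_len < 1:
            raise InvalidConfigError("clip_len must be >= 1")
        schedule = self.resolved_pool_schedule()
        if len(schedule) != 4 or any(len(k) != 3 or min(k) < 1 for k in schedule):
            raise InvalidConfigError(
                "pool_schedule must be 4 (time, height, width) kernels with entries >= 1"
            )
        if self.variant != "2d":
            t = self.clip_len
            for stage, (kt, _, _) in enumerate(schedule, start=1):
                t //= kt
                if t < 1:
                    raise InvalidConfigError(
                        f"clip_len={self.clip_len} does not survive pooling stage "
                        f"{stage} (temporal size reaches 0)"
                    )

    def resolved_pool_schedule(self) -> tuple[tuple[int, int, int], ...]:
        if self.pool_schedule is not None:
            return tuple(tuple(k) for k in self.pool_schedule)
        return POOL_SCHEDULE_2D if self.variant == "2d" else DEFAULT_POOL_SCHEDULE

    @property
    def is_spatial_only(self) -> bool:
        return self.variant == "2d"

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "base_filters": self.base_filters,
            "num_classes": self.num_classes,
            "in_channels": self.in_channels,
            "clip_len": self.clip_len,
            "mid_bn": self.mid_bn,
            "pool_schedule": [list(k) for k in self.resolved_pool_schedule()],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "pool_schedule" in d and d["pool_schedule"] is not None:
            d["pool_schedule"] = tuple(tuple(k) for k in d["pool_schedule"])
        return cls(**d)
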