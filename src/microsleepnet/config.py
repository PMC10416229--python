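"""Architectural configuration for the sleep-staging network.

``ModelConfig`` records every structural hyperparameter — channel counts,
group counts, kernel geometry, attention toggles, the fusion-module
dilations and the width multiplier alpha — and resolves them into concrete
per-layer plans shared by the network builder and the analytic
parameter/MAC accounting.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field


@dataclass
class BlockSpec:
    """Resolved plan for one feature-extraction block."""
    index: int                 # 1-based
    in_channels: int
    out_channels: int
    groups: int
    pooled: bool
    ecsa: bool
    shuffle_after: bool


@dataclass
class ConvSpec:
    """Resolved plan for one fusion convolution."""
    in_channels: int
    out_channels: int
    dilation: int
    padding: int


@dataclass
class ModelConfig:
    """Hyperparameters of the network; defaults give the reference model.

    Five blocks of grouped convolution (kernel 3, stride 1, padding 1, no
    bias) + batch norm + leaky ReLU + max pool (first four blocks only) +
    dual channel/spatial attention, with channel shuffles after blocks 2-4;
    then dropout, a three-layer dilated fusion module (channels 32/64/128,
    dilations 1/2/4) and a GAP + linear 5-class head.

    ``width_multiplier_alpha`` scales every convolution channel count; the
    effective group count of each block is reduced to
    ``gcd(groups, in_channels, out_channels)`` so scaled variants remain
    well-formed.
    """

    block_channels: tuple[int, ...] = (64, 128, 128, 128, 128)
    block_groups: tuple[int, ...] = (1, 64, 64, 64, 64)
    conv_kernel: int = 3
    conv_stride: int = 1
    conv_padding: int = 1
    pool_kernel: int = 3
    pool_stride: int = 3
    pool_blocks: tuple[int, ...] = (1, 2, 3, 4)
    shuffle_after: tuple[int, ...] = (2, 3, 4)
    ecsa_enabled: bool | tuple[bool, ...] = True
    eca_gamma: int = 2
    eca_b: int = 1
    spatial_kernel: int = 7
    leaky_slope: float = 0.01
    dropout_rate: float = 0.5
    dconv_channels: tuple[int, ...] = (32, 64, 128)
    dconv_dilations: tuple[int, ...] = (1, 2, 4)
    n_classes: int = 5
    width_multiplier_alpha: float = 1.0
    head: str = "GAP"
    conv_bias: bool = False
    fusion: str = "dilated"
    in_channels: int = 1
    input_length: int = 3000

    # -- validation ----------------------------------------------------
    def validate(self) -> "ModelConfig":
        if len(self.block_channels) != len(self.block_groups):
            raise ValueError(
                "block_channels and block_groups must have equal length "
                f"({len(self.block_channels)} vs {len(self.block_groups)})")
        if len(self.dconv_channels) != len(self.dconv_dilations):
            raise ValueError(
                "dconv_channels and dconv_dilations must have equal length")
        if self.width_multiplier_alpha <= 0:
            raise ValueError("width_multiplier_alpha must be > 0")
        if self.head not in ("GAP", "FC"):
            raise ValueError(f"head must be 'GAP' or 'FC', got {self.head!r}")
        if self.fusion not in ("dilated", "normal"):
            raise ValueError(
                f"fusion must be 'dilated' or 'normal', got {self.fusion!r}")
        if self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be odd")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        bad = [i for i in self.shuffle_after
               if not 1 <= i <= len(self.block_channels)]
        if bad:
            raise ValueError(f"shuffle_after contains invalid block index {bad}")
        flags = self.ecsa_flags()
        if len(flags) != len(self.block_channels):
            raise ValueError("ecsa_enabled must be a bool or one flag per block")
        for spec in self.block_plan():
            if spec.out_channels % spec.groups or spec.in_channels % spec.groups:
                raise ValueError(
                    f"block_groups: block {spec.index} channels "
                    f"{spec.in_channels}->{spec.out_channels} not divisible by "
                    f"groups {spec.groups}")
        return self

    def ecsa_flags(self) -> tuple[bool, ...]:
        if isinstance(self.ecsa_enabled, bool):
            return (self.ecsa_enabled,) * len(self.block_channels)
        return tuple(bool(v) for v in self.ecsa_enabled)

    # -- resolution ----------------------------------------------------
    def _scaled(self, counts) -> list[int]:
        a = self.width_multiplier_alpha
        return [max(1, round(c * a)) for c in counts]

    def block_plan(self) -> list[BlockSpec]:
        channels = self._scaled(self.block_channels)
        flags = self.ecsa_flags()
        specs = []
        in_ch = self.in_channels
        for i, (out_ch, g) in enumerate(zip(channels, self.block_groups), 1):
            g_eff = math.gcd(g, math.gcd(in_ch, out_ch))
            specs.append(BlockSpec(
                index=i, in_channels=in_ch, out_channels=out_ch, groups=g_eff,
                pooled=i in self.pool_blocks,
                ecsa=flags[i - 1],
                shuffle_after=i in self.shuffle_after))
            in_ch = out_ch
        return specs

    def fusion_plan(self) -> list[ConvSpec]:
        in_ch = self._scaled(self.block_channels)[-1]
        specs = []
        for out_ch, d in zip(self._scaled(self.dconv_channels),
                             self.dconv_dilations):
            d_eff = d if self.fusion == "dilated" else 1
            specs.append(ConvSpec(in_channels=in_ch, out_channels=out_ch,
                                  dilation=d_eff, padding=d_eff))
            in_ch = out_ch
        return specs

    def feature_lengths(self) -> list[int]:
        """Temporal length after each block, starting from ``input_length``."""
        length = self.input_length
        out = []
        for spec in self.block_plan():
            # conv: stride/padding preserve length for the default k=3,p=1,s=1
            length = (length + 2 * self.conv_padding
                      - (self.conv_kernel - 1) - 1) // self.conv_stride + 1
            if spec.pooled:
                length = (length - self.pool_kernel) // self.pool_stride + 1
            out.append(length)
        return out

    def head_in_features(self) -> int:
        fusion_out = self.fusion_plan()[-1].out_channels
        if self.head == "GAP":
            return fusion_out
        return fusion_out * self.feature_lengths()[-1]

    # -- (de)serialisation ---------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown ModelConfig keys: {sorted(unknown)}")
        kwargs = {}
        for key, value in data.items():
            if isinstance(value, list):
                value = tuple(value)
            kwargs[key] = value
        return cls(**kwargs).validate()


def ablation_configs() -> dict[str, ModelConfig]:
    """The ablation family: group conv alone, + shuffle, + attention,
    attention with plain (undilated) fusion, and the full model."""
    return {
        "gconv": ModelConfig(ecsa_enabled=False, shuffle_after=()),
        "gconv_shuffle": ModelConfig(ecsa_enabled=False),
        "gconv_shuffle_ecsa": ModelConfig(),
        "gse_normal_conv": ModelConfig(fusion="normal"),
        "full": ModelConfig(),
    }
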