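"""Analytic complexity accounting: per-layer shapes, parameters and MACs.

Parameters follow the closed forms ``k * (C_in / g) * C_out`` for (group)
convolutions plus ``2C`` per batch-norm layer and ``C_in * C_out + C_out``
for the linear head; attention gates add their tiny bias-free convolution
weights.  MACs are ``k * L_out * C_in * C_out / g`` per convolution and
``C_in * C_out`` for the linear head.  FLOPs, where reported, are
``2 * MACs`` under this package's convention; batch norm, pooling and
activations are not counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ModelConfig
from .nn.attention import eca_kernel_size


@dataclass
class LayerSummary:
    name: str
    in_shape: tuple[int, int]   # (channels, length)
    out_shape: tuple[int, int]
    params: int
    macs: int

    def __post_init__(self):
        if self.params < 0 or self.macs < 0:
            raise ValueError("params and macs must be non-negative")


def receptive_field(kernel: int, dilations) -> int:
    """Receptive field of stacked dilated convolutions: 1 + (k-1) * sum(d)."""
    dilations = list(dilations)
    if not dilations:
        raise ValueError("dilations must be non-empty")
    if kernel < 1 or kernel % 2 == 0:
        raise ValueError(f"kernel must be odd and positive, got {kernel}")
    return 1 + (kernel - 1) * sum(int(d) for d in dilations)


def receptive_field_probe(kernel: int = 3, dilations=(1, 2, 4),
                          channels: int = 2, seed: int = 0,
                          n_trials: int = 3) -> int:
    """Measure the receptive field empirically by gradient support.

    Builds the stack of dilated convolutions (with leaky-ReLU
    nonlinearities, as in the fusion module; batch norm is omitted because
    its batch statistics couple every position without changing the conv
    geometry), back-propagates a one-hot gradient from a centre output
    position and counts input positions receiving non-zero gradient.  The
    union over a few random weight draws guards against accidental zeros.
    """
    from . import nn

    length = 2 * receptive_field(kernel, dilations) + 31
    centre = length // 2
    support = np.zeros(length, dtype=bool)
    for trial in range(n_trials):
        rng = np.random.default_rng(seed + trial)
        mods: list[nn.Module] = []
        c = channels
        for d in dilations:
            mods.append(nn.Conv1d(c, channels, kernel, padding=d, dilation=d,
                                  bias=False, rng=rng, dtype=np.float64))
            mods.append(nn.LeakyReLU(0.01))
            c = channels
        x = rng.standard_normal((1, channels, length))
        h = x
        for m in mods:
            h = m(h)
        grad = np.zeros_like(h)
        grad[0, :, centre] = 1.0
        for m in reversed(mods):
            grad = m.backward(grad)
        support |= np.abs(grad).sum(axis=(0, 1)) > 0
    return int(support.sum())


def _conv_macs(k: int, l_out: int, c_in: int, c_out: int, groups: int = 1) -> int:
    return k * l_out * c_in * c_out // groups


def summarize(cfg: ModelConfig | None = None,
              input_length: int | None = None) -> list[LayerSummary]:
    """Per-layer summary mirroring the model's layer table.

    One row per feature block (its conv + BN + attention aggregated), then
    dropout, the fusion convolutions, the pooling head and the linear
    classifier.
    """
    cfg = (cfg or ModelConfig()).validate()
    length = input_length if input_length is not None else cfg.input_length
    rows: list[LayerSummary] = []

    for spec in cfg.block_plan():
        l_in = length
        l_conv = (length + 2 * cfg.conv_padding
                  - (cfg.conv_kernel - 1) - 1) // cfg.conv_stride + 1
        l_out = ((l_conv - cfg.pool_kernel) // cfg.pool_stride + 1
                 if spec.pooled else l_conv)
        params = (cfg.conv_kernel * (spec.in_channels // spec.groups)
                  * spec.out_channels)
        if cfg.conv_bias:
            params += spec.out_channels
        params += 2 * spec.out_channels                      # BN gamma/beta
        macs = _conv_macs(cfg.conv_kernel, l_conv, spec.in_channels,
                          spec.out_channels, spec.groups)
        if spec.ecsa:
            k_eca = eca_kernel_size(spec.out_channels, cfg.eca_gamma, cfg.eca_b)
            params += k_eca + 2 * cfg.spatial_kernel
            macs += k_eca * spec.out_channels                # gate over C
            macs += 2 * cfg.spatial_kernel * l_out           # gate over L
        rows.append(LayerSummary(
            name=f"Block{spec.index}",
            in_shape=(spec.in_channels, l_in),
            out_shape=(spec.out_channels, l_out),
            params=params, macs=macs))
        length = l_out

    last_c = cfg.block_plan()[-1].out_channels
    rows.append(LayerSummary("Dropout", (last_c, length), (last_c, length), 0, 0))

    for i, fs in enumerate(cfg.fusion_plan(), 1):
        params = cfg.conv_kernel * fs.in_channels * fs.out_channels
        if cfg.conv_bias:
            params += fs.out_channels
        params += 2 * fs.out_channels
        macs = _conv_macs(cfg.conv_kernel, length, fs.in_channels,
                          fs.out_channels)
        rows.append(LayerSummary(
            name=f"Dconv{i}", in_shape=(fs.in_channels, length),
            out_shape=(fs.out_channels, length), params=params, macs=macs))
        last_c = fs.out_channels

    if cfg.head == "GAP":
        rows.append(LayerSummary("GAP", (last_c, length), (last_c, 1), 0, 0))
        head_in = last_c
    else:
        rows.append(LayerSummary("Flatten", (last_c, length),
                                 (last_c * length, 1), 0, 0))
        head_in = last_c * length
    rows.append(LayerSummary(
        "Linear", (head_in, 1), (cfg.n_classes, 1),
        params=head_in * cfg.n_classes + cfg.n_classes,
        macs=head_in * cfg.n_classes))
    return rows


def analytic_parameter_count(cfg: ModelConfig | None = None) -> int:
    """Closed-form trainable-parameter total from the layer summary."""
    return sum(row.params for row in summarize(cfg))


def count_parameters(model) -> int:
    """Number of trainable scalars in a built model (BN running statistics
    are buffers, not parameters, and are excluded)."""
    return sum(p.size for p in model.parameters())


def count_macs(model_or_cfg, input_length: int | None = None) -> int:
    """Total multiply-accumulate operations for one forward pass."""
    cfg = getattr(model_or_cfg, "cfg", model_or_cfg)
    return sum(row.macs for row in summarize(cfg, input_length))


def count_flops(model_or_cfg, input_length: int | None = None) -> int:
    """FLOPs under the 2 x MACs convention."""
    return 2 * count_macs(model_or_cfg, input_length)


def format_summary(cfg: ModelConfig | None = None,
                   input_length: int | None = None) -> str:
    """Plain-text layer table with totals."""
    cfg = (cfg or ModelConfig()).validate()
    rows = summarize(cfg, input_length)
    lines = [f"{'Layer':<10} {'Input dim':>14} {'Output dim':>14} "
             f"{'Params':>10} {'MACs':>12}"]
    for r in rows:
        lines.append(f"{r.name:<10} {f'(B, {r.in_shape[0]}, {r.in_shape[1]})':>14} "
                     f"{f'(B, {r.out_shape[0]}, {r.out_shape[1]})':>14} "
                     f"{r.params:>10,} {r.macs:>12,}")
    total_p = sum(r.params for r in rows)
    total_m = sum(r.macs for r in rows)
    lines.append(f"{'Total':<10} {'':>14} {'':>14} {total_p:>10,} {total_m:>12,}")
    lines.append(f"Total parameters: {total_p:,}")
    lines.append(f"Total MACs: {total_m:,} (FLOPs = 2 x MACs = {2 * total_m:,})")
    return "\n".join(lines)
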