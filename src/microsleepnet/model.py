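"""Network assembly: feature blocks, attention, dilated fusion, GAP head.

The model maps a 30-s single-channel EEG epoch (3000 samples at 100 Hz) to
5 sleep-stage logits.  Five grouped-convolution blocks downsample the
signal 3000 -> 1000 -> 333 -> 111 -> 37 -> 37 while widening to 128
channels; channel shuffles after blocks 2-4 restore cross-group mixing; a
three-layer dilated convolution module fuses each position with its 15
neighbours; global average pooling and a small linear layer classify.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .config import ModelConfig
from .nn.attention import eca_kernel_size

STAGE_NAMES = ("W", "N1", "N2", "N3", "REM")


@dataclass
class SignalBatch:
    """A batch of 30-s single-channel epochs, shape (B, 1, 30 * rate)."""

    data: np.ndarray
    sample_rate: float = 100.0

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[1] != 1:
            raise ValueError(
                f"SignalBatch data must be (B, 1, samples), got {self.data.shape}")
        expected = int(round(30 * self.sample_rate))
        if self.data.shape[2] != expected:
            raise ValueError(
                f"epoch must hold {expected} samples at {self.sample_rate} Hz, "
                f"got {self.data.shape[2]}")

    def __len__(self) -> int:
        return self.data.shape[0]


@dataclass
class FeatureMap:
    """An intermediate activation, shape (B, C, L)."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"FeatureMap must be 3-D, got {self.data.shape}")
        if self.data.shape[1] < 1 or self.data.shape[2] < 1:
            raise ValueError("FeatureMap channels and length must be positive")

    @property
    def channels(self) -> int:
        return self.data.shape[1]

    @property
    def length(self) -> int:
        return self.data.shape[2]


class FeatureBlock(nn.Module):
    """Group conv -> BN -> leaky ReLU -> max pool (optional) -> attention."""

    def __init__(self, spec, cfg: ModelConfig, rng: np.random.Generator):
        super().__init__()
        name = f"block{spec.index}"
        self.spec = spec
        self.conv = nn.Conv1d(
            spec.in_channels, spec.out_channels, cfg.conv_kernel,
            stride=cfg.conv_stride, padding=cfg.conv_padding,
            groups=spec.groups, bias=cfg.conv_bias, rng=rng,
            name=f"{name}.conv")
        self.bn = nn.BatchNorm1d(spec.out_channels, name=f"{name}.bn")
        self.act = nn.LeakyReLU(cfg.leaky_slope)
        self.pool = (nn.MaxPool1d(cfg.pool_kernel, cfg.pool_stride)
                     if spec.pooled else None)
        self.eca = (nn.ECA(spec.out_channels, cfg.eca_gamma, cfg.eca_b,
                           rng=rng, name=f"{name}.eca")
                    if spec.ecsa else None)
        self.spatial = (nn.SpatialAttention(cfg.spatial_kernel, rng=rng,
                                            name=f"{name}.spatial")
                        if spec.ecsa else None)

    def _stages(self):
        for m in (self.conv, self.bn, self.act, self.pool, self.eca,
                  self.spatial):
            if m is not None:
                yield m

    def forward(self, x: np.ndarray) -> np.ndarray:
        for m in self._stages():
            x = m(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for m in reversed(list(self._stages())):
            grad = m.backward(grad)
        return grad


class MicroSleepNet(nn.Module):
    """The full single-epoch sleep-staging network."""

    def __init__(self, cfg: ModelConfig | None = None, seed: int = 0):
        super().__init__()
        cfg = (cfg or ModelConfig()).validate()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        steps: list[tuple[str, nn.Module]] = []
        for spec in cfg.block_plan():
            steps.append((f"block{spec.index}", FeatureBlock(spec, cfg, rng)))
            if spec.shuffle_after:
                steps.append((f"shuffle{spec.index}",
                              nn.ChannelShuffle(spec.groups)))
        steps.append(("dropout", nn.Dropout(cfg.dropout_rate,
                                            rng=np.random.default_rng(
                                                rng.integers(2 ** 31)))))
        for i, fs in enumerate(cfg.fusion_plan(), 1):
            steps.append((f"dconv{i}_conv", nn.Conv1d(
                fs.in_channels, fs.out_channels, cfg.conv_kernel,
                stride=1, padding=fs.padding, dilation=fs.dilation,
                bias=cfg.conv_bias, rng=rng, name=f"dconv{i}.conv")))
            steps.append((f"dconv{i}_bn",
                          nn.BatchNorm1d(fs.out_channels, name=f"dconv{i}.bn")))
            steps.append((f"dconv{i}_act", nn.LeakyReLU(cfg.leaky_slope)))
        self.features = nn.Sequential(steps)
        self.head_pool = nn.GlobalAvgPool() if cfg.head == "GAP" else nn.Flatten()
        self.classifier = nn.Linear(cfg.head_in_features(), cfg.n_classes,
                                    bias=True, rng=rng, name="classifier")

    # -- forward/backward ----------------------------------------------
    def forward_features(self, x: np.ndarray) -> np.ndarray:
        """Activation after the fusion module, shape (B, C_fusion, L)."""
        return self.features(x)

    def forward(self, x: np.ndarray) -> np.ndarray:
        fm = self.features(x)
        pooled = self.head_pool(fm)
        return self.classifier(pooled)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        grad = self.classifier.backward(dlogits)
        grad = self.head_pool.backward(grad)
        return self.features.backward(grad)

    # -- inference helpers ----------------------------------------------
    def predict_logits(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        was_training = self.training
        self.eval()
        outs = []
        for start in range(0, x.shape[0], batch_size):
            outs.append(self.forward(x[start:start + batch_size]))
        self.train(was_training)
        return np.concatenate(outs, axis=0)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return nn.softmax(self.predict_logits(x, batch_size))


def build_model(cfg: ModelConfig | None = None, seed: int = 0) -> MicroSleepNet:
    """Instantiate the network from a configuration (default: reference)."""
    return MicroSleepNet(cfg, seed=seed)


# ---------------------------------------------------------------------
# Functional forms of the individual operations (thin wrappers used by
# tests and by external callers that want a single op, not a model).
# ---------------------------------------------------------------------

def _as_array(fm) -> np.ndarray:
    return fm.data if isinstance(fm, FeatureMap) else np.asarray(fm)


def channel_shuffle(fm, groups: int):
    """Reshape-transpose-flatten channel permutation (values untouched)."""
    x = _as_array(fm)
    out = nn.ChannelShuffle(groups).eval()(x)
    return FeatureMap(out) if isinstance(fm, FeatureMap) else out


def channel_attention(fm, conv_weights, gamma: int = 2, b: int = 1):
    """Apply ECA channel gating with explicit gate-convolution weights."""
    x = _as_array(fm)
    module = nn.ECA(x.shape[1], gamma, b).eval()
    w = np.asarray(conv_weights, dtype=module.conv.weight.data.dtype).ravel()
    if w.size != module.kernel_size:
        raise ValueError(
            f"conv_weights must have length {module.kernel_size}, got {w.size}")
    module.conv.weight.data = w.reshape(1, 1, -1)
    out = module(x)
    return FeatureMap(out) if isinstance(fm, FeatureMap) else out


def spatial_attention(fm, conv_weights, kernel_size: int = 7):
    """Apply the temporal-position gate with explicit convolution weights."""
    x = _as_array(fm)
    module = nn.SpatialAttention(kernel_size).eval()
    w = np.asarray(conv_weights, dtype=module.conv.weight.data.dtype)
    if w.size != 2 * kernel_size:
        raise ValueError(
            f"conv_weights must have 2*{kernel_size} entries, got {w.size}")
    module.conv.weight.data = w.reshape(1, 2, kernel_size)
    out = module(x)
    return FeatureMap(out) if isinstance(fm, FeatureMap) else out


def feature_block(fm, cfg: ModelConfig | None = None, block_index: int = 1,
                  seed: int = 0):
    """Run one freshly initialised feature block (shape semantics only)."""
    cfg = (cfg or ModelConfig()).validate()
    x = _as_array(fm)
    specs = cfg.block_plan()
    if not 1 <= block_index <= len(specs):
        raise ValueError(f"block_index must be in 1..{len(specs)}")
    spec = specs[block_index - 1]
    if x.shape[1] != spec.in_channels:
        raise ValueError(
            f"block {block_index} expects {spec.in_channels} channels, "
            f"got {x.shape[1]}")
    block = FeatureBlock(spec, cfg, np.random.default_rng(seed))
    out = block(x)
    return FeatureMap(out) if isinstance(fm, FeatureMap) else out


__all__ = [
    "FeatureBlock",
    "FeatureMap",
    "MicroSleepNet",
    "STAGE_NAMES",
    "SignalBatch",
    "build_model",
    "channel_attention",
    "channel_shuffle",
    "eca_kernel_size",
    "feature_block",
    "spatial_attention",
]
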