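"""Class activation mapping for 30-s EEG epochs.

With a GAP + linear head, the class score is (up to the bias) the temporal
mean of a per-position evidence curve: ``cam_raw[x] = sum_k w_k^C f_k(x)``,
where ``f_k`` is the k-th channel of the post-fusion feature map and
``w^C`` the linear-head weight row of class C.  The curve (length 37 for
the default geometry) is min-max normalised to [0, 1] and linearly
upsampled back to the 3000-sample epoch so it can be overlaid on the raw
signal.  ``localization_score`` quantifies how strongly the map
concentrates on annotated feature-wave intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MicroSleepNet, STAGE_NAMES
from .nn import softmax


@dataclass
class CamResult:
    """Per-epoch class activation curve and posterior probabilities."""

    cam_raw: np.ndarray          # per-position evidence, feature resolution
    cam: np.ndarray              # normalised, upsampled to the epoch length
    predicted_class: int
    target_class: int
    posteriors: np.ndarray       # 5-vector, sums to 1

    def __post_init__(self):
        if not np.all((self.cam >= 0.0) & (self.cam <= 1.0)):
            raise ValueError("cam values must lie in [0, 1]")
        if abs(float(self.posteriors.sum()) - 1.0) > 1e-6:
            raise ValueError("posteriors must sum to 1")

    @property
    def predicted_stage(self) -> str:
        return STAGE_NAMES[self.predicted_class]


def normalize_upsample(cam_raw: np.ndarray, target_len: int = 3000) -> np.ndarray:
    """Min-max normalise to [0, 1] and linearly interpolate to ``target_len``.

    A constant input has zero range and maps to all-zeros (documented
    convention for the degenerate case).
    """
    cam_raw = np.asarray(cam_raw, dtype=np.float64).ravel()
    if cam_raw.size == 0:
        raise ValueError("cam_raw must be non-empty")
    if target_len < cam_raw.size:
        raise ValueError(
            f"target_len ({target_len}) must be >= len(cam_raw) ({cam_raw.size})")
    lo, hi = cam_raw.min(), cam_raw.max()
    if hi - lo == 0:
        norm = np.zeros_like(cam_raw)
    else:
        norm = (cam_raw - lo) / (hi - lo)
    if cam_raw.size == 1:
        return np.full(target_len, norm[0])
    positions = np.linspace(0.0, cam_raw.size - 1.0, target_len)
    return np.interp(positions, np.arange(cam_raw.size), norm)


def compute_cam(model: MicroSleepNet, epoch: np.ndarray,
                target_class: int | str = "predicted") -> CamResult:
    """Class activation map of one epoch.

    ``epoch`` is a single 3000-sample trace (shape (3000,), (1, 3000) or
    (1, 1, 3000)).  ``target_class`` selects the linear-head weight row;
    "predicted" uses the argmax class.  The linear-head bias is excluded,
    as in classical CAM.
    """
    if model.cfg.head != "GAP":
        raise ValueError("CAM requires the GAP head")
    x = np.asarray(epoch)
    x = x.reshape(1, 1, -1).astype(np.float32, copy=False)
    if x.shape[2] != model.cfg.input_length:
        raise ValueError(
            f"epoch must have {model.cfg.input_length} samples, got {x.shape[2]}")
    was_training = model.training
    model.eval()
    fm = model.forward_features(x)              # (1, C, L)
    logits = model.classifier(fm.mean(axis=2))
    model.train(was_training)
    posteriors = softmax(logits)[0]
    predicted = int(np.argmax(posteriors))
    if target_class == "predicted":
        cls = predicted
    else:
        cls = int(target_class)
        if not 0 <= cls < model.cfg.n_classes:
            raise ValueError(
                f"target_class must be in 0..{model.cfg.n_classes - 1}, got {cls}")
    weights = model.classifier.weight.data[cls]          # (C,)
    cam_raw = weights @ fm[0]                            # (L,)
    cam = normalize_upsample(cam_raw, model.cfg.input_length)
    return CamResult(cam_raw=np.asarray(cam_raw, dtype=np.float64), cam=cam,
                     predicted_class=predicted, target_class=cls,
                     posteriors=np.asarray(posteriors, dtype=np.float64))


def localization_score(cam: np.ndarray, event_intervals) -> float:
    """Mean CAM inside annotated intervals minus mean outside.

    Positive scores mean the map concentrates on the annotated feature
    waves.  Intervals are half-open sample ranges ``[start, end)`` within
    the epoch.
    """
    cam = np.asarray(cam, dtype=np.float64).ravel()
    intervals = list(event_intervals)
    if not intervals:
        raise ValueError("event_intervals must be non-empty")
    inside = np.zeros(cam.size, dtype=bool)
    for start, end in intervals:
        start, end = int(start), int(end)
        if not 0 <= start < end <= cam.size:
            raise ValueError(f"interval ({start}, {end}) outside [0, {cam.size})")
        inside[start:end] = True
    if inside.all():
        raise ValueError("intervals cover the whole epoch; no outside samples")
    return float(cam[inside].mean() - cam[~inside].mean())
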