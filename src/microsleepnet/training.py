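"""Training protocol, subject-wise cross-validation and staging metrics.

Training follows the fixed recipe: Adam (lr 1e-3, betas 0.9/0.999), L2
regularisation 1e-3 on convolution/linear weights, batch size 200, at most
100 epochs with early stopping once the validation loss has not improved
for 10 consecutive epochs; the returned weights are those of the best
validation epoch.  Cross-validation is subject-wise (held-out subjects
never appear in training), with a stratified 9:1 epoch-level train/val
split inside each fold.  Metrics are overall accuracy (percent), one-vs-
rest per-class F1, macro-F1 and Cohen's kappa, all computed from the 5x5
confusion matrix.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import ModelConfig
from .data_io import EPOCH_SAMPLES, EpochDataset, SubjectRecord
from .model import MicroSleepNet, build_model
from .nn import Adam, softmax, weighted_cross_entropy

logger = logging.getLogger(__name__)


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during optimisation."""


@dataclass
class TrainConfig:
    batch_size: int = 200
    learning_rate: float = 1e-3
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    weight_decay: float = 1e-3
    max_epochs: int = 100
    early_stop_patience: int = 10
    class_weights: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    seed: int = 0

    def validate(self) -> "TrainConfig":
        for name in ("batch_size", "learning_rate", "max_epochs",
                     "early_stop_patience"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.early_stop_patience > self.max_epochs:
            raise ValueError("early_stop_patience must be <= max_epochs")
        if len(self.class_weights) != 5:
            raise ValueError("class_weights must have length 5")
        return self


@dataclass
class ConfusionMatrix:
    """5x5 counts; rows are expert labels, columns model predictions."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (5, 5) or np.any(self.counts < 0):
            raise ValueError("counts must be a non-negative 5x5 array")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_labels(cls, y_true, y_pred, n_classes: int = 5) -> "ConfusionMatrix":
        y_true = np.asarray(y_true, dtype=np.int64)
        y_pred = np.asarray(y_pred, dtype=np.int64)
        counts = np.bincount(n_classes * y_true + y_pred,
                             minlength=n_classes * n_classes)
        return cls(counts.reshape(n_classes, n_classes))


@dataclass
class MetricsReport:
    accuracy: float                # percent
    per_class_f1: np.ndarray       # length 5, in [0, 1]
    macro_f1: float
    kappa: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class_f1": [float(v) for v in self.per_class_f1],
            "macro_f1": self.macro_f1,
            "kappa": self.kappa,
        }


def accuracy_from_confusion(cm: np.ndarray) -> float:
    """Overall agreement x 100."""
    cm = np.asarray(cm, dtype=np.float64)
    return float(np.trace(cm) / cm.sum() * 100.0)


def f1_from_confusion(cm: np.ndarray) -> np.ndarray:
    """One-vs-rest F1 per class; 0 (with a warning) when undefined."""
    cm = np.asarray(cm, dtype=np.float64)
    n = cm.shape[0]
    f1 = np.zeros(n)
    for c in range(n):
        tp = cm[c, c]
        fp = cm[:, c].sum() - tp
        fn = cm[c, :].sum() - tp
        denom = 2 * tp + fp + fn
        if denom == 0:
            warnings.warn(f"class {c} absent from truth and prediction; "
                          "F1 defined as 0", RuntimeWarning, stacklevel=2)
            f1[c] = 0.0
        else:
            f1[c] = 2 * tp / denom
    return f1


def kappa_from_confusion(cm: np.ndarray) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e) from the confusion marginals."""
    cm = np.asarray(cm, dtype=np.float64)
    total = cm.sum()
    p_o = np.trace(cm) / total
    p_e = float((cm.sum(axis=1) * cm.sum(axis=0)).sum()) / total ** 2
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def metrics_from_confusion(cm: ConfusionMatrix | np.ndarray) -> MetricsReport:
    counts = cm.counts if isinstance(cm, ConfusionMatrix) else np.asarray(cm)
    f1 = f1_from_confusion(counts)
    return MetricsReport(accuracy=accuracy_from_confusion(counts),
                         per_class_f1=f1,
                         macro_f1=float(f1.mean()),
                         kappa=kappa_from_confusion(counts))


# ---------------------------------------------------------------------
# cross-validation structure
# ---------------------------------------------------------------------

def subject_kfold(subject_ids, k: int) -> list[tuple[list, list]]:
    """Partition subjects into k test folds (k = n gives leave-one-out).

    Subjects are taken in order of first appearance; fold sizes differ by
    at most one.  Returns ``(train_subjects, test_subjects)`` pairs.
    """
    ids = list(dict.fromkeys(subject_ids))   # unique, order-preserving
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the number of subjects ({len(ids)})")
    if k < 1:
        raise ValueError("k must be >= 1")
    folds = [list(chunk) for chunk in np.array_split(np.array(ids, dtype=object), k)]
    splits = []
    for test in folds:
        test_set = set(test)
        train = [s for s in ids if s not in test_set]
        splits.append((train, list(test)))
    return splits


def stratified_train_val_split(dataset: EpochDataset, val_fraction: float = 0.1,
                               rng: np.random.Generator | None = None
                               ) -> tuple[EpochDataset, EpochDataset]:
    """Epoch-level stratified split (default 9:1) after shuffling.

    Per class the validation share is ``round(val_fraction * n)`` with at
    least one epoch; classes with fewer than 10 epochs trigger a warning
    and best-effort allocation.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    labels = dataset.labels
    val_idx: list[np.ndarray] = []
    train_idx: list[np.ndarray] = []
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        if idx.size < 10:
            warnings.warn(f"class {c} has only {idx.size} epochs; "
                          "best-effort validation allocation", RuntimeWarning,
                          stacklevel=2)
        idx = rng.permutation(idx)
        n_val = max(1, round(val_fraction * idx.size))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    val = np.sort(np.concatenate(val_idx))
    train = np.sort(np.concatenate(train_idx))
    return dataset.subset(train), dataset.subset(val)


# ---------------------------------------------------------------------
# training
# ---------------------------------------------------------------------

class EarlyStopper:
    """Stop when the monitored loss has not improved for ``patience``
    consecutive epochs; remembers the best epoch."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best_loss = np.inf
        self.best_epoch = -1
        self.bad_epochs = 0

    def update(self, epoch: int, loss: float) -> bool:
        """Record this epoch's loss; returns True when training should stop."""
        if loss < self.best_loss:
            self.best_loss = loss
            self.best_epoch = epoch
            self.bad_epochs = 0
            return False
        self.bad_epochs += 1
        return self.bad_epochs >= self.patience


def _dataset_loss(model: MicroSleepNet, ds: EpochDataset,
                  class_weights, batch_size: int) -> tuple[float, float]:
    """(mean loss, accuracy fraction) in inference mode."""
    model.eval()
    losses = []
    weights = []
    correct = 0
    for start in range(0, len(ds), batch_size):
        xb = ds.epochs[start:start + batch_size]
        yb = ds.labels[start:start + batch_size]
        logits = model.forward(xb)
        loss, _ = weighted_cross_entropy(logits, yb, class_weights)
        losses.append(loss)
        weights.append(len(yb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    model.train()
    mean_loss = float(np.average(losses, weights=weights))
    return mean_loss, correct / len(ds)


def train(model: MicroSleepNet, train_ds: EpochDataset, val_ds: EpochDataset,
          cfg: TrainConfig | None = None
          ) -> tuple[MicroSleepNet, dict]:
    """Fit the model in place; returns it with best-validation weights.

    The history dict records per-epoch train/val loss and val accuracy,
    plus the stopping and best epochs.
    """
    cfg = (cfg or TrainConfig()).validate()
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("train and validation sets must be non-empty")
    rng = np.random.default_rng(cfg.seed)
    cw = np.asarray(cfg.class_weights, dtype=np.float64)
    optimiser = Adam(model.parameters(), lr=cfg.learning_rate,
                     beta1=cfg.adam_beta1, beta2=cfg.adam_beta2,
                     weight_decay=cfg.weight_decay)
    stopper = EarlyStopper(cfg.early_stop_patience)
    history = {"train_loss": [], "val_loss": [], "val_accuracy": []}
    best_state = model.get_state()
    model.train()
    n = len(train_ds)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = train_ds.epochs[idx]
            yb = train_ds.labels[idx]
            logits = model.forward(xb)
            loss, dlogits = weighted_cross_entropy(logits, yb, cw)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch} "
                    f"(lr={cfg.learning_rate}, batch mean={xb.mean():.3g}, "
                    f"batch std={xb.std():.3g})")
            model.zero_grad()
            model.backward(dlogits)
            optimiser.step()
            epoch_losses.append(loss)
        val_loss, val_acc = _dataset_loss(model, val_ds, cw, cfg.batch_size)
        history["train_loss"].append(float(np.mean(epoch_losses)))
        history["val_loss"].append(val_loss)
        history["val_accuracy"].append(val_acc)
        improved = val_loss < stopper.best_loss
        stop = stopper.update(epoch, val_loss)
        if improved:
            best_state = model.get_state()
        logger.info("epoch %d: train %.4f val %.4f acc %.3f", epoch,
                    history["train_loss"][-1], val_loss, val_acc)
        if stop:
            break
    history["best_epoch"] = stopper.best_epoch
    history["stopped_epoch"] = len(history["val_loss"]) - 1
    model.set_state(best_state)
    model.eval()
    return model, history


def evaluate(model: MicroSleepNet, test_ds: EpochDataset,
             batch_size: int = 256) -> tuple[MetricsReport, ConfusionMatrix]:
    """Score a test set: metrics report plus confusion matrix."""
    if len(test_ds) == 0:
        raise ValueError("test set must be non-empty")
    logits = model.predict_logits(test_ds.epochs, batch_size)
    preds = logits.argmax(axis=1)
    cm = ConfusionMatrix.from_labels(test_ds.labels, preds)
    return metrics_from_confusion(cm), cm


def predict_hypnogram(model: MicroSleepNet, record: SubjectRecord,
                      batch_size: int = 256
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch stage predictions and 5-class posteriors for a record.

    Every full 30-s window of the signal is scored, with no temporal
    smoothing (the model is strictly one-epoch-to-one-label).
    """
    n = len(record.signal) // EPOCH_SAMPLES
    epochs = (record.signal[:n * EPOCH_SAMPLES]
              .reshape(n, 1, EPOCH_SAMPLES).astype(np.float32))
    posteriors = model.predict_proba(epochs, batch_size)
    return posteriors.argmax(axis=1), posteriors


# ---------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------

def save_checkpoint(model: MicroSleepNet, path) -> None:
    """Single-file checkpoint: architecture config + weights/buffers."""
    path = Path(path)
    arrays = {f"array_{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, config=json.dumps(model.cfg.to_dict()), **arrays)


def load_checkpoint(path) -> MicroSleepNet:
    with np.load(Path(path), allow_pickle=False) as data:
        cfg = ModelConfig.from_dict(json.loads(str(data["config"])))
        model = build_model(cfg)
        n = len([k for k in data.files if k.startswith("array_")])
        model.set_state([data[f"array_{i}"] for i in range(n)])
    model.eval()
    return model
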