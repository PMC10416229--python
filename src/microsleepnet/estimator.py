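"""scikit-learn style estimator wrapping the network and training recipe.

``MicroSleepNetClassifier`` accepts epochs as ``(n, 3000)`` or
``(n, 1, 3000)`` arrays of single-channel EEG (100 Hz, 30 s) and AASM
labels in {0..4}; it composes with sklearn model selection and pipelines.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .config import ModelConfig
from .data_io import EPOCH_SAMPLES, EpochDataset
from .model import build_model
from .training import TrainConfig, evaluate, stratified_train_val_split, train


class MicroSleepNetClassifier(ClassifierMixin, BaseEstimator):
    """Single-epoch sleep-stage classifier.

    Parameters mirror the architecture and training configurations; a
    stratified ``val_fraction`` share of the training epochs is held out
    internally for early stopping.

    Attributes set by :meth:`fit`: ``network_`` (the trained network),
    ``history_`` (per-epoch losses), ``classes_``, ``n_features_in_``.
    """

    def __init__(self, model_config: ModelConfig | None = None,
                 batch_size: int = 200, learning_rate: float = 1e-3,
                 adam_beta1: float = 0.9, adam_beta2: float = 0.999,
                 weight_decay: float = 1e-3, max_epochs: int = 100,
                 early_stop_patience: int = 10,
                 class_weights: tuple | None = None,
                 val_fraction: float = 0.1, random_state: int = 0):
        self.model_config = model_config
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.adam_beta1 = adam_beta1
        self.adam_beta2 = adam_beta2
        self.weight_decay = weight_decay
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.class_weights = class_weights
        self.val_fraction = val_fraction
        self.random_state = random_state

    # -- helpers --------------------------------------------------------
    def _as_epochs(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        if X.ndim == 2:
            X = X[:, None, :]
        if X.ndim != 3 or X.shape[1] != 1 or X.shape[2] != EPOCH_SAMPLES:
            raise ValueError(
                f"X must be (n, {EPOCH_SAMPLES}) or (n, 1, {EPOCH_SAMPLES}); "
                f"got {X.shape}")
        return X

    def _train_config(self) -> TrainConfig:
        cw = (tuple(self.class_weights) if self.class_weights is not None
              else (1.0,) * 5)
        return TrainConfig(
            batch_size=self.batch_size, learning_rate=self.learning_rate,
            adam_beta1=self.adam_beta1, adam_beta2=self.adam_beta2,
            weight_decay=self.weight_decay, max_epochs=self.max_epochs,
            early_stop_patience=self.early_stop_patience,
            class_weights=cw, seed=self.random_state)

    # -- sklearn API ----------------------------------------------------
    def fit(self, X, y) -> "MicroSleepNetClassifier":
        X = self._as_epochs(X)
        y = np.asarray(y, dtype=np.int64)
        if len(X) != len(y):
            raise ValueError("X and y must be equally long")
        self.classes_ = np.unique(y)
        self.n_features_in_ = X.shape[2]
        ds = EpochDataset(X, y, np.zeros(len(y), dtype=object))
        rng = np.random.default_rng(self.random_state)
        train_ds, val_ds = stratified_train_val_split(ds, self.val_fraction, rng)
        cfg = self.model_config or ModelConfig()
        network = build_model(cfg, seed=self.random_state)
        network, history = train(network, train_ds, val_ds, self._train_config())
        self.network_ = network
        self.history_ = history
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        return self.network_.predict_proba(self._as_epochs(X))

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def evaluate(self, X, y):
        """Full staging metrics (accuracy %, per-class F1, MF1, kappa)."""
        check_is_fitted(self, "network_")
        ds = EpochDataset(self._as_epochs(X), np.asarray(y, dtype=np.int64),
                          np.zeros(len(y), dtype=object))
        return evaluate(self.network_, ds)
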