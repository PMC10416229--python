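"""Cross-validation structure, metrics vs independent oracles, training
mechanics (early stopping, class weighting)."""

import numpy as np
import pytest

from microsleepnet import (
    ConfusionMatrix,
    EpochDataset,
    ModelConfig,
    TrainConfig,
    build_model,
    gen_dataset,
    gen_subject,
    metrics_from_confusion,
    predict_hypnogram,
    stratified_train_val_split,
    subject_kfold,
    train,
)
from microsleepnet.nn import weighted_cross_entropy
from microsleepnet.training import (
    EarlyStopper,
    accuracy_from_confusion,
    f1_from_confusion,
    kappa_from_confusion,
)


# ---------------------------------------------------------------------
# subject-wise folds
# ---------------------------------------------------------------------

def test_twenty_subjects_k20_is_leave_one_subject_out():
    ids = [f"s{i}" for i in range(20)]
    folds = subject_kfold(ids, 20)
    assert len(folds) == 20
    assert all(len(test) == 1 for _, test in folds)
    assert sorted(t for _, test in folds for t in test) == sorted(ids)


def test_every_subject_in_exactly_one_test_fold():
    ids = [f"s{i}" for i in range(13)]
    folds = subject_kfold(ids, 4)
    seen = [t for _, test in folds for t in test]
    assert sorted(seen) == sorted(ids)
    for train_subjects, test_subjects in folds:
        assert not set(train_subjects) & set(test_subjects)
        assert sorted(train_subjects + test_subjects) == sorted(ids)


def test_fold_sizes_balanced_within_one():
    folds = subject_kfold([f"s{i}" for i in range(78)], 10)
    sizes = [len(test) for _, test in folds]
    assert max(sizes) - min(sizes) <= 1
    assert sum(sizes) == 78


def test_k_larger_than_subjects_rejected():
    with pytest.raises(ValueError, match="exceeds"):
        subject_kfold(["a", "b"], 3)


# ---------------------------------------------------------------------
# stratified split
# ---------------------------------------------------------------------

def _dataset(labels):
    labels = np.asarray(labels, dtype=np.int64)
    return EpochDataset(np.zeros((len(labels), 1, 3000), dtype=np.float32),
                        labels, np.zeros(len(labels), dtype=object))


def test_stratified_split_exact_arithmetic(rng):
    ds = _dataset(np.repeat(np.arange(5), 200))
    train_ds, val_ds = stratified_train_val_split(ds, 0.1, rng)
    np.testing.assert_array_equal(val_ds.class_counts(), [20] * 5)
    np.testing.assert_array_equal(train_ds.class_counts(), [180] * 5)


def test_stratified_split_reproducible_and_disjoint():
    ds = _dataset(np.repeat(np.arange(5), 50))
    # mark each epoch so indices can be recovered after the split
    ds.epochs[:, 0, 0] = np.arange(len(ds))
    t1, v1 = stratified_train_val_split(ds, 0.1, np.random.default_rng(4))
    t2, v2 = stratified_train_val_split(ds, 0.1, np.random.default_rng(4))
    np.testing.assert_array_equal(v1.epochs[:, 0, 0], v2.epochs[:, 0, 0])
    ids = np.concatenate([t1.epochs[:, 0, 0], v1.epochs[:, 0, 0]])
    np.testing.assert_array_equal(np.sort(ids), np.arange(len(ds)))


def test_stratified_split_warns_on_sparse_class(rng):
    ds = _dataset([0] * 50 + [1] * 5)
    with pytest.warns(RuntimeWarning, match="best-effort"):
        _, val_ds = stratified_train_val_split(ds, 0.1, rng)
    assert (val_ds.labels == 1).sum() >= 1


# ---------------------------------------------------------------------
# metrics vs independent oracles
# ---------------------------------------------------------------------

def _labels_from_confusion(cm):
    y_true, y_pred = [], []
    for i in range(cm.shape[0]):
        for j in range(cm.shape[1]):
            y_true += [i] * cm[i, j]
            y_pred += [j] * cm[i, j]
    return np.array(y_true), np.array(y_pred)


def test_metrics_match_sklearn_on_random_confusions():
    """1,000 random confusion matrices: accuracy, per-class F1, MF1 and
    kappa agree with sklearn computed from expanded label vectors to
    1e-12."""
    from sklearn.metrics import accuracy_score, cohen_kappa_score, f1_score

    rng = np.random.default_rng(0)
    for _ in range(1000):
        cm = rng.integers(0, 30, size=(5, 5))
        cm[rng.integers(5), rng.integers(5)] += 1   # never all-zero
        y_true, y_pred = _labels_from_confusion(cm)
        report = metrics_from_confusion(ConfusionMatrix(cm))
        assert abs(report.accuracy
                   - 100 * accuracy_score(y_true, y_pred)) < 1e-12
        skl_f1 = f1_score(y_true, y_pred, labels=range(5), average=None,
                          zero_division=0)
        np.testing.assert_allclose(report.per_class_f1, skl_f1, atol=1e-12)
        assert abs(report.macro_f1 - skl_f1.mean()) < 1e-12
        assert abs(report.kappa
                   - cohen_kappa_score(y_true, y_pred)) < 1e-12


def test_perfect_predictions():
    cm = np.diag([10, 20, 30, 40, 50])
    report = metrics_from_confusion(ConfusionMatrix(cm))
    assert report.accuracy == 100.0
    np.testing.assert_array_equal(report.per_class_f1, np.ones(5))
    assert report.kappa == 1.0


def test_kappa_hand_computed_two_class_example():
    """counts ((45, 5), (15, 35)): p_o = 0.8, p_e = 0.5, kappa = 0.6."""
    cm = np.array([[45, 5], [15, 35]])
    assert accuracy_from_confusion(cm) == pytest.approx(80.0)
    assert kappa_from_confusion(cm) == pytest.approx(0.6)


def test_kappa_near_zero_for_independent_predictions():
    """Permutation oracle: predictions shuffled independently of truth
    give |kappa| < 0.02 at n = 10,000."""
    rng = np.random.default_rng(1)
    y_true = rng.integers(0, 5, 10000)
    y_pred = rng.permutation(y_true)
    cm = ConfusionMatrix.from_labels(y_true, y_pred)
    assert abs(kappa_from_confusion(cm.counts)) < 0.02


def test_macro_f1_invariant_under_class_relabelling(rng):
    cm = rng.integers(0, 40, size=(5, 5))
    perm = rng.permutation(5)
    permuted = cm[np.ix_(perm, perm)]
    r1 = metrics_from_confusion(ConfusionMatrix(cm))
    r2 = metrics_from_confusion(ConfusionMatrix(permuted))
    assert r1.macro_f1 == pytest.approx(r2.macro_f1, abs=1e-12)
    np.testing.assert_allclose(np.sort(r1.per_class_f1),
                               np.sort(r2.per_class_f1), atol=1e-12)


def test_absent_class_f1_is_zero_with_warning():
    cm = np.zeros((5, 5), dtype=int)
    cm[0, 0] = 10
    with pytest.warns(RuntimeWarning, match="absent"):
        f1 = f1_from_confusion(cm)
    assert f1[1] == 0.0


# ---------------------------------------------------------------------
# training mechanics
# ---------------------------------------------------------------------

def test_early_stopper_halts_after_patience_and_keeps_best():
    """Validation losses worsening for 10 consecutive epochs after epoch 3
    halt training at epoch 13 with epoch-3 weights retained."""
    stopper = EarlyStopper(patience=10)
    losses = [1.0, 0.8, 0.6, 0.5] + [0.5 + 0.01 * i for i in range(1, 11)]
    stopped_at = None
    for epoch, loss in enumerate(losses):
        if stopper.update(epoch, loss):
            stopped_at = epoch
            break
    assert stopped_at == 13
    assert stopper.best_epoch == 3
    assert stopper.best_loss == 0.5


def test_class_weight_two_doubles_gradient_contribution(rng):
    """With weights (1, 2, 1, 1, 1) an N1 sample contributes exactly twice
    the logit gradient of an otherwise identical W sample."""
    logits = np.vstack([rng.standard_normal(5)] * 2)
    y = np.array([0, 1])                    # W and N1, identical logits
    _, grad = weighted_cross_entropy(logits, y, np.array([1, 2, 1, 1, 1.0]))
    p = np.exp(logits[0] - logits[0].max())
    p /= p.sum()
    g0 = p.copy()
    g0[0] -= 1
    g1 = p.copy()
    g1[1] -= 1
    # each raw per-sample gradient g_i is scaled by w_i / sum(w): the N1
    # sample's contribution is exactly twice the W sample's
    np.testing.assert_allclose(grad[0], g0 * (1 / 3), rtol=1e-6)
    np.testing.assert_allclose(grad[1], g1 * (2 / 3), rtol=1e-6)


def test_train_config_validation():
    with pytest.raises(ValueError, match="patience"):
        TrainConfig(max_epochs=5, early_stop_patience=10).validate()
    with pytest.raises(ValueError, match="class_weights"):
        TrainConfig(class_weights=(1.0, 1.0)).validate()


@pytest.fixture(scope="module")
def tiny_trained():
    """A narrow model trained briefly on a small synthetic set."""
    rng = np.random.default_rng(0)
    train_ds, _ = gen_dataset(150, rng=rng)
    val_ds, _ = gen_dataset(50, rng=rng)
    model = build_model(ModelConfig(width_multiplier_alpha=0.25), seed=0)
    cfg = TrainConfig(batch_size=50, max_epochs=3, early_stop_patience=3,
                      seed=0)
    model, history = train(model, train_ds, val_ds, cfg)
    return model, history


def test_training_returns_best_epoch_weights(tiny_trained):
    _, history = tiny_trained
    best = history["best_epoch"]
    assert history["val_loss"][best] == min(history["val_loss"])
    assert len(history["train_loss"]) == len(history["val_loss"])


def test_predict_hypnogram_contract(tiny_trained):
    model, _ = tiny_trained
    record = gen_subject(6, rng=np.random.default_rng(8))
    stages, posteriors = predict_hypnogram(model, record)
    assert stages.shape == (6,) and posteriors.shape == (6, 5)
    np.testing.assert_allclose(posteriors.sum(axis=1), 1.0, atol=1e-6)
    np.testing.assert_array_equal(stages, posteriors.argmax(axis=1))
    stages2, posteriors2 = predict_hypnogram(model, record)
    np.testing.assert_array_equal(posteriors, posteriors2)
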