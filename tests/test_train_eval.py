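import numpy as np
import pytest

from pcgnet.cnn_model import ModelConfig, build_model
from pcgnet.errors import TrainingError, ValidationError
from pcgnet.segment_augment import LabeledDataset, Segment
from pcgnet.train_eval import (
    ConfusionMatrix,
    TrainConfig,
    compute_metrics,
    confusion,
    cross_entropy,
    evaluate,
    roc_auc,
    train,
)

TINY_MODEL = ModelConfig(
    input_len=32,
    conv_filters=(4, 4),
    kernel_size=3,
    pool_size=2,
    conv_dropout=0.0,
    dense_units=8,
    dense_dropout=0.0,
    seed=5,
)


def _toy_dataset(n_per_class=4, length=32, fs=2000.0, seed=0, shift=3.0):
    """Trivially separable: abnormal segments sit at +shift offset."""
    rng = np.random.default_rng(seed)
    segs = []
    for i in range(n_per_class):
        segs.append(Segment(samples=rng.standard_normal(length), fs=fs,
                            label="normal", source_id=f"n{i}"))
        segs.append(Segment(samples=rng.standard_normal(length) + shift, fs=fs,
                            label="abnormal", source_id=f"a{i}"))
    return LabeledDataset(segs)


class TestCrossEntropy:
    def test_perfect_prediction_near_zero(self):
        assert cross_entropy([1], [1.0 - 1e-7]) < 1e-6

    def test_coin_flip_is_ln2(self):
        assert cross_entropy([1], [0.5]) == pytest.approx(np.log(2), rel=1e-9)

    def test_two_sample_batch_closed_form(self):
        got = cross_entropy([1, 0], [0.9, 0.2])
        assert got == pytest.approx((-np.log(0.9) - np.log(0.8)) / 2, rel=1e-9)

    def test_accepts_one_hot_and_two_column_probs(self):
        y_onehot = np.array([[0, 1], [1, 0]])
        p_two = np.array([[0.1, 0.9], [0.8, 0.2]])
        assert cross_entropy(y_onehot, p_two) == pytest.approx(
            cross_entropy([1, 0], [0.9, 0.2]), rel=1e-12
        )

    def test_extreme_probabilities_clipped(self):
        assert np.isfinite(cross_entropy([1, 0], [0.0, 1.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            cross_entropy([1, 0], [0.5])


class TestTrain:
    def test_zero_learning_rate_leaves_parameters_unchanged(self):
        ds = _toy_dataset()
        model = build_model(TINY_MODEL)
        before = {f"{i}.{n}": p.copy() for i, n, p in model.net.parameters()}
        train(model, ds, ds, TrainConfig(learning_rate=0.0, epochs=3, seed=0))
        for i, n, p in model.net.parameters():
            np.testing.assert_array_equal(before[f"{i}.{n}"], p)

    def test_overfits_separable_toy_set(self):
        ds = _toy_dataset(n_per_class=1)
        model = build_model(TINY_MODEL)
        model = train(model, ds, ds, TrainConfig(learning_rate=1e-2, epochs=200,
                                                 batch_size=2, seed=0))
        assert model.training_history[-1]["train_loss"] < 0.05

    def test_identical_seeds_identical_history(self):
        ds = _toy_dataset()
        cfg = TrainConfig(epochs=3, seed=7)
        h1 = train(build_model(TINY_MODEL), ds, ds, cfg).training_history
        h2 = train(build_model(TINY_MODEL), ds, ds, cfg).training_history
        assert h1 == h2

    def test_history_records_every_epoch(self):
        ds = _toy_dataset()
        model = train(build_model(TINY_MODEL), ds, ds, TrainConfig(epochs=4, seed=0))
        assert [h["epoch"] for h in model.training_history] == [0, 1, 2, 3]
        for h in model.training_history:
            assert set(h) == {"epoch", "train_loss", "train_acc", "val_loss", "val_acc"}

    def test_nan_weights_raise_training_error(self):
        ds = _toy_dataset()
        model = build_model(TINY_MODEL)
        model.net.layers[0].params["W"][:] = np.nan
        with pytest.raises(TrainingError, match="epoch 0"):
            train(model, ds, ds, TrainConfig(epochs=1, seed=0))

    def test_early_stopping_restores_best_epoch(self):
        ds = _toy_dataset()
        model = train(
            build_model(TINY_MODEL), ds, ds,
            TrainConfig(epochs=30, seed=0, early_stop_patience=3),
        )
        assert len(model.training_history) <= 30

    def test_empty_sets_rejected(self):
        ds = _toy_dataset()
        with pytest.raises(ValidationError):
            train(build_model(TINY_MODEL), LabeledDataset([]), ds, TrainConfig(epochs=1))


class TestConfusion:
    def test_perfect_predictions(self):
        y = [0] * 5 + [1] * 5
        cm = confusion(y, y)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (5, 5, 0, 0)

    def test_published_validation_cells_sum(self):
        cm = ConfusionMatrix(tp=976, tn=904, fp=12, fn=50)
        assert cm.total == 1_942

    def test_published_test_cells_sum(self):
        cm = ConfusionMatrix(tp=1112, tn=1069, fp=28, fn=76)
        assert cm.total == 2_285

    def test_all_predicted_positive(self):
        cm = confusion([0, 0, 0, 1, 1], [1, 1, 1, 1, 1])
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (2, 3, 0, 0)

    def test_unknown_labels_rejected(self):
        with pytest.raises(ValidationError):
            confusion([0, 2], [0, 1])


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = compute_metrics(ConfusionMatrix(tp=50, tn=50, fp=0, fn=0))
        assert m.accuracy == m.precision == m.recall == m.f1 == m.specificity == 1.0

    def test_validation_cells_arithmetic(self):
        m = compute_metrics(ConfusionMatrix(tp=976, tn=904, fp=12, fn=50))
        assert m.accuracy == pytest.approx(1880 / 1942, abs=1e-12)
        assert m.recall == pytest.approx(976 / 1026, abs=1e-12)
        assert m.specificity == pytest.approx(904 / 916, abs=1e-12)
        assert m.f1 == pytest.approx(
            2 * m.precision * m.recall / (m.precision + m.recall), abs=1e-12
        )

    def test_test_cells_arithmetic(self):
        m = compute_metrics(ConfusionMatrix(tp=1112, tn=1069, fp=28, fn=76))
        assert m.accuracy == pytest.approx(2181 / 2285, abs=1e-12)

    def test_undefined_ratio_reported_with_reason(self):
        m = compute_metrics(ConfusionMatrix(tp=0, tn=10, fp=0, fn=5))
        assert m.precision is None
        assert "precision" in m.undefined
        assert m.accuracy == pytest.approx(10 / 15)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            compute_metrics(ConfusionMatrix(0, 0, 0, 0))


def auc_pair_counting(y, s) -> float:
    """Independent oracle: wins + half-ties over all positive-negative pairs."""
    y = np.asarray(y)
    s = np.asarray(s, dtype=float)
    pos = s[y == 1][:, None]
    neg = s[y == 0][None, :]
    wins = (pos > neg).sum() + 0.5 * (pos == neg).sum()
    return float(wins / (pos.size * neg.size))


class TestRocAuc:
    def test_perfect_separation(self):
        roc = roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert roc.auc == pytest.approx(1.0)
        assert roc.fpr[0] == roc.tpr[0] == 0.0
        assert roc.fpr[-1] == roc.tpr[-1] == 1.0

    def test_constant_scores_chance_line(self):
        roc = roc_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5])
        assert roc.auc == pytest.approx(0.5)

    def test_known_small_case(self):
        roc = roc_auc([1, 0, 1, 0], [0.9, 0.8, 0.4, 0.2])
        assert roc.auc == pytest.approx(0.75)

    def test_monotone_curve(self):
        rng = np.random.default_rng(0)
        roc = roc_auc(rng.integers(0, 2, 50) | np.array([1] + [0] * 49),
                      rng.random(50))
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 1, 1], [0.1, 0.5, 0.9])

    def test_matches_pair_counting_oracle_and_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(123)
        for _ in range(50):
            n = int(rng.integers(5, 60))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = np.round(rng.random(n), 2)  # rounding forces ties
            ours = roc_auc(y, s).auc
            assert ours == pytest.approx(auc_pair_counting(y, s), abs=1e-9)
            assert ours == pytest.approx(roc_auc_score(y, s), abs=1e-9)


class TestEvaluate:
    def test_report_schema_and_perfect_fit(self):
        ds = _toy_dataset(n_per_class=3)
        model = build_model(TINY_MODEL)
        model = train(model, ds, ds, TrainConfig(learning_rate=1e-2, epochs=150,
                                                 batch_size=4, seed=1))
        report = evaluate(model, ds)
        assert set(report) == {"n", "confusion", "metrics", "metrics_undefined", "auc", "roc"}
        assert report["n"] == 6
        assert report["metrics"]["accuracy"] >= 0.99
        assert report["auc"] == pytest.approx(1.0)
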