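"""Metric definitions against hand-computed and library oracles, ROC/AUC
equivalence with the Mann-Whitney statistic, and training-loop contracts."""
import numpy as np
import pandas as pd
import pytest
from sklearn import metrics as skm

from mobilemfs.datasets import preprocess_images
from mobilemfs.models import build_compact_mfs, save_checkpoint
from mobilemfs.train import (MetricsReport, TrainConfig, auc_trapezoid,
                             confusion_matrix, evaluate,
                             metrics_from_confusion, one_vs_rest_counts,
                             precision_recall_f1, roc_auc, roc_curve, train)


class TestMetricDefinitions:
    def test_binary_toy_counts(self):
        # TP=2, FP=1, FN=2, TN=6 for the positive class:
        # precision 2/3, recall 1/2, F1 = harmonic mean = 4/7
        cm = np.array([[6, 1], [2, 2]])
        counts = one_vs_rest_counts(cm, 1)
        assert counts == {"tp": 2, "fp": 1, "fn": 2, "tn": 6}
        pc = precision_recall_f1(cm)
        assert pc.loc[1, "precision"] == pytest.approx(2 / 3)
        assert pc.loc[1, "recall"] == pytest.approx(1 / 2)
        assert pc.loc[1, "f1"] == pytest.approx(4 / 7)

    def test_rust_misclassification_row(self):
        # printed confusion row: 534 correct, 4 to Frogeye, 2 to Health,
        # 10 to Scab; the row sum equals the class's test count (550)
        classes = ("Alternaria leaf spot", "Brown spot", "Frogeye leaf spot",
                   "Grey spot", "Health", "Mosaic", "Powdery mildew", "Rust",
                   "Scab")
        cm = np.zeros((9, 9), dtype=np.int64)
        for i in range(9):
            cm[i, i] = 100  # arbitrary diagonal elsewhere
        rust = classes.index("Rust")
        cm[rust] = 0
        cm[rust, rust] = 534
        cm[rust, classes.index("Frogeye leaf spot")] = 4
        cm[rust, classes.index("Health")] = 2
        cm[rust, classes.index("Scab")] = 10
        assert cm[rust].sum() == 550
        pc = precision_recall_f1(cm)
        assert pc.loc[rust, "recall"] == pytest.approx(534 / 550)
        assert pc.loc[rust, "recall"] == pytest.approx(0.9709, abs=1e-4)

    def test_perfect_predictions(self):
        cm = np.diag([5, 7, 3])
        rep = metrics_from_confusion(cm)
        assert rep.accuracy == 1.0
        assert rep.macro_f1 == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_micro_precision_equals_recall_equals_accuracy(self, seed):
        rng = np.random.default_rng(seed)
        cm = rng.integers(0, 40, size=(6, 6))
        rep = metrics_from_confusion(cm)
        assert rep.micro_precision == pytest.approx(rep.micro_recall)
        assert rep.micro_precision == pytest.approx(rep.accuracy)

    @pytest.mark.parametrize("seed", range(5))
    def test_f1_between_precision_and_recall(self, seed):
        rng = np.random.default_rng(100 + seed)
        cm = rng.integers(1, 40, size=(5, 5))
        pc = precision_recall_f1(cm)
        lo = pc[["precision", "recall"]].min(axis=1)
        hi = pc[["precision", "recall"]].max(axis=1)
        assert ((pc["f1"] >= lo - 1e-12) & (pc["f1"] <= hi + 1e-12)).all()

    def test_zero_division_convention(self):
        # a class never predicted: precision 0/0 -> 0.0 with a warning
        cm = np.array([[3, 0], [2, 0]])
        with pytest.warns(RuntimeWarning, match="0/0"):
            pc = precision_recall_f1(cm)
        assert pc.loc[1, "precision"] == 0.0

    def test_against_sklearn_on_random_predictions(self):
        rng = np.random.default_rng(7)
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        cm = confusion_matrix(y_true, y_pred, 4)
        np.testing.assert_array_equal(
            cm, skm.confusion_matrix(y_true, y_pred, labels=range(4)))
        rep = metrics_from_confusion(cm)
        assert rep.weighted_f1 == pytest.approx(
            skm.f1_score(y_true, y_pred, average="weighted"))
        assert rep.macro_recall == pytest.approx(
            skm.recall_score(y_true, y_pred, average="macro"))


class TestROC:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        curve = roc_curve(scores, labels)
        assert (0.0, 1.0) in curve
        assert auc_trapezoid(curve) == 1.0

    def test_random_scores_auc_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=10_000)
        labels = rng.integers(0, 2, 10_000)
        assert roc_auc(scores, labels) == pytest.approx(0.5, abs=0.02)

    def test_sign_reversal_flips_auc(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=300)
        labels = (scores + rng.normal(size=300) > 0).astype(int)
        assert roc_auc(-scores, labels) == pytest.approx(
            1.0 - roc_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve(np.array([0.1, 0.2]), np.array([1, 1]))

    @pytest.mark.parametrize("seed", range(6))
    def test_auc_equals_mann_whitney(self, seed):
        # trapezoid-with-tie-grouping AUC == U / (n_pos * n_neg), ties 0.5
        rng = np.random.default_rng(seed)
        scores = rng.integers(0, 6, 40).astype(float)  # heavy ties
        labels = rng.integers(0, 2, 40)
        if labels.sum() in (0, len(labels)):
            pytest.skip("degenerate draw")
        pos, neg = scores[labels == 1], scores[labels == 0]
        u = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        expected = u / (len(pos) * len(neg))
        assert roc_auc(scores, labels) == pytest.approx(expected)
        assert roc_auc(scores, labels) == pytest.approx(
            skm.roc_auc_score(labels, scores))

    def test_curve_monotone_from_origin_to_corner(self):
        rng = np.random.default_rng(11)
        scores = rng.normal(size=120)
        labels = rng.integers(0, 2, 120)
        curve = np.array(roc_curve(scores, labels))
        assert tuple(curve[0]) == (0.0, 0.0)
        assert tuple(curve[-1]) == (1.0, 1.0)
        assert (np.diff(curve[:, 0]) >= 0).all()
        assert (np.diff(curve[:, 1]) >= 0).all()


class _StubModel:
    """Deterministic scorer standing in for a trained network in metric
    plumbing tests (synthetic — not a trained model)."""

    def __init__(self, probs, num_classes):
        self._probs = probs
        from mobilemfs.models import compact_mfs_spec
        self.spec = compact_mfs_spec(num_classes)

    def predict_proba(self, X, batch_size=64):
        return self._probs


class TestEvaluate:
    def test_perfect_predictions_give_accuracy_and_auc_one(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        probs = np.eye(3)[y] * 0.9 + 0.05
        model = _StubModel(probs, 3)
        rep = evaluate(model, np.zeros((6, 1)), y, classes=("a", "b", "c"))
        assert rep.accuracy == 1.0
        assert rep.macro_auc == 1.0
        np.testing.assert_array_equal(np.diag(rep.confusion), [2, 2, 2])

    def test_confusion_row_sums_equal_test_counts(self):
        rng = np.random.default_rng(5)
        y = rng.integers(0, 4, 60)
        probs = rng.dirichlet(np.ones(4), size=60)
        rep = evaluate(_StubModel(probs, 4), np.zeros((60, 1)), y)
        counts = np.bincount(y, minlength=4)
        np.testing.assert_array_equal(rep.confusion.sum(axis=1), counts)

    def test_absent_class_excluded_with_warning(self):
        y = np.array([0, 0, 1, 1])  # class 2 absent
        probs = np.full((4, 3), 1 / 3)
        with pytest.warns(RuntimeWarning, match="absent"):
            rep = evaluate(_StubModel(probs, 3), np.zeros((4, 1)), y)
        assert np.isnan(rep.per_class["auc"].iloc[2])

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate(_StubModel(np.zeros((0, 3)), 3), np.zeros((0, 1)),
                     np.array([], dtype=int))


def _tiny_training_setup(seed, n_per_class=8, size=48):
    from mobilemfs.datasets import SyntheticSpec, generate_synthetic_arrays

    spec = SyntheticSpec(image_size=size, n_per_class=n_per_class, seed=seed)
    images, labels, _ = generate_synthetic_arrays(spec)
    return preprocess_images(images), labels


class TestTrainingLoop:
    def test_history_length_and_smoke(self):
        X, y = _tiny_training_setup(2)
        model = build_compact_mfs(9, seed=0)
        hist = train(model, X, y, X[:18], y[:18],
                     TrainConfig(epochs=2, seed=0))
        assert len(hist) == 2
        assert {"train_loss", "train_acc", "test_loss",
                "test_acc"} <= set(hist.columns)

    def test_same_seed_same_final_loss(self):
        X, y = _tiny_training_setup(3)
        losses = []
        for _ in range(2):
            model = build_compact_mfs(9, seed=4)
            hist = train(model, X, y, cfg=TrainConfig(epochs=2, seed=4))
            losses.append(hist["train_loss"].iloc[-1])
        assert losses[0] == losses[1]

    def test_loss_mostly_nonincreasing_early(self):
        # optimization sanity: the first five epochs trend downward in at
        # least 4 of 5 seeded runs
        monotone = 0
        for seed in range(5):
            X, y = _tiny_training_setup(seed, n_per_class=6)
            model = build_compact_mfs(9, seed=seed)
            hist = train(model, X, y, cfg=TrainConfig(epochs=5, seed=seed))
            monotone += int((np.diff(hist["train_loss"]) <= 1e-3).all())
        assert monotone >= 4

    def test_empty_train_set_rejected(self):
        model = build_compact_mfs(9, seed=0)
        with pytest.raises(ValueError, match="empty"):
            train(model, np.zeros((0, 3, 8, 8), np.float32),
                  np.array([], dtype=int))

    def test_transfer_init_loads_and_freezes(self, tmp_path):
        X, y = _tiny_training_setup(6, n_per_class=4)
        donor = build_compact_mfs(9, seed=1)
        save_checkpoint(donor, tmp_path / "donor.npz")
        student = build_compact_mfs(9, seed=2)
        cfg = TrainConfig(epochs=1, seed=2,
                          pretrained=str(tmp_path / "donor.npz"),
                          freeze_backbone_epochs=1)
        train(student, X, y, cfg=cfg)
        # frozen loaded weights unchanged after the frozen epoch
        for name, p in student.named_parameters():
            if name.startswith("blocks.0.depthwise"):
                donor_p = dict(donor.named_parameters())[name]
                np.testing.assert_array_equal(p.data, donor_p.data)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=-1)
        with pytest.raises(ValueError):
            TrainConfig(optimizer="lbfgs")


def test_report_serialization(tmp_path):
    y = np.array([0, 1, 0, 1, 1])
    probs = np.column_stack([1 - y * 0.8 - 0.1, y * 0.8 + 0.1])
    rep = evaluate(_StubModel(probs, 2), np.zeros((5, 1)), y,
                   classes=("neg", "pos"))
    rep.save(tmp_path)
    assert (tmp_path / "metrics.json").exists()
    assert (tmp_path / "metrics_confusion.csv").exists()
    assert (tmp_path / "metrics_roc_pos.csv").exists()
    df = pd.read_csv(tmp_path / "metrics_roc_pos.csv")
    assert {"fpr", "tpr"} <= set(df.columns)
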