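import numpy as np
import pytest

from pcgkit.train_eval import (
    ConfusionMatrix,
    FoldSplit,
    TrainConfig,
    compute_metrics,
    evaluate,
    roc_auc,
    stratified_kfold,
)


def _labels(n_per_class, classes=("N", "AS", "MR", "MS", "MVP")):
    out = {}
    for c in classes:
        for i in range(n_per_class):
            out[f"{c}{i}"] = c
    return out


class TestStratifiedKFold:
    def test_fold_sizes_forced_by_stratification(self):
        split = stratified_kfold(_labels(400), k=10, seed=0)
        labels = _labels(400)
        for fold in range(10):
            ids = split.test_ids(fold)
            assert len(ids) == 200
            per_class = {}
            for i in ids:
                per_class[labels[i]] = per_class.get(labels[i], 0) + 1
            assert all(v == 40 for v in per_class.values())

    def test_partition_property(self):
        split = stratified_kfold(_labels(13), k=5, seed=3)
        all_ids = set(_labels(13))
        seen = set()
        for fold in range(5):
            ids = set(split.test_ids(fold))
            assert not ids & seen
            seen |= ids
        assert seen == all_ids

    def test_deterministic_under_seed(self):
        a = stratified_kfold(_labels(20), k=4, seed=9)
        b = stratified_kfold(_labels(20), k=4, seed=9)
        assert a.assignments == b.assignments

    def test_too_few_records_per_class(self):
        with pytest.raises(ValueError, match="needs"):
            stratified_kfold(_labels(3), k=10)


class _ConstantModel:
    """Predicts a fixed class for everything."""

    def __init__(self, cls):
        self.cls = cls

    def predict(self, X):
        return np.array([self.cls] * len(X))


class _OracleModel:
    def __init__(self, y):
        self.y = np.asarray(y)

    def predict(self, X):
        return self.y


class TestEvaluate:
    def test_perfect_predictor_diagonal(self):
        y = np.array(["N", "AS"] * 5)
        cm = evaluate(_OracleModel(y), np.zeros((10, 1)), y, labels=("N", "AS"))
        assert cm.counts.sum() == 10
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))

    def test_constant_predictor_single_column(self):
        y = np.repeat(["N", "AS", "MR", "MS", "MVP"], 40)
        cm = evaluate(_ConstantModel("N"), np.zeros((200, 1)), y)
        assert np.all(cm.counts[:, 0] == 40)
        assert cm.counts[:, 1:].sum() == 0

    def test_row_sums_match_class_counts(self, rng):
        classes = ("N", "AS", "MR")
        y = rng.choice(classes, size=60)
        pred = rng.choice(classes, size=60)
        cm = evaluate(_OracleModel(pred), np.zeros((60, 1)), y, labels=classes)
        for i, c in enumerate(classes):
            assert cm.counts[i].sum() == (y == c).sum()

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate(_ConstantModel("N"), np.zeros((0, 1)), np.array([]))


class TestComputeMetrics:
    def test_perfect_binary_case(self):
        cm = ConfusionMatrix(np.array([[50, 0], [0, 50]]), ("pos", "neg"))
        rep = compute_metrics(cm)
        for m in ("ACC", "SE", "SP", "PR", "F1"):
            assert rep.per_class.loc["pos", m] == 100.0
            assert rep.macro[m] == 100.0

    def test_hand_computed_one_vs_rest_case(self):
        # TP=8, FN=2, TN=85, FP=5 for the positive class
        cm = ConfusionMatrix(np.array([[8, 2], [5, 85]]), ("pos", "neg"))
        rep = compute_metrics(cm)
        row = rep.per_class.loc["pos"]
        assert row["SE"] == pytest.approx(80.0)
        assert row["SP"] == pytest.approx(94.4444, abs=1e-3)
        assert row["PR"] == pytest.approx(61.5385, abs=1e-3)
        assert row["ACC"] == pytest.approx(93.0)
        assert row["F1"] == pytest.approx(69.5652, abs=1e-3)

    def test_f1_fixed_point_when_pr_equals_se(self):
        # symmetric errors: PR == SE for each class
        cm = ConfusionMatrix(np.array([[8, 2], [2, 8]]), ("a", "b"))
        rep = compute_metrics(cm)
        row = rep.per_class.loc["a"]
        assert row["PR"] == row["SE"] == row["F1"]

    def test_zero_denominator_flagged_as_zero(self):
        # no predictions of class b at all: PR(b) undefined -> 0 + flag
        cm = ConfusionMatrix(np.array([[10, 0], [5, 0]]), ("a", "b"))
        rep = compute_metrics(cm)
        assert rep.per_class.loc["b", "PR"] == 0.0
        assert "b:PR" in rep.zero_division_flags

    def test_macro_invariant_to_class_relabeling(self):
        counts = np.array([[30, 3, 2], [4, 28, 1], [0, 5, 27]])
        rep = compute_metrics(ConfusionMatrix(counts, ("x", "y", "z")))
        perm = [2, 0, 1]
        rep_p = compute_metrics(
            ConfusionMatrix(counts[np.ix_(perm, perm)], ("z", "x", "y"))
        )
        for m in ("ACC", "SE", "SP", "PR", "F1"):
            assert rep.macro[m] == pytest.approx(rep_p.macro[m], abs=1e-9)


def mann_whitney_auc(pos_scores, neg_scores):
    """Pairwise-comparison AUC oracle."""
    wins = 0.0
    for p in pos_scores:
        for q in neg_scores:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))


class TestRocAuc:
    def test_perfect_separation(self):
        scores = np.array([[0.9, 0.1]] * 5 + [[0.1, 0.9]] * 5)
        labels = np.array(["a"] * 5 + [["b"] * 5]).ravel() if False else np.array(
            ["a"] * 5 + ["b"] * 5
        )
        aucs, macro = roc_auc(scores, labels, classes=("a", "b"))
        assert aucs["a"] == pytest.approx(1.0)
        assert macro == pytest.approx(1.0)

    def test_matches_rank_statistic_oracle(self, rng):
        scores = rng.uniform(size=(30, 2))
        scores /= scores.sum(axis=1, keepdims=True)
        labels = rng.choice(["a", "b"], size=30)
        aucs, _ = roc_auc(scores, labels, classes=("a", "b"))
        ref = mann_whitney_auc(
            scores[labels == "a", 0], scores[labels == "b", 0]
        )
        assert aucs["a"] == pytest.approx(ref, abs=1e-9)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=(2000, 2))
        scores /= scores.sum(axis=1, keepdims=True)
        labels = rng.choice(["a", "b"], size=2000)
        _, macro = roc_auc(scores, labels, classes=("a", "b"))
        assert macro == pytest.approx(0.5, abs=0.05)

    def test_single_class_flagged_nan(self):
        scores = np.array([[0.6, 0.4]] * 4)
        aucs, macro = roc_auc(scores, np.array(["a"] * 4), classes=("a", "b"))
        assert np.isnan(aucs["a"]) and np.isnan(aucs["b"]) and np.isnan(macro)


class TestTrainConfig:
    def test_momentum_bounds(self):
        with pytest.raises(ValueError):
            TrainConfig(momentum=1.0)

    def test_batch_bounds(self):
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)


class TestRunCV:
    def test_smoke_two_folds_small(self, tmp_path):
        """k=2 on a 4-per-class set completes and pools every record once."""
        from pcgkit.synthetic import generate_dataset
        from pcgkit.train_eval import run_cv

        _, recs = generate_dataset(4, None, seed=5)
        result = run_cv(
            recs,
            k=2,
            model_params=dict(
                stage_widths=(4, 8, 8, 8, 8, 8),
                convs_per_stage=(1, 1, 1, 1, 1, 1),
                embed_dim=16,
                heads=4,
                ffn_hidden=32,
                head_hidden=32,
            ),
            train_cfg=TrainConfig(epochs=1, batch_size=5, seed=5),
            seed=5,
            out_dir=tmp_path / "run",
        )
        assert len(result["fold_reports"]) == 2
        assert result["pooled_confusion"].total == 20
        accs = result["summary"]["fold_accuracies"]
        assert result["summary"]["mean_accuracy"] == pytest.approx(
            np.mean(accs), abs=1e-9
        )
        for name in ("summary.json", "confusion.csv", "folds.csv", "history.csv"):
            assert (tmp_path / "run" / name).exists()
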