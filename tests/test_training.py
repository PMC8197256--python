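"""Metrics against independent oracles, the fit loop, CV, and the grid runner."""

import itertools

import numpy as np
import pytest

from kmerbind.datasets import split_folds
from kmerbind.embedding import CbowConfig
from kmerbind.model import ModelConfig, build_model
from kmerbind.training import (
    FeatureConfig,
    TrainConfig,
    cross_validate,
    evaluate,
    f1,
    fit,
    pr_auc,
    predict_in_batches,
    roc_auc,
    run_ablation,
)

SMALL_CBOW = CbowConfig(d=16, epochs=2, seed=0)


def _pairwise_roc_auc(labels, scores):
    """Exhaustive positive-negative pair comparison, ties counted 0.5."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def _confusion_metrics(labels, scores, threshold=0.5):
    """Step-sum PR AUC and threshold F1 from first principles."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    order = np.argsort(-scores, kind="stable")
    tp = fp = 0
    n_pos = labels.sum()
    prev_recall = 0.0
    area = 0.0
    # walk down distinct thresholds; precision weighted by recall increments
    for s in np.unique(scores)[::-1]:
        sel = scores >= s
        tp = int((labels[sel] == 1).sum())
        fp = int((labels[sel] == 0).sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
    preds = scores >= threshold
    tp = int(((preds == 1) & (labels == 1)).sum())
    fp = int(((preds == 1) & (labels == 0)).sum())
    fn = int(((preds == 0) & (labels == 1)).sum())
    f1v = 0.0 if tp == 0 else 2 * tp / (2 * tp + fp + fn)
    return area, f1v


class TestRocAuc:
    @pytest.mark.parametrize(
        "labels,scores,expected",
        [
            ([1, 0], [0.9, 0.1], 1.0),
            ([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5], 0.5),
            ([1, 1, 0, 0], [0.8, 0.3, 0.5, 0.1], 0.75),
        ],
    )
    def test_worked_examples(self, labels, scores, expected):
        assert roc_auc(labels, scores) == expected

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.2, 0.8])

    def test_agrees_with_pairwise_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 31))
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                labels[0], labels[1] = 0, 1
            scores = np.round(rng.random(n), 2)  # rounding forces ties
            assert roc_auc(labels, scores) == pytest.approx(
                _pairwise_roc_auc(labels, scores), abs=1e-12
            )


class TestPrAucAndF1:
    def test_perfect_ranking(self):
        assert pr_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0
        assert f1([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0

    def test_single_positive_ranked_first(self):
        labels = [1] + [0] * 9
        scores = np.linspace(1.0, 0.1, 10)
        assert pr_auc(labels, scores) == 1.0

    def test_tp1_fp1_fn1(self):
        # threshold 0.5: one true positive, one false positive, one miss
        assert f1([1, 0, 1, 0], [0.9, 0.8, 0.1, 0.2]) == 0.5

    def test_all_predicted_negative_zero(self):
        assert f1([1, 0], [0.1, 0.2]) == 0.0

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_auc([0, 0], [0.1, 0.2])

    def test_enumerated_four_record_labelings(self, rng):
        """All 2^4 labelings with at least one positive, against the
        confusion-matrix arithmetic oracle."""
        scores = np.array([0.9, 0.6, 0.4, 0.2])
        for bits in itertools.product([0, 1], repeat=4):
            labels = np.array(bits)
            if labels.sum() == 0:
                continue
            want_pr, want_f1 = _confusion_metrics(labels, scores)
            assert pr_auc(labels, scores) == pytest.approx(want_pr, abs=1e-12)
            assert f1(labels, scores) == pytest.approx(want_f1, abs=1e-12)

    def test_random_scores_pr_auc_near_prevalence(self, rng):
        n = 10_000
        labels = rng.integers(0, 2, n)
        scores = rng.random(n)
        assert pr_auc(labels, scores) == pytest.approx(labels.mean(), abs=0.03)


def _toy_separable(n=200, length=40, d=8, seed=0):
    """Positives carry a constant pattern in the first feature dimension."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, length, d)).astype(np.float32) * 0.3
    y = np.arange(n) % 2
    X[y == 1, :, 0] += 1.0
    return X, y


@pytest.fixture(scope="module")
def toy_fit():
    X, y = _toy_separable()
    model = build_model(
        ModelConfig(input_dim=8, conv_channels=4, lstm_units=3, fc_hidden=8,
                    seed=0),
        input_len=40,
    )
    result = fit(model, (X[:140], y[:140]), (X[140:], y[140:]),
                 TrainConfig(epochs=30, seed=0))
    return result, X, y


class TestFit:
    def test_loss_decreases_and_val_auc_perfect(self, toy_fit):
        result, _, _ = toy_fit
        losses = [h["train_loss"] for h in result.history]
        assert losses[2] < losses[0]
        assert result.best_val_auc == 1.0

    def test_history_length_equals_epochs(self, toy_fit):
        result, _, _ = toy_fit
        assert len(result.history) == 30

    def test_best_val_auc_is_max_over_history(self, toy_fit):
        result, _, _ = toy_fit
        assert result.best_val_auc == max(h["val_roc_auc"] for h in result.history)
        assert result.history[result.best_epoch]["val_roc_auc"] == result.best_val_auc

    def test_single_epoch_returns_epoch_one_model(self):
        X, y = _toy_separable(n=60)
        model = build_model(
            ModelConfig(input_dim=8, conv_channels=4, lstm_units=3, seed=0),
            input_len=40,
        )
        result = fit(model, (X[:40], y[:40]), (X[40:], y[40:]),
                     TrainConfig(epochs=1, seed=0))
        assert result.best_epoch == 0 and len(result.history) == 1

    def test_single_class_validation_rejected(self):
        X, y = _toy_separable(n=40)
        model = build_model(
            ModelConfig(input_dim=8, conv_channels=4, lstm_units=3, seed=0),
            input_len=40,
        )
        with pytest.raises(ValueError, match="both classes"):
            fit(model, (X[:30], y[:30]), (X[30:], np.ones(10, dtype=int)),
                TrainConfig(epochs=1))


@pytest.fixture(scope="module")
def cv_result(small_dataset):
    dataset, _ = small_dataset
    split = split_folds(dataset, n_folds=3, seed=0)
    fc = FeatureConfig(cbow=SMALL_CBOW)
    mc = ModelConfig(conv_channels=4, lstm_units=3, fc_hidden=8, seed=0)
    tc = TrainConfig(epochs=2, seed=0)
    return cross_validate(dataset, split, mc, tc, fc), (dataset, split, mc, tc, fc)


class TestCrossValidate:
    def test_one_report_per_fold(self, cv_result):
        result, _ = cv_result
        assert len(result.fold_reports) == 3

    def test_mean_is_arithmetic_mean(self, cv_result):
        result, _ = cv_result
        assert result.mean_report.roc_auc == pytest.approx(
            np.mean([r.roc_auc for r in result.fold_reports])
        )
        assert result.mean_report.f1 == pytest.approx(
            np.mean([r.f1 for r in result.fold_reports])
        )

    def test_deterministic_under_fixed_seeds(self, cv_result):
        result, (dataset, split, mc, tc, fc) = cv_result
        again = cross_validate(dataset, split, mc, tc, fc)
        for a, b in zip(result.fold_reports, again.fold_reports):
            assert a == b


class TestRunAblation:
    def test_grid_rows_and_graceful_failure(self, small_dataset):
        dataset, _ = small_dataset  # 60 bp sequences
        grid = {"k": [3, 400], "stride": [1, 2]}  # k=400 > length: infeasible
        table = run_ablation(
            dataset,
            grid,
            model_config=ModelConfig(conv_channels=4, lstm_units=3, fc_hidden=8,
                                     seed=0),
            train_config=TrainConfig(epochs=1, seed=0),
            feature_config=FeatureConfig(cbow=SMALL_CBOW),
            seed=0,
        )
        assert len(table) == 4  # one row per cell
        ok = table[table["k"] == 3]
        bad = table[table["k"] == 400]
        assert (ok["status"] == "ok").all()
        assert (bad["status"] == "failed").all()
        assert bad["error"].str.len().gt(0).all()

    def test_featurizer_and_architecture_axes(self, small_dataset, tmp_path):
        dataset, _ = small_dataset
        grid = {"featurizer": ["cbow", "onehot"], "architecture": ["cnn_only"]}
        out = tmp_path / "ablation.tsv"
        table = run_ablation(
            dataset,
            grid,
            model_config=ModelConfig(conv_channels=4, lstm_units=3, fc_hidden=8,
                                     seed=0),
            train_config=TrainConfig(epochs=1, seed=0),
            feature_config=FeatureConfig(cbow=SMALL_CBOW),
            seed=0,
            out_tsv=out,
        )
        assert len(table) == 2
        assert out.exists()
        assert (table["status"] == "ok").all()

    def test_unknown_axis_rejected(self, small_dataset):
        dataset, _ = small_dataset
        with pytest.raises(ValueError):
            run_ablation(dataset, {"bogus": [1]})
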