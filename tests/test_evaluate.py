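"""Confusion metrics, ROC/AUC, cross-validation and confidence tests."""

import numpy as np
import pandas as pd
import pytest

from essgene import evaluate
from essgene.model import ModelSpec, PredictionRecord
from essgene.tableio import ESSENTIAL, NONESSENTIAL

from .conftest import separable_table
from .oracles import auc_concordance


def _records(pred_classes, ids=None, confs=None):
    ids = ids or [f"g{i}" for i in range(len(pred_classes))]
    confs = confs or [0.8] * len(pred_classes)
    return [
        PredictionRecord(g, c, conf, conf if c == ESSENTIAL else 1 - conf)
        for g, c, conf in zip(ids, pred_classes, confs)
    ]


class TestConfusionMetrics:
    def test_all_correct(self):
        truth = pd.Series([ESSENTIAL, NONESSENTIAL], index=["g0", "g1"])
        counts, mets = evaluate.confusion_and_metrics(_records([ESSENTIAL, NONESSENTIAL]), truth)
        assert (mets.tpr, mets.fpr, mets.accuracy) == (1.0, 0.0, 1.0)

    def test_published_confusion_counts_reproduce_metrics(self):
        # confusion cells TP=170, FN=59, TN=645, FP=157 imply the test-set
        # class sizes 229 essential / 802 non-essential and accuracy 815/1031
        c = evaluate.ConfusionCounts(tp=170, fn=59, tn=645, fp=157)
        m = evaluate.metrics_from_counts(c)
        assert c.n_essential == 229
        assert c.n_nonessential == 802
        assert m.accuracy == pytest.approx(815 / 1031)
        assert m.accuracy == pytest.approx(0.7905, abs=1e-4)
        assert m.tpr == pytest.approx(170 / 229)
        assert m.tpr == pytest.approx(0.7424, abs=1e-4)

    def test_counts_built_from_prediction_lists(self):
        truth = pd.Series(
            [ESSENTIAL, ESSENTIAL, NONESSENTIAL, NONESSENTIAL],
            index=[f"g{i}" for i in range(4)],
        )
        preds = _records([ESSENTIAL, NONESSENTIAL, NONESSENTIAL, ESSENTIAL])
        counts, _ = evaluate.confusion_and_metrics(preds, truth)
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (1, 1, 1, 1)

    def test_id_mismatch_rejected(self):
        truth = pd.Series([ESSENTIAL], index=["absent"])
        with pytest.raises(ValueError, match="absent"):
            evaluate.confusion_and_metrics(_records([ESSENTIAL]), truth)


class TestROC:
    def test_perfect_and_reversed_ranking(self):
        truth = [ESSENTIAL, ESSENTIAL, NONESSENTIAL, NONESSENTIAL]
        assert evaluate.roc_auc([0.9, 0.8, 0.2, 0.1], truth).auc == 1.0
        assert evaluate.roc_auc([0.1, 0.2, 0.8, 0.9], truth).auc == 0.0

    def test_hand_counted_concordance(self):
        curve = evaluate.roc_auc([0.9, 0.8, 0.7, 0.6], [ESSENTIAL, NONESSENTIAL, ESSENTIAL, NONESSENTIAL])
        assert curve.auc == pytest.approx(0.75)

    def test_curve_spans_unit_square(self):
        rng = np.random.default_rng(0)
        truth = [ESSENTIAL] * 10 + [NONESSENTIAL] * 10
        curve = evaluate.roc_auc(rng.random(20), truth)
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)

    def test_complement_symmetry(self):
        rng = np.random.default_rng(1)
        s = rng.random(30)
        truth = [ESSENTIAL if x else NONESSENTIAL for x in rng.integers(0, 2, 30)]
        assert evaluate.roc_auc(s, truth).auc + evaluate.roc_auc(1 - s, truth).auc == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_pair_concordance_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)  # ties likely
        truth = [ESSENTIAL] * (n // 2 + 1) + [NONESSENTIAL] * (n - n // 2 - 1)
        assert evaluate.roc_auc(scores, truth).auc == pytest.approx(
            auc_concordance(scores, truth, ESSENTIAL)
        )

    def test_one_class_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate.roc_auc([0.1, 0.9], [ESSENTIAL, ESSENTIAL])


class TestFolds:
    def test_partition_covers_each_index_once(self):
        folds = evaluate.partition_folds(23, 10, seed=0)
        assert sorted(np.concatenate(folds)) == list(range(23))
        sizes = [len(f) for f in folds]
        assert sizes == [3, 3, 3] + [2] * 7  # remainder spread from fold 0

    def test_more_folds_than_items_rejected(self):
        with pytest.raises(ValueError):
            evaluate.partition_folds(3, 5)


class TestCrossValidate:
    def test_separable_data_near_perfect(self):
        table, labels = separable_table(n_per_class=60, seed=0)
        res = evaluate.cross_validate(table, labels, ModelSpec("random_forest", {"n_trees": 60}), k=10, seed=0)
        assert res.pooled_accuracy >= 0.99

    def test_pooled_counts_sum_to_n_and_match_metrics(self):
        table, labels = separable_table(n_per_class=40, seed=1, shift=1.0)
        res = evaluate.cross_validate(table, labels, ModelSpec("naive_bayes"), k=5, seed=1)
        assert res.pooled_counts.n == table.n_genes
        assert res.pooled_accuracy == pytest.approx(
            evaluate.metrics_from_counts(res.pooled_counts).accuracy
        )
        assert len(res.records) == table.n_genes

    def test_default_fold_count_is_10(self):
        import inspect

        assert inspect.signature(evaluate.cross_validate).parameters["k"].default == 10

    def test_too_many_folds_rejected(self):
        table, labels = separable_table(n_per_class=3, seed=2)
        with pytest.raises(ValueError):
            evaluate.cross_validate(table, labels, ModelSpec("naive_bayes"), k=50)


class TestCompareConfidences:
    def test_identical_groups_not_significant(self):
        g = [0.6, 0.7, 0.8, 0.9] * 5
        rep = evaluate.compare_confidences(g, g)
        assert rep.p_value > 0.9

    def test_normal_samples_choose_welch_with_correct_direction(self):
        rng = np.random.default_rng(0)
        correct = rng.normal(0.647, 0.05, 116 - 32)
        incorrect = rng.normal(0.608, 0.05, 32)
        rep = evaluate.compare_confidences(correct, incorrect)
        assert rep.test_used == "welch-t"
        assert rep.mean_correct > rep.mean_incorrect

    def test_non_normal_samples_choose_rank_sum(self):
        rng = np.random.default_rng(1)
        a = rng.exponential(1.0, 80) ** 2  # heavily skewed
        b = rng.exponential(1.3, 80) ** 2
        rep = evaluate.compare_confidences(a, b)
        assert rep.test_used == "wilcoxon-rank-sum"

    def test_shifted_normals_detected(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0.5, 0.1, 100)
        b = rng.normal(0.45, 0.1, 100)  # shift of 0.5 sd
        rep = evaluate.compare_confidences(a, b)
        assert rep.p_value < 0.01

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            evaluate.compare_confidences([0.5, 0.6], [0.7, 0.8, 0.9])
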