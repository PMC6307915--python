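"""Cross-validation, confusion-count metrics, ROC/AUC and confidence
statistics.

Metric conventions for the binary essentiality problem: TP = essential
genes predicted correctly, FN = essential genes predicted incorrectly,
TN = non-essential genes predicted correctly, FP = non-essential genes
predicted incorrectly, with

    TPR = TP / (TP + FN)        (recall / sensitivity)
    FPR = FP / (FP + TN)
    accuracy = (TP + TN) / (TP + TN + FP + FN)

Cross-validation uses a seeded unstratified random partition into k
near-equal folds.  By default imputation and discretisation are refit
inside each training fold and applied to its test fold, so no held-out
label information can leak into the cutpoints; fitting the
pre-processing once on the full table before CV (the looser historical
order) is available via ``refit_per_fold=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from . import chimerge, tableio
from .model import EnsembleModel, ModelSpec, PredictionRecord, predict_with_confidence, train_model
from .tableio import ESSENTIAL, NONESSENTIAL, FeatureTable, validate_labels


@dataclass
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def n_essential(self) -> int:
        return self.tp + self.fn

    @property
    def n_nonessential(self) -> int:
        return self.tn + self.fp


@dataclass
class MetricSet:
    tpr: float
    fpr: float
    accuracy: float
    auc: float | None = None


def metrics_from_counts(c: ConfusionCounts, auc: float | None = None) -> MetricSet:
    tpr = c.tp / c.n_essential if c.n_essential else 0.0
    fpr = c.fp / c.n_nonessential if c.n_nonessential else 0.0
    return MetricSet(tpr=tpr, fpr=fpr, accuracy=(c.tp + c.tn) / c.n, auc=auc)


def confusion_and_metrics(
    predictions: list[PredictionRecord], truth: pd.Series
) -> tuple[ConfusionCounts, MetricSet]:
    """Count the four confusion cells of a prediction list against truth
    labels and derive TPR / FPR / accuracy."""
    validate_labels(truth)
    by_gene = {r.gene_id: r.predicted_class for r in predictions}
    missing = [g for g in truth.index if g not in by_gene]
    if missing:
        raise ValueError(f"predictions missing for gene(s): {missing[:5]}")
    tp = fn = tn = fp = 0
    for g, t in truth.items():
        p = by_gene[g]
        if t == ESSENTIAL:
            tp, fn = tp + (p == ESSENTIAL), fn + (p != ESSENTIAL)
        else:
            tn, fp = tn + (p == NONESSENTIAL), fp + (p != NONESSENTIAL)
    counts = ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)
    return counts, metrics_from_counts(counts)


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores_for_essential, truth) -> ROCCurve:
    """ROC curve from a threshold sweep over distinct scores; AUC by the
    trapezoid rule.  Tied scores step simultaneously, so the AUC equals
    the rank (Mann-Whitney) statistic with ties counted one half."""
    y = np.asarray(truth)
    s = np.asarray(scores_for_essential, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("truth must contain both classes")
    fpr, tpr, _ = _sk_roc_curve(y, s, pos_label=ESSENTIAL)
    return ROCCurve(fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)))


def partition_folds(n: int, k: int, seed: int | None = None) -> list[np.ndarray]:
    """Seeded unstratified partition of range(n) into k folds of size
    n // k, with the remainder spread one per fold starting at fold 0."""
    if k > n:
        raise ValueError("more folds than genes")
    if k < 2:
        raise ValueError("k must be >= 2")
    perm = np.random.default_rng(seed).permutation(n)
    base, extra = divmod(n, k)
    folds, start = [], 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        folds.append(np.sort(perm[start : start + size]))
        start += size
    return folds


@dataclass
class CVResult:
    fold_metrics: list[MetricSet]
    pooled_counts: ConfusionCounts
    pooled_accuracy: float
    records: list[PredictionRecord]  # held-out prediction of every gene


def cross_validate(
    table: FeatureTable,
    labels: pd.Series,
    spec: ModelSpec,
    k: int = 10,
    seed: int | None = None,
    refit_per_fold: bool = True,
    discretise: bool = True,
    significance: float = 0.95,
) -> CVResult:
    """k-fold cross-validation with in-fold pre-processing.

    Each fold's training part fits the imputation model and (optionally)
    the discretisation schemes, which are then applied unchanged to the
    fold's test part.  Pooled accuracy is total correct over total genes.
    """
    validate_labels(labels, table)
    labels = labels.reindex(table.values.index)
    folds = partition_folds(table.n_genes, k, seed)

    if not refit_per_fold:
        imp = tableio.fit_impute(table)
        full = tableio.apply_impute(imp, table)
        if discretise:
            full, _ = chimerge.discretise_table(full, labels, significance)
        table = full

    all_idx = np.arange(table.n_genes)
    gene_ids = np.asarray(table.gene_ids)
    records: list[PredictionRecord] = []
    fold_metrics: list[MetricSet] = []
    tp = fn = tn = fp = 0
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        tr = table.subset_genes(gene_ids[train_idx])
        te = table.subset_genes(gene_ids[test_idx])
        if refit_per_fold:
            imp = tableio.fit_impute(tr)
            tr, te = tableio.apply_impute(imp, tr), tableio.apply_impute(imp, te)
            if discretise:
                tr, schemes = chimerge.discretise_table(tr, labels.loc[tr.gene_ids], significance)
                te = chimerge.apply_schemes(te, schemes)
        fold_spec = ModelSpec(spec.family, dict(spec.hyperparameters), seed=spec.seed + i)
        mdl = train_model(tr, labels.loc[tr.gene_ids], fold_spec)
        recs = predict_with_confidence(mdl, te)
        records.extend(recs)
        counts, mets = confusion_and_metrics(recs, labels.loc[te.gene_ids])
        fold_metrics.append(mets)
        tp, fn, tn, fp = tp + counts.tp, fn + counts.fn, tn + counts.tn, fp + counts.fp

    pooled = ConfusionCounts(tp=tp, fn=fn, tn=tn, fp=fp)
    return CVResult(
        fold_metrics=fold_metrics,
        pooled_counts=pooled,
        pooled_accuracy=(tp + tn) / pooled.n,
        records=records,
    )


@dataclass
class ConfidenceComparison:
    """Shapiro-Wilk-gated two-sample comparison of prediction confidences."""

    normal_correct: bool
    normal_incorrect: bool
    test_used: str  # "welch-t" or "wilcoxon-rank-sum"
    statistic: float
    p_value: float
    mean_correct: float
    mean_incorrect: float


def compare_confidences(correct, incorrect, alpha: float = 0.05) -> ConfidenceComparison:
    """Compare confidence levels of correct vs incorrect predictions.

    Each group is tested for normality (Shapiro-Wilk at ``alpha``); if
    both pass, Welch's two-sided unequal-variance t-test is used,
    otherwise the two-sided Wilcoxon rank-sum test.
    """
    a = np.asarray(correct, dtype=float)
    b = np.asarray(incorrect, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    # Shapiro-Wilk is undefined for zero-variance samples; treat a constant
    # sample as non-normal so the rank test (which tolerates ties) is used
    norm_a = a.std() > 0 and stats.shapiro(a).pvalue > alpha
    norm_b = b.std() > 0 and stats.shapiro(b).pvalue > alpha
    if norm_a and norm_b:
        res = stats.ttest_ind(a, b, equal_var=False)
        test = "welch-t"
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "wilcoxon-rank-sum"
    return ConfidenceComparison(
        normal_correct=bool(norm_a),
        normal_incorrect=bool(norm_b),
        test_used=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_correct=float(a.mean()),
        mean_incorrect=float(b.mean()),
    )
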