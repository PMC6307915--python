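"""Classifier families and vote-fraction prediction confidence.

The primary classifier is a random forest whose per-tree votes give each
prediction a confidence: the fraction of trees voting for the predicted
class, always in [0.5, 1] for binary majority voting (an exact tie is
called non-essential — the conservative class — at confidence 0.5).
Five baseline families are available with their conventional
hyperparameters: RBF and polynomial SVMs at C = 50, logistic regression
with ridge 1e-8, a Gaussian naive Bayes, and a pruned decision tree with
confidence factor 0.25 (approximated here by cost-complexity pruning).

Non-forest families expose a probability-like score for ROC analysis
(SVM margins pass through a logistic link); the vote-fraction confidence
semantics are forest-specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .tableio import ESSENTIAL, NONESSENTIAL, FeatureTable, validate_labels

FAMILIES = ("random_forest", "svm_rbf", "svm_poly", "logistic", "naive_bayes", "decision_tree")

_DEFAULTS: dict[str, dict[str, Any]] = {
    "random_forest": {"n_trees": 230},
    "svm_rbf": {"C": 50.0, "gamma": 0.01},
    "svm_poly": {"C": 50.0, "degree": 2},
    "logistic": {"ridge": 1e-8},
    "naive_bayes": {},
    "decision_tree": {"confidence_factor": 0.25},
}


@dataclass
class ModelSpec:
    """A classifier family plus its hyperparameters and seed."""

    family: str
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        self.hyperparameters = {**_DEFAULTS[self.family], **self.hyperparameters}
        hp = self.hyperparameters
        if self.family == "random_forest" and hp["n_trees"] < 1:
            raise ValueError("n_trees must be >= 1")
        if "C" in hp and hp["C"] <= 0:
            raise ValueError("C must be > 0")
        if "ridge" in hp and hp["ridge"] < 0:
            raise ValueError("ridge must be >= 0")


def build_estimator(spec: ModelSpec):
    """Instantiate the scikit-learn estimator behind a spec."""
    hp = spec.hyperparameters
    seed = spec.seed % (2**31)
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=hp["n_trees"],
            max_features="sqrt",
            bootstrap=True,
            random_state=seed,
            n_jobs=1,
        )
    if spec.family == "svm_rbf":
        return SVC(kernel="rbf", C=hp["C"], gamma=hp["gamma"], random_state=seed)
    if spec.family == "svm_poly":
        return SVC(kernel="poly", C=hp["C"], degree=hp["degree"], random_state=seed)
    if spec.family == "logistic":
        # ridge r on the squared-weight penalty ~ inverse-regularisation C = 1/r
        c = np.inf if hp["ridge"] == 0 else 1.0 / hp["ridge"]
        return LogisticRegression(C=min(c, 1e12), max_iter=2000)
    if spec.family == "naive_bayes":
        return GaussianNB()
    # decision_tree: C4.5-style confidence-factor pruning is approximated by
    # cost-complexity pruning; lower confidence factor -> heavier pruning
    return DecisionTreeClassifier(ccp_alpha=0.25 * hp["confidence_factor"] / 100, random_state=seed)


@dataclass
class EnsembleModel:
    """A fitted classifier locked to its training feature order."""

    spec: ModelSpec
    estimator: Any
    features: list[str]

    def _matrix(self, table: FeatureTable) -> np.ndarray:
        missing = [f for f in self.features if f not in table.features]
        if missing:
            raise ValueError(f"table lacks required feature(s): {missing}")
        return table.values[self.features].to_numpy(dtype=float)


@dataclass
class PredictionRecord:
    """One gene's call: predicted class, winning-vote confidence, and the
    essential-class score used for ROC curves."""

    gene_id: str
    predicted_class: str
    confidence: float
    score_for_essential: float


def train_model(table: FeatureTable, labels: pd.Series, spec: ModelSpec) -> EnsembleModel:
    """Fit a classifier on an imputed (no missing cells) table."""
    validate_labels(labels, table)
    if table.values.isna().any().any():
        raise ValueError("table contains missing cells; impute before training")
    y = labels.reindex(table.values.index).to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("training labels contain a single class")
    est = build_estimator(spec)
    est.fit(table.values.to_numpy(dtype=float), y)
    return EnsembleModel(spec=spec, estimator=est, features=table.features)


def _forest_scores(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting essential, per gene."""
    est = model.estimator
    classes = list(est.classes_)
    e_idx = classes.index(ESSENTIAL)
    votes = np.zeros(len(X))
    for tree in est.estimators_:
        votes += tree.predict(X) == e_idx
    return votes / len(est.estimators_)


def _score_for_essential(model: EnsembleModel, X: np.ndarray) -> np.ndarray:
    est = model.estimator
    if model.spec.family == "random_forest":
        return _forest_scores(model, X)
    if hasattr(est, "predict_proba"):
        e_idx = list(est.classes_).index(ESSENTIAL)
        return est.predict_proba(X)[:, e_idx]
    # SVMs: signed margin through a logistic link
    margin = est.decision_function(X)
    if list(est.classes_)[1] != ESSENTIAL:
        margin = -margin
    return 1.0 / (1.0 + np.exp(-margin))


def predict_with_confidence(model: EnsembleModel, table: FeatureTable) -> list[PredictionRecord]:
    """Predict each gene's class with a confidence score.

    For the random forest the predicted class is the majority tree vote
    (exact tie -> non-essential) and the confidence is the winning vote
    fraction, in [0.5, 1].  Other families use their probability-like
    score the same way.
    """
    X = model._matrix(table)
    scores = _score_for_essential(model, X)
    records = []
    for gene, s in zip(table.gene_ids, scores):
        predicted = ESSENTIAL if s > 0.5 else NONESSENTIAL  # tie -> non-essential
        records.append(
            PredictionRecord(
                gene_id=str(gene),
                predicted_class=predicted,
                confidence=float(max(s, 1.0 - s)),
                score_for_essential=float(s),
            )
        )
    return records


def predictions_frame(records: list[PredictionRecord]) -> pd.DataFrame:
    """Tabular view of prediction records (gene_id, predicted_class,
    confidence, score_for_essential)."""
    return pd.DataFrame(
        [
            (r.gene_id, r.predicted_class, r.confidence, r.score_for_essential)
            for r in records
        ],
        columns=["gene_id", "predicted_class", "confidence", "score_for_essential"],
    ).set_index("gene_id")
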