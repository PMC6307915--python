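"""Feature-table I/O and pre-processing.

The central container is :class:`FeatureTable`: a genes x features matrix
with typed columns (numeric or integer-coded categorical) and NaN as the
missing marker.  Pre-processing mirrors the standard workflow for a
two-class knockout-phenotype table: drop features that are mostly missing,
impute the rest from training statistics, and repeatedly subsample the
majority class to build balanced training sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ESSENTIAL = "essential"
NONESSENTIAL = "non-essential"

NUMERIC = "numeric"
CATEGORICAL = "categorical-integer"

#: missing-value spellings accepted by the reader, in addition to empty fields
DEFAULT_NA_MARKERS = ("", "NA", "NaN", "nan")


@dataclass
class FeatureTable:
    """Genes x features matrix with per-feature kinds.

    Parameters
    ----------
    values
        DataFrame indexed by unique gene IDs; columns are feature names.
        Missing cells are ``NaN``.
    kinds
        Mapping feature name -> ``"numeric"`` or ``"categorical-integer"``.
        Integer-coded categorical features are carried as numeric codes
        throughout but are exempt from discretisation.
    """

    values: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene IDs: {list(dupes[:5])}")
        for f in self.values.columns:
            self.kinds.setdefault(f, NUMERIC)
        unknown = set(self.kinds) - set(self.values.columns)
        if unknown:
            raise ValueError(f"kinds refer to absent features: {sorted(unknown)}")
        bad = {f: k for f, k in self.kinds.items() if k not in (NUMERIC, CATEGORICAL)}
        if bad:
            raise ValueError(f"unknown feature kinds: {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return len(self.values)

    def missing_fraction(self) -> pd.Series:
        """Fraction of missing cells per feature."""
        return self.values.isna().mean()

    def subset_genes(self, gene_ids: Sequence[str]) -> "FeatureTable":
        return FeatureTable(self.values.loc[list(gene_ids)].copy(), dict(self.kinds))

    def subset_features(self, features: Sequence[str]) -> "FeatureTable":
        feats = list(features)
        return FeatureTable(self.values[feats].copy(), {f: self.kinds[f] for f in feats})

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), dict(self.kinds))

    def equals(self, other: "FeatureTable") -> bool:
        return self.values.equals(other.values) and self.kinds == other.kinds


def validate_labels(labels: pd.Series, table: FeatureTable | None = None) -> pd.Series:
    """Check a label vector: values in {essential, non-essential}; optionally
    that it covers exactly the table's gene IDs."""
    bad = set(labels.unique()) - {ESSENTIAL, NONESSENTIAL}
    if bad:
        raise ValueError(f"unknown class labels: {sorted(bad)}")
    if table is not None and (set(labels.index) != set(table.gene_ids)):
        raise ValueError("labels do not cover exactly the table's gene IDs")
    return labels


@dataclass
class ImputationModel:
    """Per-feature training statistic used to fill missing cells:
    the training mean for numeric features, the training mode (smallest on
    ties) for integer-coded categorical features."""

    fill_values: dict[str, float]


def _schema_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".schema.json")


def write_feature_table(
    table: FeatureTable,
    path: str | Path,
    labels: pd.Series | None = None,
    label_column: str = "essentiality",
    sep: str = "\t",
) -> None:
    """Write a table (and optional labels) as delimited text with a JSON
    sidecar recording feature kinds."""
    path = Path(path)
    out = table.values.copy()
    if labels is not None:
        validate_labels(labels, table)
        out[label_column] = labels.reindex(out.index)
    out.index.name = "gene_id"
    out.to_csv(path, sep=sep, na_rep="NA")
    _schema_path(path).write_text(json.dumps(table.kinds, indent=1))


def read_feature_table(
    source: str | Path,
    label_column: str | None = None,
    sep: str = "\t",
    na_markers: Iterable[str] = DEFAULT_NA_MARKERS,
    kinds: dict[str, str] | None = None,
) -> tuple[FeatureTable, pd.Series | None]:
    """Read a delimited feature table.

    The first column is the gene ID.  Feature kinds come from ``kinds``, a
    sidecar ``<file>.schema.json`` if present, or are inferred (columns whose
    observed values are all integral with few distinct levels are treated as
    integer-coded categorical).  Ragged rows and duplicate gene IDs are
    rejected.
    """
    path = Path(source)
    df = pd.read_csv(
        path,
        sep=sep,
        na_values=list(na_markers),
        keep_default_na=False,
        index_col=0,
        on_bad_lines="error",
    )
    if df.shape[0] == 0:
        raise ValueError("no data rows")
    _check_ragged(path, sep)
    df.index = df.index.astype(str)
    df.index.name = None
    if df.index.has_duplicates:
        raise ValueError("duplicate gene IDs in input")

    labels = None
    if label_column is not None:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not present")
        labels = df[label_column].astype(str)
        df = df.drop(columns=[label_column])

    df = df.astype(float)
    if kinds is None:
        schema = _schema_path(path)
        if schema.exists():
            kinds = {f: k for f, k in json.loads(schema.read_text()).items() if f in df.columns}
        else:
            kinds = {f: _infer_kind(df[f]) for f in df.columns}
    table = FeatureTable(df, dict(kinds))
    if labels is not None:
        validate_labels(labels, table)
    return table, labels


def _check_ragged(path: Path, sep: str) -> None:
    # pandas pads short rows silently; reject rows whose field count differs
    with open(path) as fh:
        n_fields = None
        for lineno, line in enumerate(fh, start=1):
            n = line.rstrip("\n").count(sep) + 1
            if n_fields is None:
                n_fields = n
            elif n != n_fields:
                raise ValueError(f"ragged row at line {lineno}: {n} fields, expected {n_fields}")


def _infer_kind(col: pd.Series, max_levels: int = 12) -> str:
    obs = col.dropna()
    if len(obs) == 0:
        return NUMERIC
    integral = np.allclose(obs, np.round(obs))
    if integral and obs.nunique() <= max_levels:
        return CATEGORICAL
    return NUMERIC


def drop_sparse_features(
    table: FeatureTable, max_missing_fraction: float = 0.30
) -> tuple[FeatureTable, list[str]]:
    """Remove features whose missing fraction exceeds the threshold.

    The default of 0.30 separates a heavily missing block (around 40% of
    genes lacking values, typical of interaction-network features compiled
    from sparse experimental evidence) from features missing in fewer than
    ~12% of genes, which are retained and later imputed.
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    frac = table.missing_fraction()
    dropped = [f for f in table.features if frac[f] > max_missing_fraction]
    kept = [f for f in table.features if f not in dropped]
    return table.subset_features(kept), dropped


def fit_impute(train: FeatureTable) -> ImputationModel:
    """Learn per-feature fill values from a training table.

    Numeric features use the training mean; integer-coded categorical
    features use the training mode (ties broken toward the smallest code),
    because a fractional mean is not a valid category code.
    """
    fill: dict[str, float] = {}
    for f in train.features:
        obs = train.values[f].dropna()
        if len(obs) == 0:
            raise ValueError(f"feature {f!r} is fully missing in training data")
        if train.kinds[f] == CATEGORICAL:
            fill[f] = float(obs.mode().min())
        else:
            fill[f] = float(obs.mean())
    return ImputationModel(fill)


def apply_impute(model: ImputationModel, table: FeatureTable) -> FeatureTable:
    """Fill missing cells with the training statistics; training fill values
    are reused unchanged on held-out tables."""
    missing = set(table.features) - set(model.fill_values)
    if missing:
        raise ValueError(f"no fill value for features: {sorted(missing)}")
    filled = table.values.fillna({f: model.fill_values[f] for f in table.features})
    return FeatureTable(filled, dict(table.kinds))


def balanced_subsets(
    table: FeatureTable,
    labels: pd.Series,
    n_subsets: int = 10,
    seed: int | None = None,
) -> list[list[str]]:
    """Build class-balanced gene subsets by majority-class undersampling.

    Each subset contains every minority-class gene plus an equal-sized
    without-replacement random sample of the majority class; repeating the
    draw yields training sets that differ only in their majority-class
    members.
    """
    if n_subsets < 1:
        raise ValueError("n_subsets must be >= 1")
    validate_labels(labels, table)
    by_class = {c: labels.index[labels == c].tolist() for c in (ESSENTIAL, NONESSENTIAL)}
    if min(len(v) for v in by_class.values()) == 0:
        raise ValueError("both classes must be non-empty")
    minority, majority = sorted(by_class, key=lambda c: len(by_class[c]))
    rng = np.random.default_rng(seed)
    subsets = []
    for _ in range(n_subsets):
        sample = rng.choice(by_class[majority], size=len(by_class[minority]), replace=False)
        subsets.append(list(by_class[minority]) + [str(g) for g in sample])
    return subsets


def choose_representative_subset(cv_accuracies: Sequence[float]) -> int:
    """Index of the accuracy closest to the mean over subsets (ties -> lowest
    index).  Picking the subset nearest the mean avoids reporting an
    optimistically chosen training set."""
    accs = np.asarray(list(cv_accuracies), dtype=float)
    if accs.size == 0:
        raise ValueError("empty accuracy list")
    return int(np.argmin(np.abs(accs - accs.mean())))
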