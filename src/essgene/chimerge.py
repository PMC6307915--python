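"""Supervised bottom-up interval merging (ChiMerge) of numeric features.

Each numeric feature starts with one interval per distinct value.  The
adjacent pair whose 2 x C contingency table against the class labels has
the smallest Pearson chi-squared statistic is merged repeatedly, as long
as that minimum does not exceed the critical value at the configured
significance level.  Surviving interval boundaries become cutpoints, and
values are replaced by interval codes.  Merging stops exactly when every
adjacent pair of intervals is distinguishable from class-independence at
the chosen significance.

Conventions (all deterministic):

* degrees of freedom = (2 - 1) x (classes - 1); for binary labels the
  critical value at significance 0.95 is chi2(1).ppf(0.95) ~ 3.841;
* contingency cells with expected count 0 contribute 0 to the statistic;
* ties for the minimal chi-squared merge the leftmost pair;
* a value equal to a cutpoint falls in the upper interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tableio import CATEGORICAL, NUMERIC, FeatureTable, validate_labels


@dataclass
class DiscretisationScheme:
    """Fitted cutpoints for one feature.

    k cutpoints define k + 1 interval codes 0..k; ``apply`` maps a value to
    the number of cutpoints <= it (so a value equal to a cutpoint takes the
    upper interval).
    """

    feature: str
    cutpoints: np.ndarray
    significance: float = 0.95
    chi2_threshold: float = float(stats.chi2.ppf(0.95, df=1))

    def __post_init__(self) -> None:
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        if self.cutpoints.size and not np.all(np.diff(self.cutpoints) > 0):
            raise ValueError("cutpoints must be strictly increasing")
        if self.chi2_threshold <= 0:
            raise ValueError("chi2_threshold must be positive")

    @property
    def n_codes(self) -> int:
        return self.cutpoints.size + 1

    def apply(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return np.searchsorted(self.cutpoints, v, side="right").astype(int)


def adjacent_chi_squared(counts_a, counts_b) -> float:
    """Pearson chi-squared of two adjacent intervals' per-class counts.

    ``counts_a`` and ``counts_b`` are per-class counts for the two
    intervals (same class order).  Cells whose expected count is 0
    contribute 0 — the classic ChiMerge convention, which arises when a
    class is absent from both intervals.
    """
    obs = np.asarray([counts_a, counts_b], dtype=float)
    if np.any(obs < 0):
        raise ValueError("negative counts")
    if np.any(obs.sum(axis=1) < 1):
        raise ValueError("each interval needs total count >= 1")
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / obs.sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (obs - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def _initial_intervals(
    values: np.ndarray, y: np.ndarray, n_classes: int, max_initial_bins: int | None
) -> tuple[np.ndarray, np.ndarray]:
    """Distinct sorted values with per-class counts; optionally pre-binned
    to quantile bins when the distinct count exceeds the cap."""
    uniq, inv = np.unique(values, return_inverse=True)
    counts = np.zeros((uniq.size, n_classes), dtype=np.int64)
    np.add.at(counts, (inv, y), 1)
    if max_initial_bins is not None and uniq.size > max_initial_bins:
        # quantile pre-binning: group distinct values into ~equal-mass bins
        edges = np.quantile(values, np.linspace(0, 1, max_initial_bins + 1)[1:-1])
        bin_of = np.searchsorted(edges, uniq, side="right")
        reps = np.full(bin_of.max() + 1, -np.inf)
        agg = np.zeros((bin_of.max() + 1, n_classes), dtype=np.int64)
        np.maximum.at(reps, bin_of, uniq)
        np.add.at(agg, bin_of, counts)
        keep = agg.sum(axis=1) > 0
        return reps[keep], agg[keep]
    return uniq, counts


def fit_scheme(
    values,
    labels,
    significance: float = 0.95,
    max_initial_bins: int | None = 256,
) -> DiscretisationScheme:
    """Fit a ChiMerge discretisation of one numeric feature against binary
    class labels.

    ``max_initial_bins`` caps the number of initial single-value intervals
    by quantile pre-binning (the exact distinct-value initialisation is
    used below the cap); pass ``None`` for the uncapped algorithm.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one observed value")
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite values in feature")
    classes, y = np.unique(np.asarray(labels), return_inverse=True)
    if classes.size > 2:
        raise ValueError("ChiMerge here supports binary labels only")
    df = max(classes.size - 1, 1)
    threshold = float(stats.chi2.ppf(significance, df=df))

    uppers, counts = _initial_intervals(v, y, classes.size, max_initial_bins)
    uppers = list(uppers)
    counts = [row for row in counts]

    chis = [adjacent_chi_squared(counts[i], counts[i + 1]) for i in range(len(counts) - 1)]
    while chis:
        i = min(range(len(chis)), key=chis.__getitem__)  # leftmost minimum: tie rule
        if chis[i] > threshold:
            break
        counts[i] = counts[i] + counts[i + 1]
        del counts[i + 1]
        del uppers[i]  # interval i absorbs i+1; keep the upper boundary of i+1
        del chis[i]
        # only the pairs adjacent to the merged interval change
        if i > 0:
            chis[i - 1] = adjacent_chi_squared(counts[i - 1], counts[i])
        if i < len(chis):
            chis[i] = adjacent_chi_squared(counts[i], counts[i + 1])

    # cutpoints: midpoints between the upper bound of one interval and the
    # smallest observed value above it — approximated by midpoints between
    # adjacent surviving representative values
    cuts = [(uppers[i] + _lowest_above(v, uppers[i])) / 2.0 for i in range(len(counts) - 1)]
    return DiscretisationScheme(
        feature="", cutpoints=np.asarray(cuts), significance=significance, chi2_threshold=threshold
    )


def _lowest_above(values: np.ndarray, bound: float) -> float:
    above = values[values > bound]
    return float(above.min())


def discretise_table(
    table: FeatureTable,
    labels: pd.Series,
    significance: float = 0.95,
    max_initial_bins: int | None = 256,
) -> tuple[FeatureTable, dict[str, DiscretisationScheme]]:
    """Discretise every numeric feature of an imputed table; categorical
    integer codes pass through unchanged.

    Fitted schemes are returned so held-out tables can be coded with
    :func:`apply_schemes` without refitting (test data must never inform
    the cutpoints).
    """
    if table.values.isna().any().any():
        raise ValueError("table contains missing cells; impute before discretising")
    validate_labels(labels, table)
    y = labels.reindex(table.values.index)
    out = table.values.copy()
    schemes: dict[str, DiscretisationScheme] = {}
    for f in table.features:
        if table.kinds[f] != NUMERIC:
            continue
        s = fit_scheme(out[f].to_numpy(), y.to_numpy(), significance, max_initial_bins)
        s.feature = f
        schemes[f] = s
        out[f] = s.apply(out[f].to_numpy())
    kinds = {f: (CATEGORICAL if f in schemes else table.kinds[f]) for f in table.features}
    return FeatureTable(out, kinds), schemes


def apply_schemes(
    table: FeatureTable, schemes: dict[str, DiscretisationScheme]
) -> FeatureTable:
    """Code a (held-out) table with already-fitted schemes; out-of-range
    values clamp to the first or last interval by construction."""
    if table.values.isna().any().any():
        raise ValueError("table contains missing cells; impute before discretising")
    out = table.values.copy()
    for f, s in schemes.items():
        if f not in out.columns:
            raise ValueError(f"scheme for absent feature {f!r}")
        out[f] = s.apply(out[f].to_numpy())
    kinds = {f: (CATEGORICAL if f in schemes else table.kinds[f]) for f in table.features}
    return FeatureTable(out, kinds)
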