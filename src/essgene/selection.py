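"""Feature ranking by information gain and GA wrapper subset search.

Information gain scores each discretised feature by the reduction in
class entropy from conditioning on it; features with zero gain carry no
marginal signal and are excluded from the retained ranking.

The genetic-algorithm wrapper searches binary chromosomes (bit j = 1
means feature j is included) whose fitness is the mean k-fold
cross-validated accuracy of a chosen classifier on the candidate subset.
Defaults mirror the classic Weka GeneticSearch configuration: population
20, single-point crossover at 0.6, per-bit mutation at 0.033, roulette
selection, 1 elite, 20 generations.  The reported fitness of the winning
subset is optimistically biased (it was selected for it); honest
generalisation estimates require a held-out set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, cross_val_score

from .tableio import FeatureTable, validate_labels


def _entropy(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a count vector; 0*log0 = 0."""
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def information_gain(codes, labels) -> float:
    """IG = H(class) - H(class | feature), base-2 entropies over empirical
    frequencies of a discrete feature."""
    codes = np.asarray(codes)
    y = np.asarray(labels)
    if codes.size == 0:
        raise ValueError("empty input")
    if codes.size != y.size:
        raise ValueError("codes and labels must align")
    _, yi = np.unique(y, return_inverse=True)
    _, ci = np.unique(codes, return_inverse=True)
    joint = np.zeros((ci.max() + 1, yi.max() + 1))
    np.add.at(joint, (ci, yi), 1)
    h_class = _entropy(joint.sum(axis=0))
    n = joint.sum()
    h_cond = sum(
        (row.sum() / n) * _entropy(row) for row in joint if row.sum() > 0
    )
    return max(h_class - h_cond, 0.0)


@dataclass
class FeatureRanking:
    """All feature scores plus the retained (gain > 0) ranking."""

    scores: dict[str, float]
    retained: list[tuple[str, float]]  # descending gain, gain > 0 only


def rank_by_information_gain(disc_table: FeatureTable, labels: pd.Series) -> FeatureRanking:
    """Score every feature of a discretised table; retain those with
    positive gain, ranked descending (ties broken by feature name for
    column-order invariance)."""
    validate_labels(labels, disc_table)
    y = labels.reindex(disc_table.values.index).to_numpy()
    scores = {
        f: information_gain(disc_table.values[f].to_numpy(), y) for f in disc_table.features
    }
    retained = sorted(
        ((f, g) for f, g in scores.items() if g > 0.0), key=lambda fg: (-fg[1], fg[0])
    )
    return FeatureRanking(scores, retained)


@dataclass
class GAParams:
    """Wrapper-search knobs; defaults are the classic GeneticSearch
    settings with the generation count at 20."""

    population_size: int = 20
    crossover_prob: float = 0.6
    mutation_prob: float = 0.033
    generations: int = 20
    elitism: int = 1
    fitness_folds: int = 10
    seed: int = 0

    def validate(self) -> None:
        for name in ("crossover_prob", "mutation_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if not 0 <= self.elitism < self.population_size:
            raise ValueError("elitism must be in [0, population_size)")
        if self.fitness_folds < 2:
            raise ValueError("fitness_folds must be >= 2")


@dataclass
class GAResult:
    selected: list[str]
    best_fitness: float
    trace: list[float] = field(default_factory=list)  # best-so-far per generation


def _subset_fitness(
    X: np.ndarray, y: np.ndarray, mask: np.ndarray, model_spec, folds: int, seed: int
) -> float:
    if not mask.any():
        # empty subset: fall back to the majority-class rate rather than crash
        _, counts = np.unique(y, return_counts=True)
        return float(counts.max() / counts.sum())
    from .model import build_estimator  # deferred: avoid import cycle

    est = build_estimator(model_spec)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed % (2**31))
    return float(cross_val_score(est, X[:, mask], y, cv=cv, scoring="accuracy").mean())


def ga_feature_search(
    table: FeatureTable,
    labels: pd.Series,
    params: GAParams | None = None,
    model_spec=None,
) -> GAResult:
    """Search feature subsets with a seeded genetic algorithm.

    Returns the best chromosome ever seen (ties resolved toward the
    smaller subset, then the lexicographically lowest chromosome) and the
    non-decreasing best-so-far fitness trace, one entry per generation.
    """
    from .model import ModelSpec  # deferred: avoid import cycle

    params = params or GAParams()
    params.validate()
    if model_spec is None:
        model_spec = ModelSpec("naive_bayes")
    validate_labels(labels, table)
    features = table.features
    if not features:
        raise ValueError("table has no features")
    X = table.values.to_numpy(dtype=float)
    y = labels.reindex(table.values.index).to_numpy()
    rng = np.random.default_rng(params.seed)
    n = len(features)

    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = mask.tobytes()
        if key not in cache:
            cache[key] = _subset_fitness(X, y, mask, model_spec, params.fitness_folds, params.seed)
        return cache[key]

    def better(a: tuple[float, np.ndarray], b: tuple[float, np.ndarray]) -> bool:
        """True if a beats b: higher fitness, then fewer features, then
        lexicographically lower chromosome."""
        fa, ma = a
        fb, mb = b
        if fa != fb:
            return fa > fb
        if ma.sum() != mb.sum():
            return ma.sum() < mb.sum()
        return tuple(ma) < tuple(mb)

    pop = rng.random((params.population_size, n)) < 0.5
    fits = np.array([fitness(m) for m in pop])
    best = (float(fits[0]), pop[0].copy())
    for f, m in zip(fits, pop):
        if better((float(f), m), best):
            best = (float(f), m.copy())

    trace: list[float] = []
    for _ in range(params.generations):
        order = np.argsort(-fits, kind="stable")
        elite = [pop[i].copy() for i in order[: params.elitism]]
        # roulette selection on positive-shifted fitness
        w = fits - fits.min() + 1e-9
        p = w / w.sum()
        children = list(elite)
        while len(children) < params.population_size:
            i, j = rng.choice(params.population_size, size=2, p=p)
            a, b = pop[i].copy(), pop[j].copy()
            if n > 1 and rng.random() < params.crossover_prob:
                cut = int(rng.integers(1, n))
                a[cut:], b[cut:] = b[cut:].copy(), a[cut:].copy()
            for child in (a, b):
                flip = rng.random(n) < params.mutation_prob
                child[flip] = ~child[flip]
                if len(children) < params.population_size:
                    children.append(child)
        pop = np.array(children)
        fits = np.array([fitness(m) for m in pop])
        for f, m in zip(fits, pop):
            if better((float(f), m), best):
                best = (float(f), m.copy())
        trace.append(best[0])

    selected = [f for f, bit in zip(features, best[1]) if bit]
    return GAResult(selected=selected, best_fitness=best[0], trace=trace)
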