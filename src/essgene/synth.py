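"""Synthetic labelled feature tables and interaction graphs.

The generator emulates the statistical structure of a mouse knockout
feature table: a minority essential class against a larger viable class;
heavy-tailed interaction-degree-like features; log-normal expression-like
features; amino-acid-composition fractions in [0, 1]; integer-coded
categories (protein type, subcellular localisation); per-feature
missingness including one block missing for ~40% of genes; and
configurable class-separating effect sizes.  It makes every downstream
stage testable without touching any external database.

Class shifts are applied on the latent scale (log for positive families,
logit for fractions) so that values stay in their natural range: an effect
size d moves the essential-class latent mean by +d/2 and the viable-class
mean by -d/2, in units of the latent standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .tableio import CATEGORICAL, ESSENTIAL, NONESSENTIAL, NUMERIC, FeatureTable

HEAVY_TAILED = "heavy-tailed-positive"
LOG_NORMAL = "log-normal-positive"
FRACTION = "fraction-in-[0,1]"
CATEGORY = "integer-category"

_FAMILIES = (HEAVY_TAILED, LOG_NORMAL, FRACTION, CATEGORY)


@dataclass
class FeatureBlock:
    """A group of features sharing a distribution family and effect size."""

    prefix: str
    n_features: int
    family: str
    effect_size: float = 0.0
    n_levels: int = 4  # categories only
    missing_rate: float = 0.0

    def feature_names(self) -> list[str]:
        return [f"{self.prefix}_{i:02d}" for i in range(self.n_features)]


def default_blocks() -> list[FeatureBlock]:
    """102 features mirroring the structural roles in a real essentiality
    table: interaction-network degrees (one block ~40% missing), expression
    levels, composition fractions, coded categories, and uninformative
    sequence summaries."""
    return [
        FeatureBlock("ppi_sparse", 10, HEAVY_TAILED, effect_size=0.9, missing_rate=0.40),
        FeatureBlock("ppi", 12, HEAVY_TAILED, effect_size=0.9, missing_rate=0.05),
        FeatureBlock("expr", 20, LOG_NORMAL, effect_size=0.5, missing_rate=0.08),
        FeatureBlock("aa_frac", 20, FRACTION, effect_size=0.25, missing_rate=0.02),
        FeatureBlock("subcell_loc", 10, CATEGORY, effect_size=0.4, n_levels=5),
        FeatureBlock("protein_type", 6, CATEGORY, effect_size=0.4, n_levels=4),
        FeatureBlock("seq", 24, LOG_NORMAL, effect_size=0.0, missing_rate=0.02),
    ]


@dataclass
class SyntheticSpec:
    """Recipe for one labelled table; defaults follow the real study's
    class sizes (1307 essential vs 3459 non-essential) and a 102-feature
    layout."""

    n_essential: int = 1307
    n_nonessential: int = 3459
    blocks: list[FeatureBlock] = field(default_factory=default_blocks)
    seed: int = 0

    def validate(self) -> None:
        if self.n_essential < 1:
            raise ValueError("n_essential must be >= 1")
        if self.n_nonessential < 1:
            raise ValueError("n_nonessential must be >= 1")
        for b in self.blocks:
            if b.family not in _FAMILIES:
                raise ValueError(f"block {b.prefix!r}: unknown family {b.family!r}")
            if b.n_features < 1:
                raise ValueError(f"block {b.prefix!r}: n_features must be >= 1")
            if not np.isfinite(b.effect_size):
                raise ValueError(f"block {b.prefix!r}: effect_size must be finite")
            if not 0.0 <= b.missing_rate <= 1.0:
                raise ValueError(f"block {b.prefix!r}: missing_rate must be in [0, 1]")
            if b.family == CATEGORY and b.n_levels < 2:
                raise ValueError(f"block {b.prefix!r}: n_levels must be >= 2")

    @property
    def n_features(self) -> int:
        return sum(b.n_features for b in self.blocks)

    def missing_rates(self) -> dict[str, float]:
        return {f: b.missing_rate for b in self.blocks for f in b.feature_names()}


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests: which features actually separate
    the classes, and the label of every gene."""

    informative_features: set[str]
    class_labels: pd.Series


def _block_rng(seed: int, block_index: int) -> np.random.Generator:
    # sub-seed keyed on (seed, index): adding a block never perturbs earlier ones
    return np.random.default_rng(np.random.SeedSequence((seed, block_index)))


def _sample_block(block: FeatureBlock, y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    n = y.size
    shift = np.where(y, block.effect_size / 2.0, -block.effect_size / 2.0)
    cols = np.empty((n, block.n_features))
    for j in range(block.n_features):
        if block.family == HEAVY_TAILED:
            # wide log-normal: degree-like, right-skewed, positive
            cols[:, j] = np.exp(rng.normal(loc=shift, scale=1.0) * 1.2)
        elif block.family == LOG_NORMAL:
            cols[:, j] = np.exp(1.0 + 0.5 * rng.normal(loc=shift, scale=1.0))
        elif block.family == FRACTION:
            z = rng.normal(loc=shift, scale=1.0)
            cols[:, j] = 1.0 / (1.0 + np.exp(-z))
        else:  # CATEGORY: class-tilted level probabilities via softmax
            k = block.n_levels
            levels = np.arange(k)
            tilt = (levels / (k - 1) - 0.5)  # in [-0.5, 0.5]
            for cls, d in ((0, -block.effect_size / 2), (1, block.effect_size / 2)):
                idx = np.flatnonzero(y == cls)
                p = np.exp(2.0 * d * tilt)
                p /= p.sum()
                cols[idx, j] = rng.choice(levels, size=idx.size, p=p)
    return cols


def generate_labelled_table(
    spec: SyntheticSpec,
) -> tuple[FeatureTable, pd.Series, SyntheticTruth]:
    """Draw one labelled table (without missingness; see
    :func:`inject_missingness`).

    Returns the table, the per-gene label vector, and the ground truth
    (informative feature set) for recovery tests.  Identical spec and seed
    give identical output.
    """
    spec.validate()
    n = spec.n_essential + spec.n_nonessential
    gene_ids = [f"G{i:05d}" for i in range(n)]
    y = np.zeros(n, dtype=int)
    y[: spec.n_essential] = 1  # essential first; row order is not informative downstream

    frames, kinds = [], {}
    for i, block in enumerate(spec.blocks):
        rng = _block_rng(spec.seed, i)
        cols = _sample_block(block, y, rng)
        names = block.feature_names()
        frames.append(pd.DataFrame(cols, index=gene_ids, columns=names))
        kind = CATEGORICAL if block.family == CATEGORY else NUMERIC
        kinds.update({f: kind for f in names})
    values = pd.concat(frames, axis=1)

    labels = pd.Series(np.where(y == 1, ESSENTIAL, NONESSENTIAL), index=gene_ids)
    informative = {
        f for b in spec.blocks if b.effect_size != 0.0 for f in b.feature_names()
    }
    return FeatureTable(values, kinds), labels, SyntheticTruth(informative, labels)


def inject_missingness(
    table: FeatureTable, rates: dict[str, float], seed: int | None = None
) -> FeatureTable:
    """Blank each cell of feature f independently with probability rates[f];
    features absent from ``rates`` default to 0."""
    for f, r in rates.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"missing rate for {f!r} must be in [0, 1], got {r}")
    out = table.values.copy()
    rng = np.random.default_rng(seed)
    for f in table.features:
        r = rates.get(f, 0.0)
        if r > 0.0:
            mask = rng.random(len(out)) < r
            out.loc[mask, f] = np.nan
    return FeatureTable(out, dict(table.kinds))


def generate_table(spec: SyntheticSpec) -> tuple[FeatureTable, pd.Series, SyntheticTruth]:
    """Labelled table with the spec's per-block missingness applied."""
    table, labels, truth = generate_labelled_table(spec)
    rates = spec.missing_rates()
    if any(r > 0 for r in rates.values()):
        table = inject_missingness(table, rates, seed=np.random.SeedSequence((spec.seed, 10_007)))
    return table, labels, truth


def generate_interaction_graph(
    n_nodes: int, edges_per_new_node: int = 2, seed: int | None = None
) -> nx.Graph:
    """Preferential-attachment graph with a scale-free degree distribution.

    Starts from a complete seed core of ``edges_per_new_node + 1`` nodes;
    each subsequent node attaches to ``edges_per_new_node`` distinct
    existing nodes with probability proportional to degree, so the final
    edge count is C(m+1, 2) + m * (n - m - 1).  Edges carry a confidence
    score in [0.4, 1] and an experimental-evidence flag, mimicking a
    filtered interaction database export.
    """
    m = edges_per_new_node
    if m < 1:
        raise ValueError("edges_per_new_node must be >= 1")
    if n_nodes <= m:
        raise ValueError("n_nodes must exceed edges_per_new_node")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    core = min(m + 1, n_nodes)
    g.add_nodes_from(range(core))
    repeated: list[int] = []  # node appears once per incident edge
    for a in range(core):
        for b in range(a + 1, core):
            g.add_edge(a, b)
            repeated += [a, b]
    for new in range(core, n_nodes):
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(repeated[rng.integers(len(repeated))])
        for t in targets:
            g.add_edge(new, t)
            repeated += [new, t]
    for a, b in g.edges:
        g.edges[a, b]["confidence"] = round(float(rng.uniform(0.4, 1.0)), 3)
        g.edges[a, b]["experimental"] = bool(rng.random() < 0.8)
    return nx.relabel_nodes(g, {i: f"G{i:05d}" for i in g.nodes})
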