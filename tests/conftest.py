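import numpy as np
import pandas as pd
import pytest

from essgene import synth, tableio
from essgene.tableio import ESSENTIAL, NONESSENTIAL, FeatureTable


def make_labels(classes, ids=None):
    ids = ids or [f"g{i}" for i in range(len(classes))]
    return pd.Series(list(classes), index=ids)


@pytest.fixture
def toy_table():
    """5 genes x 4 features with one mostly-missing column."""
    values = pd.DataFrame(
        {
            "a": [1.0, 2.0, np.nan, 4.0, 5.0],
            "b": [1.0, 2.0, 3.0, 4.0, 5.0],
            "sparse": [np.nan, np.nan, np.nan, 1.0, 2.0],
            "cat": [0.0, 1.0, 1.0, 0.0, 1.0],
        },
        index=[f"g{i}" for i in range(5)],
    )
    return FeatureTable(values, {"cat": tableio.CATEGORICAL})


@pytest.fixture
def toy_labels(toy_table):
    return make_labels(
        [ESSENTIAL, ESSENTIAL, NONESSENTIAL, NONESSENTIAL, NONESSENTIAL],
        ids=toy_table.gene_ids,
    )


@pytest.fixture(scope="session")
def small_synth():
    """A small synthetic dataset shared by slower tests."""
    spec = synth.SyntheticSpec(n_essential=80, n_nonessential=160, seed=11)
    table, labels, truth = synth.generate_table(spec)
    return spec, table, labels, truth


def separable_table(n_per_class=100, seed=0, n_features=4, shift=6.0):
    """A trivially separable two-class table (wide class gap)."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    y = np.array([1] * n_per_class + [0] * n_per_class)
    cols = {
        f"f{j}": rng.normal(size=n) + shift * y for j in range(n_features)
    }
    ids = [f"g{i}" for i in range(n)]
    table = FeatureTable(pd.DataFrame(cols, index=ids))
    labels = pd.Series(np.where(y == 1, ESSENTIAL, NONESSENTIAL), index=ids)
    return table, labels
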