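"""Synthetic generator: determinism, family ranges, effect sizes,
missingness and graph structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from essgene import synth
from essgene.model import ModelSpec
from essgene.evaluate import cross_validate
from essgene.tableio import CATEGORICAL, ESSENTIAL


def test_identical_spec_and_seed_give_identical_tables():
    spec = synth.SyntheticSpec(n_essential=40, n_nonessential=60, seed=5)
    t1, y1, _ = synth.generate_table(spec)
    t2, y2, _ = synth.generate_table(synth.SyntheticSpec(n_essential=40, n_nonessential=60, seed=5))
    assert t1.values.to_csv() == t2.values.to_csv()
    assert (y1 == y2).all()


def test_default_spec_matches_study_class_sizes():
    spec = synth.SyntheticSpec()
    table, labels, _ = synth.generate_labelled_table(spec)
    assert table.n_genes == 4766
    assert (labels == ESSENTIAL).sum() == 1307
    assert len(table.features) == 102


def test_family_ranges_and_category_levels(small_synth):
    _, table, _, _ = small_synth
    frac = table.values[[f for f in table.features if f.startswith("aa_frac")]]
    assert ((frac.dropna() >= 0) & (frac.dropna() <= 1)).all().all()
    cat = table.values["subcell_loc_00"].dropna()
    assert set(cat.unique()) <= set(range(5))
    assert table.kinds["subcell_loc_00"] == CATEGORICAL
    pos = table.values[[f for f in table.features if f.startswith("ppi")]].dropna()
    assert (pos > 0).all().all()


def test_informative_features_shift_in_configured_direction():
    spec = synth.SyntheticSpec(n_essential=400, n_nonessential=400, seed=2)
    table, labels, truth = synth.generate_labelled_table(spec)
    ess = labels == ESSENTIAL
    for f in ("ppi_00", "expr_00", "aa_frac_00"):
        assert f in truth.informative_features
        assert table.values.loc[ess, f].mean() > table.values.loc[~ess, f].mean()


def test_null_features_pass_location_test_at_nominal_rate():
    # non-informative features should reject a two-sample location test at
    # alpha=0.01 roughly 1% of the time
    rejections, total = 0, 0
    for seed in range(3):
        spec = synth.SyntheticSpec(n_essential=150, n_nonessential=150, seed=seed)
        table, labels, truth = synth.generate_labelled_table(spec)
        ess = labels == ESSENTIAL
        null_features = [f for f in table.features if f not in truth.informative_features]
        for f in null_features:
            p = stats.ttest_ind(table.values.loc[ess, f], table.values.loc[~ess, f]).pvalue
            rejections += p < 0.01
            total += 1
    assert total == 72
    assert rejections <= 4  # ~1% nominal; allow binomial slack


def test_single_feature_effect_reaches_normal_overlap_accuracy():
    # one log-normal feature with latent effect d=3: the latent classes are
    # unit-variance normals 3 apart, so Bayes accuracy = Phi(1.5) ~ 0.933;
    # a tree-based single-feature classifier is invariant to the monotone
    # exp transform and should approach it
    spec = synth.SyntheticSpec(
        n_essential=1000,
        n_nonessential=1000,
        blocks=[synth.FeatureBlock("x", 1, synth.LOG_NORMAL, effect_size=3.0)],
        seed=9,
    )
    table, labels, _ = synth.generate_labelled_table(spec)
    bayes = stats.norm.cdf(1.5)
    res = cross_validate(table, labels, ModelSpec("decision_tree"), k=10, seed=9)
    assert abs(res.pooled_accuracy - bayes) <= 0.03


def test_zero_effect_gives_no_signal():
    spec = synth.SyntheticSpec(
        n_essential=100,
        n_nonessential=100,
        blocks=[synth.FeatureBlock("n", 4, synth.LOG_NORMAL, effect_size=0.0)],
        seed=3,
    )
    table, labels, truth = synth.generate_labelled_table(spec)
    assert truth.informative_features == set()
    res = cross_validate(table, labels, ModelSpec("naive_bayes"), k=5, seed=3, discretise=False)
    assert abs(res.pooled_accuracy - 0.5) <= 0.12  # majority rate on balanced data


@pytest.mark.parametrize(
    "field,value", [("n_essential", 0), ("n_nonessential", -1)]
)
def test_invalid_spec_rejected_naming_field(field, value):
    spec = synth.SyntheticSpec(**{field: value})
    with pytest.raises(ValueError, match=field):
        synth.generate_labelled_table(spec)


def test_invalid_block_rejected():
    spec = synth.SyntheticSpec(blocks=[synth.FeatureBlock("b", 1, "weird-family")])
    with pytest.raises(ValueError, match="family"):
        synth.generate_labelled_table(spec)


def test_inject_missingness_identity_at_zero(small_synth):
    _, table, _, _ = small_synth
    out = synth.inject_missingness(table, {}, seed=0)
    assert out.values.equals(table.values)


def test_inject_missingness_hits_target_rate():
    spec = synth.SyntheticSpec(
        n_essential=500,
        n_nonessential=500,
        blocks=[synth.FeatureBlock("b", 10, synth.LOG_NORMAL)],
        seed=1,
    )
    table, _, _ = synth.generate_labelled_table(spec)
    rates = {f: 0.40 for f in table.features}
    out = synth.inject_missingness(table, rates, seed=1)
    assert abs(out.values.isna().mean().mean() - 0.40) <= 0.05


def test_inject_missingness_binomial_interval():
    spec = synth.SyntheticSpec(
        n_essential=500,
        n_nonessential=500,
        blocks=[synth.FeatureBlock("b", 1, synth.LOG_NORMAL)],
        seed=4,
    )
    table, _, _ = synth.generate_labelled_table(spec)
    out = synth.inject_missingness(table, {"b_00": 0.12}, seed=4)
    n_missing = out.values["b_00"].isna().sum()
    lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.12)
    assert lo <= n_missing <= hi


def test_inject_missingness_rejects_bad_rate(small_synth):
    _, table, _, _ = small_synth
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        synth.inject_missingness(table, {table.features[0]: 1.5})


def test_graph_forced_small_structures():
    g = synth.generate_interaction_graph(3, 1, seed=0)
    assert g.number_of_edges() == 2  # a tree on 3 nodes
    g = synth.generate_interaction_graph(100, 2, seed=0)
    assert g.number_of_edges() == 3 + 2 * 97
    assert all(a != b for a, b in g.edges)
    assert sorted(synth.generate_interaction_graph(50, 2, seed=7).edges) == sorted(
        synth.generate_interaction_graph(50, 2, seed=7).edges
    )


def test_graph_rejects_bad_sizes():
    with pytest.raises(ValueError):
        synth.generate_interaction_graph(2, 2)
    with pytest.raises(ValueError):
        synth.generate_interaction_graph(10, 0)
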