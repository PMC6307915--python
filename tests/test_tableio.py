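"""Table I/O, sparse-feature dropping, imputation, balanced subsampling."""

import numpy as np
import pandas as pd
import pytest

from essgene import synth, tableio
from essgene.tableio import ESSENTIAL, NONESSENTIAL, FeatureTable


class TestReadWrite:
    def test_round_trip_preserves_table_and_labels(self, tmp_path, small_synth):
        _, table, labels, _ = small_synth
        path = tmp_path / "t.tsv"
        tableio.write_feature_table(table, path, labels=labels)
        back, back_labels = tableio.read_feature_table(path, label_column="essentiality")
        pd.testing.assert_frame_equal(back.values, table.values)
        assert back.kinds == table.kinds
        assert (back_labels == labels).all()

    def test_header_only_file_rejected(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("gene_id\tf1\tf2\n")
        with pytest.raises(ValueError, match="no data rows"):
            tableio.read_feature_table(p)

    def test_102_feature_table_parses_to_102_features(self, tmp_path):
        table, labels, _ = synth.generate_labelled_table(
            synth.SyntheticSpec(n_essential=5, n_nonessential=10)
        )
        path = tmp_path / "t.tsv"
        tableio.write_feature_table(table, path)
        back, _ = tableio.read_feature_table(path)
        assert len(back.features) == 102

    def test_duplicate_gene_ids_rejected(self, tmp_path):
        p = tmp_path / "dup.tsv"
        p.write_text("gene_id\tf1\ng1\t1\ng1\t2\n")
        with pytest.raises(ValueError, match="duplicate"):
            tableio.read_feature_table(p)

    def test_ragged_rows_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "ragged.tsv"
        p.write_text("gene_id\tf1\tf2\ng1\t1\t2\ng2\t3\n")
        with pytest.raises(ValueError, match="line 3"):
            tableio.read_feature_table(p)

    def test_na_marker_dialects_recognised(self, tmp_path):
        p = tmp_path / "na.tsv"
        p.write_text("gene_id\tf1\tf2\tf3\ng1\tNA\t\tNaN\ng2\t1\t2\t3\n")
        table, _ = tableio.read_feature_table(p)
        assert table.values.loc["g1"].isna().all()


class TestDropSparse:
    def test_vacuous_threshold_drops_nothing(self, toy_table):
        out, dropped = tableio.drop_sparse_features(toy_table, 1.0)
        assert dropped == []
        assert out.features == toy_table.features

    def test_majority_missing_column_dropped(self, toy_table):
        out, dropped = tableio.drop_sparse_features(toy_table, 0.5)
        assert dropped == ["sparse"]  # missing 3/5 > 0.5
        assert "sparse" not in out.features

    def test_forty_percent_block_dropped_emulating_102_to_92(self):
        table, _, _ = synth.generate_table(synth.SyntheticSpec(n_essential=400, n_nonessential=600, seed=0))
        out, dropped = tableio.drop_sparse_features(table, 0.30)
        assert sorted(dropped) == sorted(f"ppi_sparse_{i:02d}" for i in range(10))
        assert len(out.features) == 92

    def test_bad_threshold_rejected(self, toy_table):
        with pytest.raises(ValueError):
            tableio.drop_sparse_features(toy_table, 1.2)


class TestImpute:
    def test_no_missing_is_identity(self, toy_table):
        t = toy_table.subset_features(["b", "cat"])
        model = tableio.fit_impute(t)
        assert tableio.apply_impute(model, t).values.equals(t.values)

    def test_numeric_mean_fill(self):
        t = FeatureTable(pd.DataFrame({"x": [1.0, 2.0, np.nan]}, index=list("abc")))
        model = tableio.fit_impute(t)
        out = tableio.apply_impute(model, t)
        assert out.values.loc["c", "x"] == 1.5
        assert out.values["x"].mean() == 1.5

    def test_categorical_fill_uses_training_mode(self):
        t = FeatureTable(
            pd.DataFrame({"c": [1.0, 1.0, 2.0, np.nan]}, index=list("abcd")),
            {"c": tableio.CATEGORICAL},
        )
        out = tableio.apply_impute(tableio.fit_impute(t), t)
        assert out.values.loc["d", "c"] == 1.0

    def test_training_mean_reused_on_test_table(self):
        train = FeatureTable(pd.DataFrame({"x": [0.0, 2.0]}, index=list("ab")))
        test = FeatureTable(pd.DataFrame({"x": [100.0, np.nan]}, index=list("cd")))
        model = tableio.fit_impute(train)
        out = tableio.apply_impute(model, test)
        assert out.values.loc["d", "x"] == 1.0  # training mean, not the test mean

    def test_fully_missing_training_feature_rejected(self):
        t = FeatureTable(pd.DataFrame({"x": [np.nan, np.nan]}, index=list("ab")))
        with pytest.raises(ValueError, match="'x'"):
            tableio.fit_impute(t)

    def test_drop_then_impute_leaves_clean_table_in_order(self, toy_table):
        out, _ = tableio.drop_sparse_features(toy_table, 0.5)
        out = tableio.apply_impute(tableio.fit_impute(out), out)
        assert not out.values.isna().any().any()
        assert out.gene_ids == toy_table.gene_ids


class TestBalancedSubsets:
    def test_study_scale_subsets(self):
        table, labels, _ = synth.generate_labelled_table(synth.SyntheticSpec())
        subsets = tableio.balanced_subsets(table, labels, 10, seed=0)
        assert len(subsets) == 10
        for s in subsets:
            assert len(s) == 2614
            assert len(set(s)) == 2614  # without replacement, no duplicates
            assert (labels.loc[s] == ESSENTIAL).sum() == 1307
        # repeats differ in their majority-class draw
        assert set(subsets[0]) != set(subsets[1])

    def test_already_balanced_classes_return_full_set(self):
        spec = synth.SyntheticSpec(n_essential=30, n_nonessential=30, seed=1)
        table, labels, _ = synth.generate_labelled_table(spec)
        subsets = tableio.balanced_subsets(table, labels, 3, seed=1)
        for s in subsets:
            assert sorted(s) == sorted(table.gene_ids)

    def test_union_of_majority_samples_approaches_full_majority_class(self):
        spec = synth.SyntheticSpec(n_essential=20, n_nonessential=60, seed=2)
        table, labels, _ = synth.generate_labelled_table(spec)
        subsets = tableio.balanced_subsets(table, labels, 30, seed=2)
        majority = set(labels.index[labels == NONESSENTIAL])
        sampled = set().union(*subsets) & majority
        assert len(sampled) / len(majority) > 0.95

    def test_bad_subset_count_rejected(self, toy_table, toy_labels):
        with pytest.raises(ValueError):
            tableio.balanced_subsets(toy_table, toy_labels, 0)


class TestRepresentativeSubset:
    def test_paper_style_selection_closest_to_mean(self):
        accs = [0.8989, 0.9085, 0.9041, 0.9142, 0.9120, 0.9076, 0.9103, 0.9055, 0.9168, 0.9121]
        mean = sum(accs) / len(accs)
        idx = tableio.choose_representative_subset(accs)
        assert abs(accs[idx] - mean) == min(abs(a - mean) for a in accs)

    def test_simple_arithmetic_case(self):
        assert tableio.choose_representative_subset([0.8, 0.9, 1.0]) == 1

    def test_all_equal_ties_to_lowest_index(self):
        assert tableio.choose_representative_subset([0.9, 0.9, 0.9]) == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tableio.choose_representative_subset([])
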