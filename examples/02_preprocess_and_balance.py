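"""Pre-processing: sparse-feature removal, mean imputation, and repeated
class-balanced subsampling of the majority (viable) class."""

from essgene import synth, tableio

table, labels, _ = synth.generate_table(synth.SyntheticSpec(n_essential=200, n_nonessential=520, seed=1))

table, dropped = tableio.drop_sparse_features(table, max_missing_fraction=0.30)
print(f"dropped {len(dropped)} features missing in >30% of genes -> {len(table.features)} kept")

model = tableio.fit_impute(table)
table = tableio.apply_impute(model, table)
print(f"missing cells after mean/mode imputation: {int(table.values.isna().sum().sum())}")

subsets = tableio.balanced_subsets(table, labels, n_subsets=3, seed=1)
sizes = {len(s) for s in subsets}
print(f"3 balanced subsets, each of size {sizes.pop()} (200 essential + 200 sampled viable)")
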