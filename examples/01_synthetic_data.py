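"""Generate a synthetic labelled essentiality feature table.

The generator emulates the structure of a real mouse knockout feature
table: a minority essential class, heavy-tailed interaction-degree
features, expression-like and composition features, coded categories,
and a feature block missing for ~40% of genes.
"""

from essgene import synth

spec = synth.SyntheticSpec(n_essential=200, n_nonessential=520, seed=0)
table, labels, truth = synth.generate_table(spec)

print(f"{table.n_genes} genes x {len(table.features)} features")
print(f"essential genes: {(labels == 'essential').sum()} (the minority class)")
print(f"informative features (nonzero class shift): {len(truth.informative_features)}")
worst = table.missing_fraction().sort_values().tail(3)
print("most-missing features (the sparse interaction block sits near 0.40):")
print(worst.round(3).to_string())
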