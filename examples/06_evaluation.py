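"""Cross-validation, confusion metrics, ROC/AUC and confidence tests.

The confusion cells give TPR = TP/(TP+FN), FPR = FP/(FP+TN) and
accuracy = (TP+TN)/N; ROC sweeps the essential-class score threshold.
"""

import numpy as np

from essgene import evaluate, synth
from essgene.model import ModelSpec

spec = synth.SyntheticSpec(n_essential=150, n_nonessential=150, seed=4)
table, labels, _ = synth.generate_labelled_table(spec)

res = evaluate.cross_validate(table, labels, ModelSpec("random_forest", {"n_trees": 100}), k=10, seed=4)
c = res.pooled_counts
print(f"pooled 10-fold CV accuracy: {res.pooled_accuracy:.3f}")
print(f"pooled confusion: TP={c.tp} FN={c.fn} TN={c.tn} FP={c.fp}")

curve = evaluate.roc_auc([r.score_for_essential for r in res.records],
                         [labels[r.gene_id] for r in res.records])
print(f"held-out ROC AUC: {curve.auc:.3f} (1 = perfect ranking, 0.5 = random)")

truth = labels
ok = [r.confidence for r in res.records if r.predicted_class == truth[r.gene_id]]
bad = [r.confidence for r in res.records if r.predicted_class != truth[r.gene_id]]
rep = evaluate.compare_confidences(ok, bad)
print(f"confidence comparison via {rep.test_used}: "
      f"means {rep.mean_correct:.3f} vs {rep.mean_incorrect:.3f}, p = {rep.p_value:.2g}")
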