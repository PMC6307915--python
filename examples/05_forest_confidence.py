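"""Random-forest predictions with vote-fraction confidence.

Confidence is the fraction of trees voting for the predicted class:
1.0 means a unanimous forest, 0.5 a split vote (a tie is called
non-essential).  Correct held-out predictions carry higher confidence
than incorrect ones.
"""

import numpy as np

from essgene.model import ModelSpec, predict_with_confidence, train_model
from essgene import synth

spec = synth.SyntheticSpec(n_essential=150, n_nonessential=150, seed=3)
table, labels, _ = synth.generate_labelled_table(spec)
train, test = table.subset_genes(table.gene_ids[::2]), table.subset_genes(table.gene_ids[1::2])

model = train_model(train, labels.loc[train.gene_ids], ModelSpec("random_forest"))
records = predict_with_confidence(model, test)

conf = np.array([r.confidence for r in records])
truth = labels.loc[test.gene_ids]
ok = np.array([r.predicted_class == truth[r.gene_id] for r in records])
print(f"forest of {model.estimator.n_estimators} trees")
print(f"confidence range [{conf.min():.3f}, {conf.max():.3f}] (always within [0.5, 1])")
print(f"mean confidence: correct {conf[ok].mean():.3f} vs incorrect {conf[~ok].mean():.3f}")
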