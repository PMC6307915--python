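"""ChiMerge supervised discretisation of one feature.

Two well-separated class clusters collapse to exactly one cutpoint: the
final pair of intervals is fully class-associated (chi-squared 20 for
10 + 10 values), far above the 0.95-significance critical value 3.841.
"""

import numpy as np

from essgene import chimerge

rng = np.random.default_rng(0)
values = np.concatenate([rng.uniform(0, 4.9, 10), rng.uniform(5.1, 10, 10)])
labels = ["essential"] * 10 + ["non-essential"] * 10

scheme = chimerge.fit_scheme(values, labels)
print(f"critical value (chi2, df=1, 0.95): {scheme.chi2_threshold:.3f}")
print(f"surviving cutpoints: {np.round(scheme.cutpoints, 3)}")
print(f"codes of [1.0, 7.0]: {[int(c) for c in scheme.apply([1.0, 7.0])]}  (0 = below the cut, 1 = above)")
print(f"final adjacent chi-squared: {chimerge.adjacent_chi_squared([10, 0], [0, 10]):.1f}")
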