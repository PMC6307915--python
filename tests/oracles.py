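"""Independent reference implementations used only to check the package.

These deliberately re-derive each quantity from its definition with plain
loops, staying independent of the implementation code paths they verify.
"""

from __future__ import annotations

import itertools
import math


def chi_squared_2xc(counts_a, counts_b) -> float:
    """Pearson chi-squared of a 2 x C table by the definition, expected-0
    cells contributing 0."""
    rows = [list(counts_a), list(counts_b)]
    n = sum(map(sum, rows))
    col_tot = [sum(r[j] for r in rows) for j in range(len(rows[0]))]
    chi = 0.0
    for r in rows:
        row_tot = sum(r)
        for j, obs in enumerate(r):
            exp = row_tot * col_tot[j] / n
            if exp > 0:
                chi += (obs - exp) ** 2 / exp
    return chi


def chimerge_replay(values, labels, threshold: float):
    """Step-by-step greedy ChiMerge replay from the definition.

    Intervals start as one per distinct value; the leftmost adjacent pair
    with the smallest chi-squared merges while that minimum does not
    exceed the threshold.  Returns the per-sample interval codes.
    """
    pairs = sorted(zip(values, labels), key=lambda p: p[0])
    classes = sorted(set(labels))
    intervals = []  # list of (member values, per-class counts)
    for v, y in pairs:
        if intervals and intervals[-1][0][-1] == v:
            intervals[-1][1][classes.index(y)] += 1
            intervals[-1][0].append(v)
        else:
            counts = [0] * len(classes)
            counts[classes.index(y)] = 1
            intervals.append(([v], counts))
    while len(intervals) > 1:
        chis = [
            chi_squared_2xc(intervals[i][1], intervals[i + 1][1])
            for i in range(len(intervals) - 1)
        ]
        best = min(range(len(chis)), key=lambda i: chis[i])
        if chis[best] > threshold:
            break
        merged = (
            intervals[best][0] + intervals[best + 1][0],
            [a + b for a, b in zip(intervals[best][1], intervals[best + 1][1])],
        )
        intervals[best : best + 2] = [merged]
    code_of = {}
    for code, (members, _) in enumerate(intervals):
        for v in members:
            code_of[v] = code
    return [code_of[v] for v in values], len(intervals)


def entropy_bits(labels) -> float:
    n = len(labels)
    h = 0.0
    for c in set(labels):
        p = sum(1 for x in labels if x == c) / n
        if p > 0:
            h -= p * math.log2(p)
    return h


def information_gain_oracle(codes, labels) -> float:
    """IG by the definition: H(class) - sum_v p(v) H(class | feature=v)."""
    n = len(codes)
    h_cond = 0.0
    for v in set(codes):
        sub = [y for c, y in zip(codes, labels) if c == v]
        h_cond += len(sub) / n * entropy_bits(sub)
    return entropy_bits(labels) - h_cond


def auc_concordance(scores, truth, positive) -> float:
    """AUC as the probability of concordance over all positive-negative
    pairs, ties counted one half."""
    pos = [s for s, t in zip(scores, truth) if t == positive]
    neg = [s for s, t in zip(scores, truth) if t != positive]
    wins = 0.0
    for p, q in itertools.product(pos, neg):
        wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))
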