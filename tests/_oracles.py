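"""Independent brute-force oracles used by the equivalence suites.

These deliberately re-derive each quantity from its definition by direct
enumeration, sharing no code with the implementation paths they check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def ks_brute(x, y) -> float:
    """sup |Fx - Fy| by evaluating both ECDFs just after every pooled point."""
    x = list(map(float, x))
    y = list(map(float, y))
    best = 0.0
    for t in x + y:
        fx = sum(1 for v in x if v <= t) / len(x)
        fy = sum(1 for v in y if v <= t) / len(y)
        best = max(best, abs(fx - fy))
    return best


def auc_brute(case_scores, control_scores) -> float:
    """Pairwise concordance over all case-control pairs, ties count one half."""
    total = 0.0
    for c in case_scores:
        for k in control_scores:
            if c > k:
                total += 1.0
            elif c == k:
                total += 0.5
    return total / (len(case_scores) * len(control_scores))


def bh_brute(pvals):
    """Step-up q-values by literal min_{j>=i} p_(j)*m/j."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    for rank_i in range(m):
        candidates = [
            pvals[order[rank_j]] * m / (rank_j + 1) for rank_j in range(rank_i, m)
        ]
        q[order[rank_i]] = min(1.0, min(candidates))
    return q


def exhaustive_best_panel(score_fn, candidates, max_size):
    """Best (score, panel) over every subset of size 1..max_size."""
    best_score, best_panel = -np.inf, None
    for size in range(1, max_size + 1):
        for combo in combinations(sorted(candidates), size):
            s = score_fn(combo)
            if s > best_score or (s == best_score and combo < best_panel):
                best_score, best_panel = s, combo
    return best_score, best_panel
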