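"""Independent brute-force oracles used to cross-check the implementations.

Each of these is deliberately naive (quadratic or exhaustive) and shares no
code path with the package.
"""

from __future__ import annotations

from itertools import combinations
from math import sqrt

import numpy as np


def bh_oracle(p):
    """Quadratic-time Benjamini-Hochberg step-up adjustment."""
    p = list(map(float, p))
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [0.0] * n
    running = float("inf")
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = min(1.0, running)
    return adj


def kendall_tau_oracle(x, y):
    """All-pairs tau-b with explicit tie counting."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i, j in combinations(range(n), 2):
        dx = x[i] - x[j]
        dy = y[i] - y[j]
        if dx == 0 and dy == 0:
            ties_x += 1
            ties_y += 1
        elif dx == 0:
            ties_x += 1
        elif dy == 0:
            ties_y += 1
        elif dx * dy > 0:
            concordant += 1
        else:
            discordant += 1
    n0 = n * (n - 1) / 2
    denom = sqrt((n0 - ties_x) * (n0 - ties_y))
    if denom == 0:
        return float("nan")
    return (concordant - discordant) / denom


def wilcoxon_exact_oracle(a, b):
    """Two-sided exact rank-sum p by full enumeration (tie-free inputs)."""
    a, b = list(a), list(b)
    combined = sorted(a + b)
    n1 = len(a)

    def u_of(indices):
        ranks = [i + 1 for i in indices]
        return sum(ranks) - n1 * (n1 + 1) / 2

    obs = u_of(sorted(combined.index(v) for v in sorted(a)))
    # careful with .index under duplicates: oracle requires distinct values
    assert len(set(combined)) == len(combined), "oracle needs tie-free input"
    mu = n1 * len(b) / 2
    total = hits = 0
    for subset in combinations(range(len(combined)), n1):
        total += 1
        if abs(u_of(subset) - mu) >= abs(obs - mu) - 1e-12:
            hits += 1
    return hits / total


def intersections_oracle(sets):
    """Exclusive-combination sizes by per-element membership signature."""
    union = set().union(*sets.values())
    out = {}
    for el in union:
        sig = frozenset(name for name, s in sets.items() if el in s)
        out[sig] = out.get(sig, 0) + 1
    return out


def median_of_ratios_oracle(mat):
    """Direct recomputation of the size-factor estimator."""
    mat = np.asarray(mat, dtype=float)
    pos = (mat > 0).all(axis=1)
    geo = np.exp(np.log(mat[pos]).mean(axis=1))
    raw = np.median(mat[pos] / geo[:, None], axis=0)
    return raw / np.exp(np.mean(np.log(raw)))


def hypergeom_tail_oracle(k, size_a, size_b, universe):
    """Upper hypergeometric tail P(X >= k) for the overlap of two sets."""
    from scipy.stats import hypergeom

    return float(hypergeom.sf(k - 1, universe, size_a, size_b))
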