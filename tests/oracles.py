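"""Independent reference implementations used only to check the package.

These deliberately recompute everything from first principles (exhaustive
cluster-pair enumeration over the *original* distance matrix, closed-form
contingency arithmetic) rather than sharing any code path with the engine.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np


def naive_upgma(dist: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Exhaustive UPGMA: clusters as leaf sets, distances re-averaged from
    the original matrix at every step. Ties merge the pair whose sorted leaf
    tuples are lexicographically smallest. Returns (set_a, set_b, height)
    per merge."""
    n = dist.shape[0]
    clusters = [frozenset([i]) for i in range(n)]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in combinations(sorted(clusters, key=lambda s: sorted(s)), 2):
            d = float(np.mean([dist[i, j] for i in a for j in b]))
            key = (d, sorted(a), sorted(b))
            if best is None or key < best:
                best = key
                pair = (a, b)
        a, b = pair
        merges.append((a, b, best[0]))
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
    return merges


def dendrogram_leaf_sets(merges: np.ndarray, n: int) -> list[tuple[frozenset, float]]:
    """(leaf set, height) per internal node of a scipy-style linkage."""
    sets = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (a, b, h, _) in enumerate(merges):
        sets[n + k] = sets[int(a)] | sets[int(b)]
        out.append((sets[n + k], float(h)))
    return out


def contingency_ari(labels_a: list, labels_b: list) -> float:
    """Adjusted Rand index straight from the contingency-table formula."""
    assert len(labels_a) == len(labels_b)
    n = len(labels_a)
    cats_a = sorted(set(labels_a), key=str)
    cats_b = sorted(set(labels_b), key=str)
    table = {
        (x, y): sum(1 for a, b in zip(labels_a, labels_b) if a == x and b == y)
        for x in cats_a
        for y in cats_b
    }
    sum_ij = sum(comb(v, 2) for v in table.values())
    sum_a = sum(comb(labels_a.count(x), 2) for x in cats_a)
    sum_b = sum(comb(labels_b.count(y), 2) for y in cats_b)
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return (sum_ij - expected) / (max_index - expected)
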