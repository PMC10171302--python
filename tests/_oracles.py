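"""Independent brute-force oracles used to cross-check the implementation.

Everything here deliberately recomputes from first principles (quadratic
DP, exhaustive enumeration, per-step relinkage) and shares no code with the
package internals it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def lcs_dp(a: str, b: str) -> int:
    """Quadratic dynamic-programming LCS length."""
    dp = [[0] * (len(b) + 1) for _ in range(len(a) + 1)]
    for i, ca in enumerate(a):
        for j, cb in enumerate(b):
            dp[i + 1][j + 1] = (
                dp[i][j] + 1 if ca == cb else max(dp[i][j + 1], dp[i + 1][j])
            )
    return dp[-1][-1]


def upgma_naive(dist: np.ndarray, labels: list[str]):
    """Average-linkage agglomeration recomputing every cluster-pair average
    from the original matrix at each step.

    Returns (merge list, cophenetic matrix); merges are
    ``(height, frozenset_left, frozenset_right)``, ties broken by the
    lexicographically smallest pair of cluster minima.
    """
    index = {lab: i for i, lab in enumerate(labels)}
    clusters: list[frozenset[str]] = [frozenset([lab]) for lab in labels]
    n = len(labels)
    coph = np.zeros((n, n))
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters, key=min), 2):
            avg = np.mean(
                [dist[index[u], index[v]] for u in a for v in b]
            )
            key = (avg, min(a), min(b))
            if best is None or key < best[0]:
                best = (key, a, b)
        (avg, _, _), a, b = best
        merges.append((avg / 2.0, a, b))
        for u in a:
            for v in b:
                coph[index[u], index[v]] = coph[index[v], index[u]] = avg
        clusters.remove(a)
        clusters.remove(b)
        clusters.append(a | b)
    return merges, coph


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[rx] = ry

    def components(self):
        groups: dict = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return [frozenset(g) for g in groups.values()]


def best_subset_bruteforce(cells: np.ndarray, categories: list[str], k: int,
                           objective: str):
    """Exhaustive max over all size-k row subsets; returns the best
    objective tuple ((categories, genes) for lex, (genes,) for genes)."""
    n = cells.shape[0]
    best = None
    for rows in itertools.combinations(range(n), k):
        union = cells[list(rows)].any(axis=0)
        genes = int(union.sum())
        cats = len({c for c, present in zip(categories, union) if present})
        value = (cats, genes) if objective == "lex" else (genes,)
        if best is None or value > best:
            best = value
    return best
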