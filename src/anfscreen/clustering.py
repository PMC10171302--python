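"""Hierarchical clustering of genomes by binary gene content.

Genomes are compared over the columns of a presence/absence matrix
(optionally restricted to one ANF category) with a binary distance — Jaccard
by default, which ignores shared absences and suits sparse gene content —
and agglomerated with UPGMA (average linkage).  The resulting tree is
ultrametric: node heights are merge distances / 2, so the cophenetic
distance between two leaves (twice the height of their lowest common
ancestor) reproduces the merge distance exactly.

Determinism conventions, fixed so repeated runs give byte-identical output:

* merge ties are broken by the smallest (lexicographic) pair of cluster
  representatives, a cluster being represented by its smallest leaf label;
* at every node the child containing the smaller representative comes
  first, which pins the left-to-right leaf order used for heatmap rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pangenome import PresenceMatrix

__all__ = [
    "TreeNode",
    "ClusterTree",
    "binary_distance",
    "distance_matrix",
    "upgma",
    "leaf_order",
    "cophenetic_matrix",
]


@dataclass(frozen=True)
class TreeNode:
    """A node of an ultrametric cluster tree (leaf or binary internal)."""

    height: float
    label: str | None = None
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for child in self.children for leaf in child.leaves()]

    @property
    def min_leaf_label(self) -> str:
        return min(leaf.label for leaf in self.leaves())


@dataclass(frozen=True)
class ClusterTree:
    """UPGMA result: a rooted ultrametric tree over genome labels."""

    root: TreeNode

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.label for leaf in self.root.leaves()]


def binary_distance(u, v, metric: str = "jaccard") -> float:
    """Distance between two binary vectors.

    ``jaccard`` = 1 − |u∧v| / |u∨v| (0 when both vectors are all-zero);
    ``simple_matching`` = fraction of disagreeing positions.
    """
    u = np.asarray(u, dtype=bool)
    v = np.asarray(v, dtype=bool)
    if u.shape != v.shape or u.ndim != 1 or u.size < 1:
        raise ValueError("binary_distance requires equal-length vectors (>=1)")
    if metric == "jaccard":
        union = int(np.logical_or(u, v).sum())
        if union == 0:
            return 0.0
        return 1.0 - int(np.logical_and(u, v).sum()) / union
    if metric == "simple_matching":
        return float(np.mean(u != v))
    raise ValueError(f"unknown metric {metric!r}")


def distance_matrix(
    matrix: PresenceMatrix,
    metric: str = "jaccard",
    category: str | None = None,
) -> np.ndarray:
    """Symmetric pairwise genome distance matrix over selected features.

    *category* restricts the feature columns to one ANF category; selecting
    zero features is an error, as is a matrix with fewer than two genomes.
    """
    if len(matrix.genome_ids) < 2:
        raise ValueError("distance_matrix requires >=2 genomes")
    if category is None:
        cols = list(range(len(matrix.feature_ids)))
    else:
        cols = matrix.category_columns(category)
    if not cols:
        raise ValueError(
            f"no features selected (category={category!r})"
        )
    cells = matrix.cells[:, cols]
    n = len(matrix.genome_ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = binary_distance(cells[i], cells[j], metric)
    return dist


def upgma(dist: np.ndarray, labels) -> ClusterTree:
    """Average-linkage (UPGMA) agglomeration of a distance matrix.

    Uses the Lance–Williams size-weighted update
    ``d(i∪j, k) = (n_i·d_ik + n_j·d_jk) / (n_i + n_j)``; node height is half
    the merge distance.  Raises on asymmetric or negative input.
    """
    dist = np.asarray(dist, dtype=float)
    labels = list(labels)
    n = len(labels)
    if dist.shape != (n, n) or n < 2:
        raise ValueError("distance matrix shape must match labels (>=2)")
    if (dist < 0).any():
        raise ValueError("negative distances")
    if not np.allclose(dist, dist.T) or not np.allclose(np.diag(dist), 0):
        raise ValueError("distance matrix must be symmetric with zero diagonal")
    if len(set(labels)) != n:
        raise ValueError("labels must be unique")

    nodes: dict[str, TreeNode] = {
        lab: TreeNode(height=0.0, label=lab) for lab in labels
    }
    sizes: dict[str, int] = {lab: 1 for lab in labels}
    # distances between active clusters, keyed by representative label
    d: dict[tuple[str, str], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            key = tuple(sorted((labels[i], labels[j])))
            d[key] = float(dist[i, j])

    active = sorted(labels)
    while len(active) > 1:
        best_key = min(
            ((d[tuple(sorted((a, b)))], (a, b))
             for idx, a in enumerate(active) for b in active[idx + 1:]),
            key=lambda t: (t[0], t[1]),
        )
        merge_dist, (a, b) = best_key
        left, right = nodes[a], nodes[b]
        # child with smaller representative first (a < b since active sorted)
        parent = TreeNode(height=merge_dist / 2.0, children=(left, right))
        rep = a  # min(a, b)
        for other in active:
            if other in (a, b):
                continue
            da = d[tuple(sorted((a, other)))]
            db = d[tuple(sorted((b, other)))]
            d[tuple(sorted((rep, other)))] = (
                sizes[a] * da + sizes[b] * db
            ) / (sizes[a] + sizes[b])
        sizes[rep] = sizes[a] + sizes[b]
        nodes[rep] = parent
        active.remove(b)
    return ClusterTree(root=nodes[active[0]])


def leaf_order(tree: ClusterTree) -> list[str]:
    """Left-to-right leaf labels under the deterministic child ordering."""
    return tree.leaf_labels


def cophenetic_matrix(tree: ClusterTree, labels) -> np.ndarray:
    """Cophenetic distances (2 × LCA height) between the given leaf labels."""
    labels = list(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    out = np.zeros((n, n))

    def visit(node: TreeNode) -> list[str]:
        if node.is_leaf:
            return [node.label]
        child_leaves = [visit(c) for c in node.children]
        for i, left in enumerate(child_leaves):
            for right in child_leaves[i + 1:]:
                for u in left:
                    for v in right:
                        out[index[u], index[v]] = out[index[v], index[u]] = (
                            2.0 * node.height
                        )
        return [leaf for group in child_leaves for leaf in group]

    visit(tree.root)
    return out
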