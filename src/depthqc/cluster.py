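"""Single-linkage hierarchical clustering baseline with an objective flag rule.

Single linkage chains outliers onto the dendrogram late and at large heights,
so the height at which a sample first merges into any cluster is a natural
per-observation outlyingness statistic.  Applying the boxplot 1.5 IQR rule to
these first-merge heights (upper fence only) turns the usual visual tree
reading into an objective flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist


from .errors import InvalidInputError

__all__ = ["LinkageTree", "single_linkage_tree", "cluster_outliers", "to_newick"]


@dataclass
class LinkageTree:
    """Agglomerative merge sequence: scipy linkage matrix + leaf identifiers."""

    merges: np.ndarray          # (n-1, 4) scipy linkage matrix
    leaf_ids: tuple

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def heights(self) -> np.ndarray:
        """Merge heights in merge order (non-decreasing for single linkage)."""
        return self.merges[:, 2]

    def first_merge_heights(self) -> np.ndarray:
        """Height at which each leaf first joins any cluster.

        Leaf l is a singleton until a merge row references cluster id l
        directly; that row's height is its first-merge height.
        """
        n = self.n_leaves
        h = np.empty(n)
        for a, b, height, _ in self.merges:
            for c in (int(a), int(b)):
                if c < n:
                    h[c] = height
        return h


def single_linkage_tree(X, ids=None, metric: str = "euclidean") -> LinkageTree:
    """Single-linkage tree on pairwise distances between samples (rows).

    Duplicate samples are allowed (zero-height merges); non-finite distances
    are rejected.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 3:
        raise InvalidInputError("need at least 3 samples to build a tree")
    if ids is None:
        ids = [f"s{i}" for i in range(n)]
    if len(ids) != n:
        raise InvalidInputError(f"{len(ids)} ids for {n} samples")
    dist = pdist(X, metric=metric)
    if not np.all(np.isfinite(dist)):
        raise InvalidInputError("pairwise distances contain non-finite values")
    return LinkageTree(merges=linkage(dist, method="single"),
                       leaf_ids=tuple(ids))


def cluster_outliers(tree: LinkageTree, statistic: str = "first-merge") -> frozenset:
    """Flag leaves whose branch height exceeds the upper boxplot fence.

    ``statistic="first-merge"`` (default) assigns each leaf the height of its
    first merge; ``"all-heights"`` computes the fence from all n-1 merge
    heights instead but still flags leaves by their first-merge height.  Only
    the upper fence flags: small heights indicate tight clustering.
    """
    first = tree.first_merge_heights()
    if statistic == "first-merge":
        ref = first
    elif statistic == "all-heights":
        ref = tree.heights
    else:
        raise InvalidInputError(f"unknown statistic '{statistic}'")
    q1, q3 = np.percentile(ref, [25, 75])
    hi = q3 + 1.5 * (q3 - q1)
    return frozenset(tree.leaf_ids[i] for i in np.nonzero(first > hi)[0])


def to_newick(tree: LinkageTree) -> str:
    """Serialize the merge tree with branch lengths in Newick format."""
    n = tree.n_leaves
    height = {i: 0.0 for i in range(n)}
    label = {i: str(tree.leaf_ids[i]) for i in range(n)}
    for r, (a, b, h, _) in enumerate(tree.merges):
        a, b = int(a), int(b)
        la = h - height[a]
        lb = h - height[b]
        node = n + r
        label[node] = f"({label[a]}:{la:g},{label[b]}:{lb:g})"
        height[node] = h
    return label[n + len(tree.merges) - 1] + ";"
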