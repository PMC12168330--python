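"""Dynamic hybrid dendrogram cutting.

Adaptive module detection on an average-linkage dendrogram of a
dissimilarity matrix.  A branch qualifies as a cluster when it is large
enough, its core (the most tightly joined members) is compact, and it is
separated from its surroundings by a height gap.  The ``deep_split``
sensitivity level (0-4) maps onto the standard grid of core-scatter and
gap thresholds: higher levels split more aggressively into smaller, tighter
clusters.  Elements on branches that never qualify are left unlabeled; an
optional partitioning-around-medoids (PAM) stage then attaches each
unlabeled element to the cluster with the smallest average dissimilarity,
by default restricted to clusters on the element's own branch of the
statically cut tree.

Label 0 is reserved for unassigned elements throughout the package.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = ["dynamic_hybrid_cut", "average_linkage"]


def average_linkage(dissim: np.ndarray) -> np.ndarray:
    """Average-linkage merge tree (scipy linkage format) of a dissimilarity matrix."""
    d = np.asarray(dissim, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("dissimilarity must have zero diagonal")
    return linkage(squareform(d, checks=False), method="average")


class _Tree:
    """Per-node summaries of a scipy linkage tree."""

    def __init__(self, Z: np.ndarray, n: int, core_size: int):
        self.n = n
        self.Z = Z
        n_nodes = 2 * n - 1
        self.height = np.zeros(n_nodes)
        self.size = np.ones(n_nodes, dtype=int)
        self.left = np.full(n_nodes, -1, dtype=int)
        self.right = np.full(n_nodes, -1, dtype=int)
        # Smallest merge heights within each subtree, truncated to what the
        # core-scatter computation needs.
        self.low_heights: list[np.ndarray] = [np.empty(0)] * n_nodes
        self.core_size = core_size
        for i in range(Z.shape[0]):
            a, b, h, _ = Z[i]
            a, b = int(a), int(b)
            node = n + i
            self.left[node], self.right[node] = a, b
            self.height[node] = h
            self.size[node] = self.size[a] + self.size[b]
            merged = np.concatenate([self.low_heights[a], self.low_heights[b], [h]])
            merged.sort()
            self.low_heights[node] = merged[: core_size]

    def members(self, node: int) -> np.ndarray:
        out = []
        stack = [node]
        while stack:
            v = stack.pop()
            if v < self.n:
                out.append(v)
            else:
                stack.append(self.left[v])
                stack.append(self.right[v])
        return np.asarray(out, dtype=int)

    def core_scatter(self, node: int) -> float:
        """Mean of the lowest merge heights joining the cluster core."""
        k = min(self.core_size, max(self.size[node] - 1, 1))
        hs = self.low_heights[node][:k]
        return float(hs.mean()) if hs.size else 0.0


def dynamic_hybrid_cut(
    dissim: np.ndarray,
    deep_split: int = 4,
    min_module_size: int = 10,
    cut_height: float | None = None,
    pam_stage: bool = True,
    pam_respects_dendro: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Detect clusters in a dissimilarity matrix.

    Returns
    -------
    (labels, Z)
        ``labels`` is an int array with 0 for unassigned elements and
        arbitrary positive cluster ids; ``Z`` is the linkage matrix.
    """
    if not 0 <= deep_split <= 4:
        raise ValueError("deep_split must be in 0..4")
    d = np.asarray(dissim, dtype=float)
    n = d.shape[0]
    Z = average_linkage(d)
    if n < 2 * min_module_size:
        warnings.warn("too few elements for module detection; all unassigned")
        return np.zeros(n, dtype=int), Z

    heights = Z[:, 2]
    hmax = float(heights.max())
    if cut_height is None:
        cut_height = 0.99 * hmax
    ref = float(np.quantile(heights, 0.05))
    span = max(cut_height - ref, 1e-12)
    max_core_scatter = 0.64 + deep_split * 0.0775   # 0.64 .. 0.95 over levels 0..4
    min_gap_frac = (1.0 - max_core_scatter) * 0.75
    max_abs_scatter = ref + max_core_scatter * span
    # The separation gap is referenced to the cut height, giving it an
    # absolute scale: branches of an unstructured (pure noise) tree all
    # attach within a sliver of each other and can never clear it.
    min_abs_gap = min_gap_frac * cut_height

    tree = _Tree(Z, n, core_size=min_module_size)

    def qualifies(node: int, attach_height: float) -> bool:
        """Cluster test: big enough, compact core, hangs well below attach."""
        if tree.size[node] < min_module_size:
            return False
        gap = attach_height - tree.height[node]
        return gap >= min_abs_gap and tree.core_scatter(node) <= max_abs_scatter

    labels = np.zeros(n, dtype=int)
    next_label = [0]

    def assign(node: int, attach: float) -> None:
        """Iterative labeling of a branch.

        ``attach`` is the height at which a branch (or the chain it sits on)
        joins the rest of the tree; it is carried down through chain nodes so
        that singletons peeling off near the top do not mask a well-separated
        cluster underneath.  A branch whose merge splits it into two
        qualifying clusters is split; a branch that itself qualifies against
        its attachment becomes one cluster; anything else is descended into.
        """
        stack = [(node, attach)]
        while stack:
            v, att = stack.pop()
            if tree.size[v] < min_module_size:
                continue  # stays unassigned; PAM may pick it up
            h = tree.height[v]
            kids = (tree.left[v], tree.right[v])
            if all(qualifies(c, h) for c in kids):
                stack.extend((c, h) for c in kids)
            elif qualifies(v, att):
                next_label[0] += 1
                labels[tree.members(v)] = next_label[0]
            else:
                stack.extend((c, att) for c in kids)

    # Static cut: branches hanging below cut_height are processed separately.
    static = fcluster(Z, t=cut_height, criterion="distance")
    tops = _branch_tops(tree, static, cut_height)
    for node in tops:
        assign(node, cut_height)

    if pam_stage and labels.max() > 0:
        _pam_assign(d, labels, static, cut_height, pam_respects_dendro)
    return labels, Z


def _branch_tops(tree: _Tree, static: np.ndarray, cut_height: float) -> list[int]:
    """Highest subtree node of each static cluster."""
    n = tree.n
    tops: dict[int, int] = {}
    # walk from root down; a node is a top if its height <= cut and its parent's > cut
    node_cluster = np.zeros(2 * n - 1, dtype=int)
    node_cluster[:n] = static
    for i in range(tree.Z.shape[0]):
        node = n + i
        a, b = tree.left[node], tree.right[node]
        ca, cb = node_cluster[a], node_cluster[b]
        node_cluster[node] = ca if ca == cb else 0
    for c in np.unique(static):
        cand = [v for v in range(2 * n - 1)
                if node_cluster[v] == c and tree.height[v] <= cut_height]
        tops[c] = max(cand, key=lambda v: (tree.size[v], tree.height[v]))
    return list(tops.values())


def _pam_assign(d, labels, static, cut_height, respects_dendro) -> None:
    cluster_ids = [c for c in np.unique(labels) if c > 0]
    member_idx = {c: np.flatnonzero(labels == c) for c in cluster_ids}
    for i in np.flatnonzero(labels == 0):
        best, best_d = 0, np.inf
        for c in cluster_ids:
            if respects_dendro:
                branch = static[member_idx[c][0]]
                if static[i] != branch:
                    continue
            avg = d[i, member_idx[c]].mean()
            if avg < best_d:
                best, best_d = c, avg
        if best and best_d < cut_height:
            labels[i] = best
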