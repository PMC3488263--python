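"""Neighbor-joining trees and bootstrap support.

The agglomeration is the standard Saitou-Nei scheme with deterministic
tie-breaking (smallest node-index pair in creation order).  Additive input
matrices are recovered exactly (topology and branch lengths).  Taxa at
pairwise distance zero are merged before the agglomeration and re-attached
as zero-length pendants whose edges get bootstrap support 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .model import ValidationError

__all__ = ["TreeNode", "PhyloTree", "nj_tree", "p_distance_matrix", "bootstrap_support"]

Bipartition = FrozenSet[str]


@dataclass
class TreeNode:
    name: Optional[str] = None  # set on leaves only
    children: List[Tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List[str]:
        if self.is_leaf:
            return [self.name]
        out: List[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out


@dataclass
class PhyloTree:
    """Unrooted tree stored rooted at the final NJ join (a multifurcation)."""

    root: TreeNode
    leaf_names: Tuple[str, ...]
    pendant_edges: Tuple[Bipartition, ...] = ()  # created by zero-distance merging

    def newick(self, supports: Optional[Mapping[Bipartition, float]] = None) -> str:
        all_leaves = frozenset(self.leaf_names)
        ref = min(self.leaf_names)

        def render(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            parts = []
            for child, blen in node.children:
                label = ""
                if supports is not None and not child.is_leaf:
                    side = frozenset(child.leaves())
                    bip = side if ref not in side else all_leaves - side
                    if bip in supports:
                        label = f"{supports[bip]:.3f}"
                parts.append(f"{render(child)}{label}:{blen:.6f}")
            return "(" + ",".join(parts) + ")"

        return render(self.root) + ";"

    def bipartitions(self) -> Set[Bipartition]:
        """Internal-edge splits, canonicalized as the side excluding the smallest leaf."""
        n = len(self.leaf_names)
        all_leaves = frozenset(self.leaf_names)
        ref = min(self.leaf_names) if self.leaf_names else None
        out: Set[Bipartition] = set()

        def walk(node: TreeNode) -> FrozenSet[str]:
            if node.is_leaf:
                return frozenset([node.name])
            below: FrozenSet[str] = frozenset()
            for child, _ in node.children:
                side = walk(child)
                if 2 <= len(side) <= n - 2:
                    out.add(side if ref not in side else all_leaves - side)
                below = below | side
            return below

        walk(self.root)
        return out


def _validate_matrix(dist: np.ndarray, labels: Sequence[str]) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if dist.shape != (n, n):
        raise ValidationError(f"distance matrix shape {dist.shape} != ({n}, {n})")
    if not np.allclose(dist, dist.T):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(dist), 0.0):
        raise ValidationError("distance matrix must have a zero diagonal")
    if (dist < 0).any():
        raise ValidationError("distances must be non-negative")
    if len(set(labels)) != n:
        raise ValidationError("duplicate taxon labels")
    return dist


def _zero_groups(dist: np.ndarray) -> List[List[int]]:
    """Connected components of the exact-zero-distance graph (indices, sorted)."""
    n = dist.shape[0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] == 0.0:
                parent[find(i)] = find(j)
    groups: Dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: g[0])


def _nj_core(dist: np.ndarray, nodes: List[TreeNode]) -> TreeNode:
    """Saitou-Nei agglomeration over pre-built leaf nodes; returns the root."""
    n0 = len(nodes)
    if n0 == 1:
        return nodes[0]
    if n0 == 2:
        root = TreeNode()
        half = dist[0, 1] / 2.0
        root.children = [(nodes[0], half), (nodes[1], half)]
        return root

    D: Dict[Tuple[int, int], float] = {}
    for i in range(n0):
        for j in range(i + 1, n0):
            D[(i, j)] = dist[i, j]

    def d(i: int, j: int) -> float:
        return 0.0 if i == j else D[(min(i, j), max(i, j))]

    active = list(range(n0))
    node_of = {i: nodes[i] for i in range(n0)}
    next_id = n0

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best_q = None
        best_pair = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                if best_q is None or q < best_q - 1e-12:
                    best_q = q
                    best_pair = (i, j)
        i, j = best_pair
        li = d(i, j) / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d(i, j) - li
        u = TreeNode()
        u.children = [(node_of[i], max(0.0, li)), (node_of[j], max(0.0, lj))]
        for k in active:
            if k in (i, j):
                continue
            D[(min(k, next_id), max(k, next_id))] = (d(i, k) + d(j, k) - d(i, j)) / 2.0
        node_of[next_id] = u
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    a, b, c = active
    root = TreeNode()
    la = (d(a, b) + d(a, c) - d(b, c)) / 2.0
    lb = (d(a, b) + d(b, c) - d(a, c)) / 2.0
    lc = (d(a, c) + d(b, c) - d(a, b)) / 2.0
    root.children = [
        (node_of[a], max(0.0, la)),
        (node_of[b], max(0.0, lb)),
        (node_of[c], max(0.0, lc)),
    ]
    return root


def nj_tree(dist, labels: Sequence[str]) -> PhyloTree:
    """Neighbor-joining tree from a symmetric, zero-diagonal distance matrix.

    Negative branch lengths arising on non-additive input are clamped to 0.
    """
    labels = list(labels)
    dist = _validate_matrix(dist, labels)
    if len(labels) == 0:
        raise ValidationError("need at least one taxon")

    groups = _zero_groups(dist)
    pendant: List[Bipartition] = []
    rep_labels = [labels[g[0]] for g in groups]
    rep_idx = [g[0] for g in groups]
    rep_dist = dist[np.ix_(rep_idx, rep_idx)]

    rep_nodes: List[TreeNode] = []
    all_leaves = frozenset(labels)
    ref = min(labels)
    n = len(labels)
    for g in groups:
        if len(g) == 1:
            rep_nodes.append(TreeNode(name=labels[g[0]]))
        else:
            hub = TreeNode()
            hub.children = [(TreeNode(name=labels[i]), 0.0) for i in g]
            rep_nodes.append(hub)
            side = frozenset(labels[i] for i in g)
            if 2 <= len(side) <= n - 2:
                pendant.append(side if ref not in side else all_leaves - side)

    root = _nj_core(rep_dist, rep_nodes)
    return PhyloTree(root=root, leaf_names=tuple(labels), pendant_edges=tuple(pendant))


# ---------------------------------------------------------------------------
# alignment-based distances and bootstrap
# ---------------------------------------------------------------------------

def p_distance_matrix(rows: Sequence[str], columns: Optional[np.ndarray] = None) -> np.ndarray:
    """Pairwise p-distances over an alignment (optionally a column resample).

    Columns where either row has a gap are skipped for that pair; with no
    shared residue columns the distance is 1.0 (maximally distant).
    """
    arr = np.array([list(r) for r in rows])
    if columns is not None:
        arr = arr[:, columns]
    n = arr.shape[0]
    out = np.zeros((n, n))
    nongap = arr != "-"
    for i in range(n):
        for j in range(i + 1, n):
            valid = nongap[i] & nongap[j]
            total = int(valid.sum())
            if total == 0:
                dij = 1.0
            else:
                dij = float((arr[i, valid] != arr[j, valid]).sum()) / total
            out[i, j] = out[j, i] = dij
    return out


def bootstrap_support(
    msa: Sequence[Tuple[str, str]],
    n_reps: int,
    seed: int,
) -> Dict[Bipartition, float]:
    """Column-resampling bootstrap supports for the NJ tree of an alignment.

    Returns the support (fraction of replicates) for every internal
    bipartition of the original tree; pendant edges created by zero-distance
    merging get support 1.0 by convention.  Deterministic for a fixed seed.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    ids = [name for name, _ in msa]
    rows = [seq for _, seq in msa]
    if len(ids) < 4:
        return {}
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValidationError("alignment rows differ in length")

    base_tree = nj_tree(p_distance_matrix(rows), ids)
    targets = base_tree.bipartitions()
    counts = {bip: 0 for bip in targets}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = rng.integers(0, width, size=width)
        rep_tree = nj_tree(p_distance_matrix(rows, columns=cols), ids)
        seen = rep_tree.bipartitions()
        for bip in targets:
            if bip in seen:
                counts[bip] += 1
    supports = {bip: counts[bip] / n_reps for bip in targets}
    for bip in base_tree.pendant_edges:
        supports[bip] = 1.0
    return supports
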