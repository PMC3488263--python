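"""Screen of solitary REs against methyl-directed REs (Types IIM / IV).

Hits from the similarity search are single-linkage clustered with the
40%-identity / 60%-coverage-of-each-sequence rule; clusters holding both
solitary and Type IV sequences are flagged ``mixed`` and get a progressive
multiple alignment, an NJ tree and bootstrap supports.  The screen reports
this evidence; it never reclassifies a solitary RE on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np

from . import align, phylo
from .model import Thresholds, ValidationError

__all__ = [
    "Cluster",
    "ScreenResult",
    "cluster_by_identity",
    "progressive_msa",
    "screen_against_methyl_directed",
]


@dataclass(frozen=True)
class Cluster:
    cluster_id: str
    members: Tuple[str, ...]
    mixed: bool = False


def cluster_by_identity(
    seq_ids: Sequence[str],
    hits: Sequence[align.AlignmentHit],
    thresholds: Thresholds = Thresholds(),
    categories: Optional[Mapping[str, str]] = None,
) -> List[Cluster]:
    """Single-linkage clusters over qualifying hit pairs.

    A pair qualifies at identity > ``cluster_identity`` with coverage of
    *each* sequence > ``cluster_coverage``.  Every input id ends up in
    exactly one cluster (singletons included); the result is independent of
    input order.  With ``categories`` given (id -> arbitrary label), clusters
    containing more than one label are flagged ``mixed``.
    """
    graph = nx.Graph()
    graph.add_nodes_from(seq_ids)
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.query_id not in graph or h.subject_id not in graph:
            continue
        if align.meets(h, thresholds.cluster_identity, thresholds.cluster_coverage, "each"):
            graph.add_edge(h.query_id, h.subject_id)
    components = sorted((sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0])
    clusters = []
    for idx, comp in enumerate(components, 1):
        mixed = False
        if categories is not None:
            labels = {categories[m] for m in comp if m in categories}
            mixed = len(labels) > 1
        clusters.append(Cluster(cluster_id=f"C{idx:04d}", members=tuple(comp), mixed=mixed))
    return clusters


# ---------------------------------------------------------------------------
# progressive multiple alignment (guide tree: NJ on pairwise p-distances)
# ---------------------------------------------------------------------------

_GAP_RESIDUE_SCORE = -4.0


def _column_score(col_a: Sequence[str], col_b: Sequence[str], sub, lut) -> float:
    total = 0.0
    for x in col_a:
        for y in col_b:
            if x == "-" and y == "-":
                continue
            if x == "-" or y == "-":
                total += _GAP_RESIDUE_SCORE
            else:
                total += sub[lut.get(x, lut["X"]), lut.get(y, lut["X"])]
    return total / (len(col_a) * len(col_b))


def _align_profiles(
    rows_a: List[str], rows_b: List[str], sub, lut, gap_open: float = 11.0, gap_extend: float = 1.0
) -> Tuple[List[str], List[str]]:
    """Global affine profile-profile alignment; ties prefer diagonal, then gap-in-B."""
    neg = -1e18
    la = len(rows_a[0])
    lb = len(rows_b[0])
    cols_a = ["".join(r[i] for r in rows_a) for i in range(la)]
    cols_b = ["".join(r[i] for r in rows_b) for i in range(lb)]
    first = gap_open + gap_extend
    H = np.full((la + 1, lb + 1), neg)
    E = np.full((la + 1, lb + 1), neg)  # gap in A (consumes B)
    F = np.full((la + 1, lb + 1), neg)  # gap in B (consumes A)
    ptr = np.zeros((la + 1, lb + 1, 3), dtype=np.int8)
    H[0, 0] = 0.0
    for j in range(1, lb + 1):
        E[0, j] = max(H[0, j - 1] - first, E[0, j - 1] - gap_extend)
        ptr[0, j, 1] = 1 if H[0, j - 1] - first >= E[0, j - 1] - gap_extend else 0
        H[0, j] = E[0, j]
        ptr[0, j, 0] = 2
    for i in range(1, la + 1):
        F[i, 0] = max(H[i - 1, 0] - first, F[i - 1, 0] - gap_extend)
        ptr[i, 0, 2] = 1 if H[i - 1, 0] - first >= F[i - 1, 0] - gap_extend else 0
        H[i, 0] = F[i, 0]
        ptr[i, 0, 0] = 3
        for j in range(1, lb + 1):
            eo = H[i, j - 1] - first
            ee = E[i, j - 1] - gap_extend
            if eo >= ee:
                E[i, j] = eo
                ptr[i, j, 1] = 1
            else:
                E[i, j] = ee
                ptr[i, j, 1] = 0
            fo = H[i - 1, j] - first
            fe = F[i - 1, j] - gap_extend
            if fo >= fe:
                F[i, j] = fo
                ptr[i, j, 2] = 1
            else:
                F[i, j] = fe
                ptr[i, j, 2] = 0
            diag = H[i - 1, j - 1] + _column_score(cols_a[i - 1], cols_b[j - 1], sub, lut)
            h, p = diag, 1
            if F[i, j] > h:
                h, p = F[i, j], 3
            if E[i, j] > h:
                h, p = E[i, j], 2
            H[i, j] = h
            ptr[i, j, 0] = p

    # traceback
    out_a: List[str] = []
    out_b: List[str] = []
    i, j = la, lb
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            p = ptr[i, j, 0]
            if p == 1:
                out_a.append(cols_a[i - 1])
                out_b.append(cols_b[j - 1])
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            opened = ptr[i, j, 1]
            out_a.append("-" * len(rows_a))
            out_b.append(cols_b[j - 1])
            j -= 1
            state = 0 if opened else 1
        else:
            opened = ptr[i, j, 2]
            out_a.append(cols_a[i - 1])
            out_b.append("-" * len(rows_b))
            i -= 1
            state = 0 if opened else 2
    out_a.reverse()
    out_b.reverse()
    new_a = ["".join(col[k] for col in out_a) for k in range(len(rows_a))]
    new_b = ["".join(col[k] for col in out_b) for k in range(len(rows_b))]
    return new_a, new_b


def progressive_msa(sequences: Sequence[Tuple[str, str]]) -> List[Tuple[str, str]]:
    """Progressive multiple alignment along an NJ guide tree of p-distances.

    All returned rows have equal length and removing the gap characters of a
    row recovers the corresponding input sequence exactly.  A single
    sequence comes back unchanged as a one-row alignment.
    """
    if len(sequences) == 0:
        raise ValidationError("progressive_msa needs at least one sequence")
    if len(sequences) == 1:
        return [tuple(sequences[0])]
    ids = [name for name, _ in sequences]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sequence ids")
    seqs = {name: seq for name, seq in sequences}

    alphabet, sub = align._load_matrix("BLOSUM62")
    lut = {c: i for i, c in enumerate(alphabet)}

    # guide distances: 1 - alignment identity (1.0 when no local hit at all)
    n = len(ids)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            hit = align.align_pair(seqs[ids[i]], seqs[ids[j]])
            d = 1.0 if hit is None else 1.0 - hit.identity
            dist[i, j] = dist[j, i] = d
    guide = phylo.nj_tree(dist, ids)

    def merge(node: phylo.TreeNode) -> Tuple[List[str], List[str]]:
        if node.is_leaf:
            return [node.name], [seqs[node.name]]
        child_profiles = [merge(child) for child, _ in node.children]
        acc_ids, acc_rows = child_profiles[0]
        for nxt_ids, nxt_rows in child_profiles[1:]:
            acc_rows, nxt_rows = _align_profiles(acc_rows, nxt_rows, sub, lut)
            acc_ids = acc_ids + nxt_ids
            acc_rows = acc_rows + nxt_rows
        return acc_ids, acc_rows

    out_ids, out_rows = merge(guide.root)
    order = {name: k for k, name in enumerate(ids)}
    combined = sorted(zip(out_ids, out_rows), key=lambda t: order[t[0]])
    return [(name, row) for name, row in combined]


# ---------------------------------------------------------------------------
# full screen
# ---------------------------------------------------------------------------

@dataclass
class ScreenResult:
    clusters: List[Cluster]
    alignments: Dict[str, List[Tuple[str, str]]] = field(default_factory=dict)
    newicks: Dict[str, str] = field(default_factory=dict)
    supports: Dict[str, Dict] = field(default_factory=dict)


def screen_against_methyl_directed(
    solitary_proteins: Mapping[str, str],
    methyl_proteins: Mapping[str, str],
    thresholds: Thresholds = Thresholds(),
    seed: int = 0,
) -> ScreenResult:
    """Search, cluster, and analyse mixed clusters with an MSA + NJ + bootstrap."""
    universe = {**solitary_proteins, **methyl_proteins}
    categories = {k: "solitary" for k in solitary_proteins}
    categories.update({k: "methyl_directed" for k in methyl_proteins})
    hits = align.search(universe, universe, thresholds.typeiv_evalue, skip_self=True)
    clusters = cluster_by_identity(sorted(universe), hits, thresholds, categories)
    result = ScreenResult(clusters=clusters)
    for cluster in clusters:
        if not cluster.mixed or len(cluster.members) < 2:
            continue
        msa = progressive_msa([(m, universe[m]) for m in cluster.members])
        result.alignments[cluster.cluster_id] = msa
        supports = phylo.bootstrap_support(msa, thresholds.bootstrap_reps, seed)
        rows = [row for _, row in msa]
        tree = phylo.nj_tree(phylo.p_distance_matrix(rows), [m for m, _ in msa])
        result.newicks[cluster.cluster_id] = tree.newick(supports=supports)
        result.supports[cluster.cluster_id] = supports
    return result
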