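"""Independent reference implementations used only by the test suite.

These deliberately re-implement the documented conventions from scratch
(plain Python lists, no shared code paths with the package) so the package
implementations can be checked against a second, independently written
route.
"""

from __future__ import annotations

from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

from Bio.Align import substitution_matrices

_BLOSUM = substitution_matrices.load("BLOSUM62")
_ALPHA = str(_BLOSUM.alphabet)
_IDX = {c: i for i, c in enumerate(_ALPHA)}
NEG = -(10 ** 9)


def _score(a: str, b: str) -> int:
    ia = _IDX.get(a, _IDX["X"])
    ib = _IDX.get(b, _IDX["X"])
    return int(_BLOSUM[ia][ib])


def oracle_align(seq_a: str, seq_b: str, gap_open: int = 11, gap_extend: int = 1):
    """Reference local affine-gap alignment (gap of length k costs open + k*ext).

    Conventions mirror the documented ones: canonical orientation
    (lexicographically smaller sequence first), tie priorities diagonal >
    gap-in-first > gap-in-second, gap states prefer opening, stop at score 0,
    best cell at smallest (i, j).  Returns (score, identity, n_identical,
    n_pair_columns, aln_length, span_a, span_b) or None when no positive
    alignment exists; spans are (start, end) on each input sequence.
    """
    swap = seq_a > seq_b
    a, b = (seq_b, seq_a) if swap else (seq_a, seq_b)
    m, n = len(a), len(b)
    first = gap_open + gap_extend
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    PH = [[0] * (n + 1) for _ in range(m + 1)]
    PE = [[0] * (n + 1) for _ in range(m + 1)]
    PF = [[0] * (n + 1) for _ in range(m + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            eo, ee = H[i][j - 1] - first, E[i][j - 1] - gap_extend
            E[i][j], PE[i][j] = (eo, 1) if eo >= ee else (ee, 0)
            fo, fe = H[i - 1][j] - first, F[i - 1][j] - gap_extend
            F[i][j], PF[i][j] = (fo, 1) if fo >= fe else (fe, 0)
            h = H[i - 1][j - 1] + _score(a[i - 1], b[j - 1])
            p = 1
            if E[i][j] > h:
                h, p = E[i][j], 2
            if F[i][j] > h:
                h, p = F[i][j], 3
            if h <= 0:
                h, p = 0, 0
            H[i][j], PH[i][j] = h, p
            if h > best:
                best, bi, bj = h, i, j
    if best <= 0:
        return None
    i, j, state = bi, bj, 0
    n_cols = n_pair = n_id = 0
    a_end, b_end = bi, bj
    while True:
        if state == 0:
            p = PH[i][j]
            if p == 0:
                break
            if p == 1:
                n_cols += 1
                n_pair += 1
                n_id += a[i - 1] == b[j - 1]
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            opened = PE[i][j]
            n_cols += 1
            j -= 1
            state = 0 if opened else 1
        else:
            opened = PF[i][j]
            n_cols += 1
            i -= 1
            state = 0 if opened else 2
    span_a = (i, a_end)
    span_b = (j, b_end)
    if swap:
        span_a, span_b = span_b, span_a
    return (best, n_id / n_pair, n_id, n_pair, n_cols, span_a, span_b)


# ---------------------------------------------------------------------------
# naive neighbor joining (O(n^3) per iteration, everything recomputed)
# ---------------------------------------------------------------------------

def naive_nj(dist: Sequence[Sequence[float]], labels: Sequence[str]):
    """Reference NJ: returns (bipartitions, edge_length_map).

    ``edge_length_map`` maps canonical bipartitions (side excluding the
    smallest label) and leaf names to branch lengths.  Tie rules match the
    documented convention: smallest creation-order index pair, negative
    lengths clamped to zero, final three-node star via three-point formulas.
    """
    labels = list(labels)
    n0 = len(labels)
    all_set = frozenset(labels)
    ref = min(labels)

    def canon(side: FrozenSet[str]) -> FrozenSet[str]:
        return side if ref not in side else all_set - side

    D: Dict[Tuple[int, int], float] = {}
    for i in range(n0):
        for j in range(i + 1, n0):
            D[(i, j)] = float(dist[i][j])

    def d(i: int, j: int) -> float:
        return 0.0 if i == j else D[(min(i, j), max(i, j))]

    leafset: Dict[int, FrozenSet[str]] = {i: frozenset([labels[i]]) for i in range(n0)}
    edges: Dict[object, float] = {}
    active = list(range(n0))
    nxt = n0

    def record(node: int, length: float) -> None:
        side = leafset[node]
        if len(side) == 1:
            edges[next(iter(side))] = length
        elif 2 <= len(side) <= len(all_set) - 2:
            edges[canon(side)] = length

    while len(active) > 3:
        m = len(active)
        best_q, pair = None, None
        for x in range(m):
            for y in range(x + 1, m):
                i, j = active[x], active[y]
                ri = sum(d(i, k) for k in active if k != i)
                rj = sum(d(j, k) for k in active if k != j)
                q = (m - 2) * d(i, j) - ri - rj
                if best_q is None or q < best_q - 1e-12:
                    best_q, pair = q, (i, j)
        i, j = pair
        ri = sum(d(i, k) for k in active if k != i)
        rj = sum(d(j, k) for k in active if k != j)
        li = d(i, j) / 2.0 + (ri - rj) / (2.0 * (m - 2))
        lj = d(i, j) - li
        record(i, max(0.0, li))
        record(j, max(0.0, lj))
        for k in active:
            if k not in (i, j):
                D[(min(k, nxt), max(k, nxt))] = (d(i, k) + d(j, k) - d(i, j)) / 2.0
        leafset[nxt] = leafset[i] | leafset[j]
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    if len(active) == 3:
        a, b, c = active
        record(a, max(0.0, (d(a, b) + d(a, c) - d(b, c)) / 2.0))
        record(b, max(0.0, (d(a, b) + d(b, c) - d(a, c)) / 2.0))
        record(c, max(0.0, (d(a, c) + d(b, c) - d(a, b)) / 2.0))
    elif len(active) == 2:
        a, b = active
        record(a, d(a, b) / 2.0)
        record(b, d(a, b) / 2.0)

    bips = {k for k in edges if isinstance(k, frozenset)}
    return bips, edges


def tree_edge_lengths(tree) -> Dict[object, float]:
    """Canonical bipartition / leaf-name -> branch length map for a PhyloTree."""
    all_set = frozenset(tree.leaf_names)
    ref = min(tree.leaf_names)
    n = len(tree.leaf_names)
    edges: Dict[object, float] = {}

    def walk(node) -> FrozenSet[str]:
        below: FrozenSet[str] = frozenset()
        for child, length in node.children:
            side = walk(child) if not child.is_leaf else frozenset([child.name])
            if len(side) == 1:
                edges[next(iter(side))] = length
            elif 2 <= len(side) <= n - 2:
                edges[side if ref not in side else all_set - side] = length
            below |= side
        return below

    walk(tree.root)
    return edges


def tree_path_distances(tree) -> Dict[Tuple[str, str], float]:
    """Leaf-to-leaf path lengths of a PhyloTree."""
    out: Dict[Tuple[str, str], float] = {}

    def lca_dist(node):
        # returns {leaf: dist below node}; fills `out` with cross-child pairs
        if node.is_leaf:
            return {node.name: 0.0}
        seen: Dict[str, float] = {}
        for child, length in node.children:
            sub = lca_dist(child)
            for nm, dd in sub.items():
                for other, od in seen.items():
                    key = tuple(sorted((nm, other)))
                    out[key] = dd + length + od
            for nm, dd in sub.items():
                seen[nm] = dd + length
        return seen

    lca_dist(tree.root)
    return out
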