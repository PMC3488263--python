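import random

import numpy as np
import pytest

from rmscan.model import ValidationError
from rmscan.phylo import PhyloTree, bootstrap_support, nj_tree, p_distance_matrix
from rmscan.synth import generate_family
from rmscan.methyl import progressive_msa

from oracles import naive_nj, tree_edge_lengths, tree_path_distances


def random_additive_tree(n_taxa, rng):
    """Random binary topology with branch lengths; returns (labels, dist matrix, bipartitions)."""
    labels = [f"t{i}" for i in range(n_taxa)]
    # adjacency with branch lengths; start from a 3-star, attach remaining leaves
    nodes = {0: {}, 1: {}, 2: {}, "c0": {}}
    next_internal = 1

    def connect(a, b, w):
        nodes[a][b] = w
        nodes[b][a] = w

    for leaf in (0, 1, 2):
        connect(leaf, "c0", round(rng.uniform(0.1, 1.0), 3))
    edges = [(0, "c0"), (1, "c0"), (2, "c0")]
    for leaf in range(3, n_taxa):
        a, b = edges[rng.randrange(len(edges))]
        w = nodes[a].pop(b)
        nodes[b].pop(a)
        hub = f"c{next_internal}"
        next_internal += 1
        nodes[hub] = {}
        nodes[leaf] = {}
        w1 = round(w * rng.uniform(0.25, 0.75), 4) or 0.01
        connect(a, hub, w1)
        connect(b, hub, round(max(w - w1, 0.01), 4))
        connect(leaf, hub, round(rng.uniform(0.1, 1.0), 3))
        edges.remove((a, b))
        edges.extend([(a, hub), (b, hub), (leaf, hub)])

    # all-pairs path lengths by BFS/DFS
    def dist_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in nodes[u].items():
                if v not in out:
                    out[v] = out[u] + w
                    stack.append(v)
        return out

    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        di = dist_from(i)
        for j in range(n_taxa):
            D[i, j] = di[j]

    # true bipartitions from internal edges
    all_set = frozenset(labels)
    ref = min(labels)
    bips = set()
    internal = [k for k in nodes if isinstance(k, str)]
    for hub in internal:
        for nb in nodes[hub]:
            if isinstance(nb, str):
                # cut edge hub-nb: leaves on hub's side
                seen = {hub, nb}
                stack = [hub]
                side = set()
                while stack:
                    u = stack.pop()
                    for v in nodes[u]:
                        if v in seen:
                            continue
                        seen.add(v)
                        if isinstance(v, int):
                            side.add(f"t{v}")
                        else:
                            stack.append(v)
                if 2 <= len(side) <= n_taxa - 2:
                    fside = frozenset(side)
                    bips.add(fside if ref not in fside else all_set - fside)
    return labels, D, bips


class TestNJExactness:
    def test_three_taxa_closed_form(self):
        D = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(D, ["A", "B", "C"])
        lengths = tree_edge_lengths(tree)
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)
        assert tree.bipartitions() == set()

    def test_four_taxon_recovery(self):
        # distances from ((A:1,B:2):1,(C:3,D:1));
        labels = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0, 3, 5, 3],
                [3, 0, 6, 4],
                [5, 6, 0, 4],
                [3, 4, 4, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(D, labels)
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        paths = tree_path_distances(tree)
        for i, a in enumerate(labels):
            for j in range(i + 1, 4):
                assert paths[(a, labels[j])] == pytest.approx(D[i, j])

    @pytest.mark.parametrize("seed", range(10))
    def test_eight_taxon_additive_recovery(self, seed):
        rng = random.Random(seed)
        labels, D, true_bips = random_additive_tree(8, rng)
        tree = nj_tree(D, labels)
        assert tree.bipartitions() == true_bips
        paths = tree_path_distances(tree)
        for i in range(8):
            for j in range(i + 1, 8):
                assert paths[tuple(sorted((labels[i], labels[j])))] == pytest.approx(D[i, j])

    @pytest.mark.parametrize("n,seed", [(5, 0), (8, 1), (10, 2), (12, 3)])
    def test_matches_naive_reference_on_random_matrices(self, n, seed):
        rng = np.random.default_rng(seed)
        M = rng.uniform(0.2, 2.0, size=(n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = [f"x{i}" for i in range(n)]
        tree = nj_tree(D, labels)
        ref_bips, ref_edges = naive_nj(D.tolist(), labels)
        assert tree.bipartitions() == ref_bips
        mine = tree_edge_lengths(tree)
        assert set(mine) == set(ref_edges)
        for key in mine:
            assert mine[key] == pytest.approx(ref_edges[key])

    def test_rejects_asymmetric(self):
        D = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValidationError):
            nj_tree(D, list("ABC"))

    def test_newick_has_all_leaves(self):
        rng = random.Random(4)
        labels, D, _ = random_additive_tree(6, rng)
        newick = nj_tree(D, labels).newick()
        assert newick.endswith(";")
        for name in labels:
            assert name in newick


class TestPDistance:
    def test_simple(self):
        D = p_distance_matrix(["ACDE", "ACEE", "AC-E"])
        assert D[0, 1] == pytest.approx(0.25)
        assert D[0, 2] == pytest.approx(0.0)  # gap column skipped
        assert D[1, 2] == pytest.approx(0.0)  # E==E in the shared columns
        D2 = p_distance_matrix(["AAAA", "----"])
        assert D2[0, 1] == pytest.approx(1.0)  # no shared columns: maximally distant


def _family_msa(seed, n=4, d=0.05, length=120, prefix="s"):
    fam = generate_family(length, n, divergence=d, seed=seed)
    return [(f"{prefix}{i}", m) for i, m in enumerate(fam)]


class TestBootstrap:
    def test_fewer_than_four_taxa_empty(self):
        msa = [("a", "ACDE"), ("b", "ACDE"), ("c", "ACDF")]
        assert bootstrap_support(msa, 10, seed=0) == {}

    def test_identical_sequences_degenerate(self):
        msa = [(f"s{i}", "MKLVANDE" * 10) for i in range(5)]
        supports = bootstrap_support(msa, 10, seed=0)
        assert all(v == 1.0 for v in supports.values())

    def test_zero_distance_pendant_group_supported(self):
        fam = generate_family(100, 3, divergence=0.3, seed=3)
        msa_in = [("a0", fam[0]), ("a1", fam[0]), ("a2", fam[0]), ("a3", fam[0]),
                  ("b", fam[1]), ("c", fam[2])]
        msa = progressive_msa(msa_in)
        supports = bootstrap_support(msa, 20, seed=1)
        group = frozenset({"b", "c"})  # complement of the identical quartet
        assert supports.get(frozenset({"b", "c"})) == 1.0 or supports.get(
            frozenset({"a0", "a1", "a2", "a3"})
        ) == 1.0

    def test_clear_clades_high_support(self):
        clade1 = _family_msa(10, n=4, d=0.05, prefix="a")
        clade2 = _family_msa(20, n=4, d=0.05, prefix="b")
        msa = progressive_msa(clade1 + clade2)
        supports = bootstrap_support(msa, 200, seed=7)
        split = frozenset({"b0", "b1", "b2", "b3"})
        assert split in supports
        assert supports[split] >= 0.95

    def test_single_replicate_binary_supports(self):
        msa = progressive_msa(_family_msa(30, n=5, d=0.2))
        supports = bootstrap_support(msa, 1, seed=0)
        assert set(supports.values()) <= {0.0, 1.0}

    def test_deterministic_for_seed(self):
        msa = progressive_msa(_family_msa(40, n=5, d=0.15))
        assert bootstrap_support(msa, 25, seed=3) == bootstrap_support(msa, 25, seed=3)

    def test_relabeling_equivariance(self):
        msa = progressive_msa(_family_msa(50, n=6, d=0.15))
        mapping = {f"s{i}": f"z{5 - i}" for i in range(6)}
        relabeled = [(mapping[name], row) for name, row in msa]
        sup1 = bootstrap_support(msa, 50, seed=9)
        sup2 = bootstrap_support(relabeled, 50, seed=9)
        remapped = {
            frozenset(mapping[x] for x in bip): v for bip, v in sup1.items()
        }
        # canonical sides may flip under renaming; compare via full split identity
        def canon(bips, names):
            all_set = frozenset(names)
            return {frozenset((b, all_set - b)) for b in bips}

        names2 = [n for n, _ in relabeled]
        assert canon(remapped, names2) == canon(sup2, names2)
        by_split1 = {frozenset((b, frozenset(names2) - b)): v for b, v in remapped.items()}
        by_split2 = {frozenset((b, frozenset(names2) - b)): v for b, v in sup2.items()}
        assert by_split1 == by_split2
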