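"""Neighbor joining, bootstrap supports and outgroup rooting."""

import numpy as np
import pytest

from barcodekit import (AlignmentMatrix, bootstrap_supports, nj_tree,
                        read_newick, root_at_outgroup, write_newick)
from barcodekit.k2p import DistanceMatrix
from barcodekit.phylogeny import Node, PhyloTree


def _dm(ids, values):
    return DistanceMatrix(ids=list(ids), values=np.asarray(values, float),
                          species_of={i: i for i in ids})


def random_additive_tree(n_taxa, rng):
    """A random binary tree with positive branch lengths and its leaf
    distance matrix (path lengths), built independently of NJ."""
    nodes = [Node(name=f"t{i}") for i in range(n_taxa)]
    # track each leaf's distance to the root of its current cluster and
    # join clusters in random order with random positive branch lengths
    depth = {a.name: 0.0 for a in nodes}
    active = nodes[:]
    leaf_sets = {id(a): [a.name] for a in nodes}
    D = np.zeros((n_taxa, n_taxa))
    names = [a.name for a in nodes]
    idx = {n: i for i, n in enumerate(names)}
    while len(active) > 1:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        a, b = active[j], active[i]   # pop larger index first
        active.pop(j); active.pop(i)
        la, lb = rng.uniform(0.05, 1.0), rng.uniform(0.05, 1.0)
        a.length, b.length = la, lb
        parent = Node(children=[a, b])
        for x in leaf_sets[id(a)]:
            depth[x] += la
        for x in leaf_sets[id(b)]:
            depth[x] += lb
        for x in leaf_sets[id(a)]:
            for y in leaf_sets[id(b)]:
                D[idx[x], idx[y]] = D[idx[y], idx[x]] = depth[x] + depth[y]
        leaf_sets[id(parent)] = leaf_sets[id(a)] + leaf_sets[id(b)]
        active.append(parent)
    tree = PhyloTree(active[0])
    return tree, names, D


class TestNJ:
    def test_three_taxa_closed_form(self):
        dm = _dm("ABC", [[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        tree = nj_tree(dm)
        lengths = {leaf.name: leaf.length for leaf in tree.root.leaves()}
        # three-point formulas: lA=(3+4-5)/2=1, lB=(3+5-4)/2=2, lC=3
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0})

    def test_four_taxa_additive_recovery(self):
        # generating tree ((A:1,B:2):1,(C:3,D:4))
        ids = ["A", "B", "C", "D"]
        D = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], float)
        tree = nj_tree(_dm(ids, D))
        assert tree.bipartitions() == {frozenset({"C", "D"})}
        # path lengths reproduce the additive matrix exactly
        got = _tree_distances(tree)
        for i, a in enumerate(ids):
            for j, b in enumerate(ids):
                assert got[(a, b)] == pytest.approx(D[i, j], abs=1e-12)

    def test_recovers_random_additive_trees(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            true_tree, names, D = random_additive_tree(n, rng)
            got = nj_tree(_dm(names, D))
            assert got.bipartitions() == true_tree.bipartitions()

    def test_ultrametric_matches_single_linkage_clusters(self):
        """On an ultrametric matrix the NJ splits coincide with the
        clusters of a hierarchical single-linkage oracle."""
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        ids = list("ABCDEF")
        # nested ultrametric structure: ((A,B),(C,D)),(E,F)
        M = np.zeros((6, 6))
        groups = {0: 0.1, 1: 0.1, 2: 0.1}  # pair depths
        pairs = {("A", "B"): 0.02, ("C", "D"): 0.02, ("E", "F"): 0.02}
        for i in range(6):
            for j in range(i + 1, 6):
                a, b = ids[i], ids[j]
                if (a, b) in pairs:
                    d = pairs[(a, b)]
                elif {a, b} <= {"A", "B", "C", "D"}:
                    d = 0.08
                else:
                    d = 0.2
                M[i, j] = M[j, i] = d
        tree = nj_tree(_dm(ids, M))
        bps = tree.bipartitions()
        Z = linkage(squareform(M), method="single")
        for k in (2, 3):
            labels = fcluster(Z, t=k, criterion="maxclust")
            for c in set(labels):
                members = frozenset(ids[i] for i in range(6)
                                    if labels[i] == c)
                if 2 <= len(members) <= 4:
                    canon = members if "A" not in members \
                        else frozenset(ids) - members
                    assert canon in bps

    def test_negative_branch_clamped(self):
        # strongly non-additive matrix that drives an NJ branch negative
        D = np.array([
            [0.0, 0.1, 0.1, 0.4],
            [0.1, 0.0, 0.1, 0.4],
            [0.1, 0.1, 0.0, 0.1],
            [0.4, 0.4, 0.1, 0.0]])
        tree = nj_tree(_dm("ABCD", D))

        def all_lengths(node):
            out = [node.length]
            for c in node.children:
                out += all_lengths(c)
            return out
        assert min(all_lengths(tree.root)) >= 0.0


def _tree_distances(tree):
    """Leaf-to-leaf path lengths, summed through each pair's LCA."""
    out = {leaf.name: None for leaf in tree.root.leaves()}
    out = {(n, n): 0.0 for n in out}

    def tips(node, base):
        if node.is_leaf:
            return [(node.name, base + node.length)]
        items = []
        for c in node.children:
            items.extend(tips(c, base + node.length))
        return items

    def collect(node):
        if node.is_leaf:
            return
        for ci in range(len(node.children)):
            for cj in range(ci + 1, len(node.children)):
                for a, da in tips(node.children[ci], 0.0):
                    for b, db in tips(node.children[cj], 0.0):
                        out[(a, b)] = out[(b, a)] = da + db
        for c in node.children:
            collect(c)

    collect(tree.root)
    return out


class TestBootstrap:
    def _two_clade_alignment(self):
        left = "A" * 6 + "C" * 54
        right = "G" * 6 + "C" * 54   # 6 transition sites between clades
        ids = ["l1", "l2", "l3", "r1", "r2", "r3"]
        rows = [left, left, left, right, right, right]
        return AlignmentMatrix(ids, rows)

    def test_clean_split_gets_full_support(self):
        aln = self._two_clade_alignment()
        tree = bootstrap_supports(aln, n_reps=200, seed=1)
        splits = {}
        def walk(node):
            for c in node.children:
                if not c.is_leaf:
                    splits[frozenset(c.clade_names())] = c.support
                    walk(c)
        walk(tree.root)
        seps = [s for bp, s in splits.items()
                if bp in ({"l1", "l2", "l3"}, {"r1", "r2", "r3"})
                or bp in (frozenset(["l1", "l2", "l3"]),
                          frozenset(["r1", "r2", "r3"]))]
        assert seps and all(s == 100.0 for s in seps)

    def test_reproducible_under_fixed_seed(self):
        aln = self._two_clade_alignment()
        t1 = bootstrap_supports(aln, n_reps=50, seed=9)
        t2 = bootstrap_supports(aln, n_reps=50, seed=9)
        assert write_newick(t1) == write_newick(t2)

    def test_supports_invariant_under_leaf_permutation(self, small_sim,
                                                       small_sim_aln):
        aln = small_sim_aln
        perm = list(reversed(range(len(aln.ids))))
        aln2 = AlignmentMatrix([aln.ids[i] for i in perm],
                               [aln.rows[i] for i in perm])
        t1 = bootstrap_supports(aln, n_reps=30, seed=2)
        t2 = bootstrap_supports(aln2, n_reps=30, seed=2)

        def support_map(tree):
            full = tree.leaf_names()
            ref = min(full)
            out = {}
            def walk(node):
                for c in node.children:
                    if not c.is_leaf:
                        clade = c.clade_names()
                        canon = clade if ref not in clade else full - clade
                        out[canon] = c.support
                        walk(c)
            walk(tree.root)
            return out
        assert support_map(t1) == support_map(t2)

    def test_small_vs_large_replicates_consistent(self, small_sim,
                                                  small_sim_aln):
        """Supports from a 20-replicate run sit within binomial error of a
        400-replicate run on the same alignment."""
        t_small = bootstrap_supports(small_sim_aln, n_reps=20, seed=5)
        t_big = bootstrap_supports(small_sim_aln, n_reps=400, seed=6)

        def support_map(tree):
            full = tree.leaf_names()
            ref = min(full)
            out = {}
            def walk(node):
                for c in node.children:
                    if not c.is_leaf:
                        clade = c.clade_names()
                        canon = clade if ref not in clade else full - clade
                        if c.support is not None:
                            out[canon] = c.support
                        walk(c)
            walk(tree.root)
            return out

        s_small, s_big = support_map(t_small), support_map(t_big)
        for bp in set(s_small) & set(s_big):
            p = s_big[bp] / 100.0
            # three binomial standard errors at n=20, floor of 10 points
            tol = max(10.0, 300.0 * np.sqrt(p * (1 - p) / 20))
            assert abs(s_small[bp] - s_big[bp]) <= tol, bp


class TestRooting:
    def test_single_outgroup_bisects_pendant_edge(self):
        D = np.array([
            [0.0, 0.02, 0.1, 0.3],
            [0.02, 0.0, 0.1, 0.3],
            [0.1, 0.1, 0.0, 0.3],
            [0.3, 0.3, 0.3, 0.0]])
        tree = nj_tree(_dm(["a", "b", "c", "og"], D))
        rooted = root_at_outgroup(tree, ["og"])
        assert rooted.rooted
        sides = [c.clade_names() for c in rooted.root.children]
        assert frozenset({"og"}) in sides
        og_node = next(c for c in rooted.root.children
                       if c.clade_names() == {"og"})
        other = next(c for c in rooted.root.children if c is not og_node)
        # the root bisects the outgroup's pendant edge
        assert og_node.length == pytest.approx(other.length)
        assert og_node.length > 0

    def test_two_leaf_outgroup_roots_on_stem(self):
        ids = ["a", "b", "o1", "o2"]
        D = np.array([
            [0.0, 0.02, 0.3, 0.3],
            [0.02, 0.0, 0.3, 0.3],
            [0.3, 0.3, 0.0, 0.02],
            [0.3, 0.3, 0.02, 0.0]])
        rooted = root_at_outgroup(nj_tree(_dm(ids, D)), ["o1", "o2"])
        sides = [c.clade_names() for c in rooted.root.children]
        assert frozenset({"o1", "o2"}) in sides

    def test_non_monophyletic_outgroup_warns_and_falls_back(self):
        ids = ["a", "o1", "b", "o2"]
        # o1 groups with a, o2 with b: outgroup cannot be monophyletic
        D = np.array([
            [0.0, 0.02, 0.3, 0.3],
            [0.02, 0.0, 0.3, 0.3],
            [0.3, 0.3, 0.0, 0.02],
            [0.3, 0.3, 0.02, 0.0]])
        tree = nj_tree(_dm(ids, D))
        with pytest.warns(UserWarning, match="not monophyletic"):
            rooted = root_at_outgroup(tree, ["o1", "o2"])
        assert rooted.leaf_names() == {"a", "b", "o1", "o2"}

    def test_missing_outgroup_id_errors(self):
        dm = _dm("ABC", [[0, 3, 4], [3, 0, 5], [4, 5, 0]])
        with pytest.raises(ValueError, match="absent"):
            root_at_outgroup(nj_tree(dm), ["nope"])


class TestNewick:
    def test_round_trip_through_dendropy(self, tmp_path):
        dm = _dm("ABCD", [[0, 3, 5, 6], [3, 0, 6, 7],
                          [5, 6, 0, 7], [6, 7, 7, 0]])
        tree = nj_tree(dm)
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert back.leaf_names() == tree.leaf_names()
        assert back.bipartitions() == tree.bipartitions()
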