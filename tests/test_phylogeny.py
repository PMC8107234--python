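import itertools

import numpy as np
import pandas as pd
import pytest

from cladepan.pangenome import OrthogroupMatrix
from cladepan.phylogeny import (
    family_distance_matrix,
    neighbor_joining,
    rf_distance,
    root_with_outgroup,
    single_copy_core,
)
from cladepan.tree import PhyloTree


def _random_additive_matrix(rng, n_taxa):
    """Distances realised on a random binary tree: exactly additive."""
    nodes = [(f"t{i}",) for i in range(n_taxa)]
    paths = {(f"t{i}",): {f"t{i}": 0.0} for i in range(n_taxa)}
    dist = {}
    clusters = [{f"t{i}": 0.0} for i in range(n_taxa)]
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        a, b = clusters[i], clusters[j]
        la, lb = rng.uniform(0.1, 1.0), rng.uniform(0.1, 1.0)
        for leaf_a, da in a.items():
            for leaf_b, db in b.items():
                dist[tuple(sorted((leaf_a, leaf_b)))] = da + la + db + lb
        merged = {leaf: d + la for leaf, d in a.items()}
        merged.update({leaf: d + lb for leaf, d in b.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    names = [f"t{i}" for i in range(n_taxa)]
    frame = pd.DataFrame(0.0, index=names, columns=names)
    for (a, b), d in dist.items():
        frame.loc[a, b] = frame.loc[b, a] = d
    return frame


def _tree_distances(tree):
    depths = tree.depths()
    leaves = tree.leaf_names()
    parents = {}
    for parent, child in tree.branches():
        parents[child.name] = parent.name
    out = {}
    for a, b in itertools.combinations(leaves, 2):
        lca = tree.lca(a, b)
        out[(a, b)] = depths[a] + depths[b] - 2 * depths[lca.name]
    return out


class TestSingleCopyCore:
    def test_selection_rules(self):
        frame = pd.DataFrame(
            {"g1": [1, 2, 1, 0], "g2": [1, 1, 1, 1], "g3": [1, 1, 0, 1]},
            index=["ok", "dup", "absent", "missing_g1"],
        )
        matrix = OrthogroupMatrix(frame, {})
        assert single_copy_core(matrix) == ["ok"]

    def test_empty_result_is_an_error(self):
        frame = pd.DataFrame({"g1": [2], "g2": [1]}, index=["dup"])
        with pytest.raises(ValueError, match="smaller"):
            single_copy_core(OrthogroupMatrix(frame, {}))


class TestDistanceMatrix:
    def test_identical_genomes_distance_zero(self):
        seqs = {"gA": {"f1": "MKVLA" * 20}, "gB": {"f1": "MKVLA" * 20}}
        dist = family_distance_matrix(["f1"], seqs)
        assert dist.loc["gA", "gB"] == 0.0

    def test_uniform_ten_percent_substitution(self):
        rng = np.random.default_rng(6)
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        seq_a = {}
        seq_b = {}
        for f in range(10):
            seq = rng.choice(alphabet, 300)
            copy = seq.copy()
            pos = rng.choice(300, size=30, replace=False)
            for p in pos:
                options = [c for c in alphabet if c != copy[p]]
                copy[p] = options[int(rng.integers(len(options)))]
            seq_a[f"f{f}"] = "".join(seq)
            seq_b[f"f{f}"] = "".join(copy)
        dist = family_distance_matrix(
            [f"f{f}" for f in range(10)], {"gA": seq_a, "gB": seq_b}
        )
        assert dist.loc["gA", "gB"] == pytest.approx(0.10, abs=0.01)

    def test_missing_sequence_rejected(self):
        with pytest.raises(ValueError):
            family_distance_matrix(["f1"], {"gA": {"f1": "MKV"}, "gB": {}})


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        frame = pd.DataFrame(
            [[0, 5, 9], [5, 0, 10], [9, 10, 0]], index=list("ABC"), columns=list("ABC"), dtype=float
        )
        tree = neighbor_joining(frame)
        lengths = {leaf.name: leaf.length for leaf in tree.leaves()}
        assert lengths["A"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["B"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["C"] == pytest.approx((9 + 10 - 5) / 2)

    def test_four_taxon_additive_split_recovered(self):
        frame = pd.DataFrame(
            [[0, 3, 7, 8], [3, 0, 6, 7], [7, 6, 0, 3], [8, 7, 3, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        tree = neighbor_joining(frame)
        reference = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert rf_distance(tree, reference) == 0

    def test_recovers_topology_on_random_additive_matrices(self):
        rng = np.random.default_rng(17)
        for trial in range(50):
            frame = _random_additive_matrix(rng, 8)
            tree = neighbor_joining(frame)
            realized = _tree_distances(tree)
            for (a, b), want in realized.items():
                assert frame.loc[a, b] == pytest.approx(want, abs=1e-9), trial

    def test_matches_external_nj_oracle(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj

        from io import StringIO

        rng = np.random.default_rng(23)
        frame = _random_additive_matrix(rng, 7)
        ours = neighbor_joining(frame)
        theirs = skbio_nj(SkbioDM(frame.to_numpy(), ids=list(frame.index)))
        buf = StringIO()
        theirs.write(buf, format="newick")
        their_tree = PhyloTree.from_newick(buf.getvalue().strip().replace("'", ""))
        assert rf_distance(ours, their_tree) == 0

    def test_too_few_taxa_rejected(self):
        frame = pd.DataFrame([[0, 1], [1, 0]], index=list("AB"), columns=list("AB"), dtype=float)
        with pytest.raises(ValueError):
            neighbor_joining(frame)


class TestRooting:
    def test_leaf_set_preserved_and_one_extra_node(self):
        tree = neighbor_joining(
            pd.DataFrame(
                [[0, 2, 7, 8], [2, 0, 7, 8], [7, 7, 0, 3], [8, 8, 3, 0]],
                index=list("ABCO"), columns=list("ABCO"), dtype=float,
            )
        )
        n_unrooted = sum(1 for _ in tree.postorder())
        rooted = root_with_outgroup(tree, "O")
        assert sorted(rooted.leaf_names()) == ["A", "B", "C", "O"]
        assert sum(1 for _ in rooted.postorder()) == n_unrooted + 1
        assert rooted.rooted and len(rooted.root.children) == 2

    def test_outgroup_bipartition_matches_truth(self, small_clade):
        records, truth = small_clade
        dists = _tree_distances(truth.tree)
        names = sorted(truth.tree.leaf_names())
        frame = pd.DataFrame(0.0, index=names, columns=names)
        for (a, b), d in dists.items():
            frame.loc[a, b] = frame.loc[b, a] = d
        # attach a synthetic outgroup equidistant from everything
        for name in names:
            frame.loc[name, "OUT"] = frame.loc["OUT", name] = 2.0
        frame.loc["OUT", "OUT"] = 0.0
        rooted = root_with_outgroup(neighbor_joining(frame), "OUT")
        ingroup_child = [c for c in rooted.root.children if c.name != "OUT"]
        assert len(ingroup_child) == 1
        sub_leaves = set()
        stack = [ingroup_child[0]]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                sub_leaves.add(node.name)
            stack.extend(node.children)
        assert sub_leaves == set(names)

    def test_unrooting_and_rerooting_is_stable(self):
        frame = pd.DataFrame(
            [[0, 3, 7, 8], [3, 0, 6, 7], [7, 6, 0, 3], [8, 7, 3, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        tree = neighbor_joining(frame)
        r1 = root_with_outgroup(tree, "D")
        r2 = root_with_outgroup(r1, "D")
        assert rf_distance(r1, r2) == 0

    def test_missing_outgroup_rejected(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError):
            root_with_outgroup(tree, "Z")


class TestRfDistance:
    def test_identical_trees_zero(self):
        t = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        assert rf_distance(t, t.copy()) == 0

    def test_conflicting_four_leaf_topologies(self):
        t1 = PhyloTree.from_newick("((A,B),(C,D));")
        t2 = PhyloTree.from_newick("((A,C),(B,D));")
        assert rf_distance(t1, t2) == 2

    def test_leaf_set_mismatch_rejected(self):
        t1 = PhyloTree.from_newick("((A,B),C);")
        t2 = PhyloTree.from_newick("((A,B),D);")
        with pytest.raises(ValueError):
            rf_distance(t1, t2)

    def test_agrees_with_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        n1 = "((A:1,B:1):1,((C:1,D:1):1,E:2):1);"
        n2 = "((A:1,C:1):1,((B:1,D:1):1,E:2):1);"
        t1, t2 = PhyloTree.from_newick(n1), PhyloTree.from_newick(n2)
        taxa = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=n1, schema="newick", taxon_namespace=taxa)
        d2 = dendropy.Tree.get(data=n2, schema="newick", taxon_namespace=taxa)
        expected = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert rf_distance(t1, t2) == expected
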