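import dendropy
import numpy as np
import pytest

from helpers_oracles import random_tree_distances, tree_bipartitions
from hemescan.phylo import (
    DistanceMatrix,
    bootstrap_support,
    is_monophyletic,
    leaf_labels,
    nj_tree,
    p_distance,
    root_with_outgroup,
)


class TestPDistance:
    def test_identical_rows(self):
        dm = p_distance({"a": "ACGT", "b": "ACGT"})
        assert dm.matrix[0, 1] == 0.0

    def test_quarter_difference(self):
        dm = p_distance({"a": "ACGT", "b": "ACGA"})
        assert dm.matrix[0, 1] == 0.25

    def test_gap_columns_excluded(self):
        dm = p_distance({"a": "AC-T", "b": "ACGA"})
        assert dm.matrix[0, 1] == pytest.approx(1 / 3)

    def test_no_comparable_columns_raises(self):
        with pytest.raises(ValueError):
            p_distance({"a": "A--", "b": "-CC"})

    def test_jukes_cantor_exceeds_p(self):
        p = p_distance({"a": "AAAA", "b": "AAAC"}).matrix[0, 1]
        jc = p_distance({"a": "AAAA", "b": "AAAC"}, correction="jc").matrix[0, 1]
        assert jc > p


class TestNeighborJoining:
    def test_four_taxon_additive_exact(self):
        # distances from ((A:1,B:2):1,(C:3,D:4):1)
        labels = ("A", "B", "C", "D")
        mat = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = nj_tree(DistanceMatrix(labels, mat))
        assert tree_bipartitions(tree, labels) == {frozenset({"C", "D"})}
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths == {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}

    def test_three_taxon_closed_form(self):
        mat = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(("a", "b", "c"), mat))
        lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
        assert lengths == {"a": 1.0, "b": 2.0, "c": 3.0}

    def test_recovers_random_additive_topologies(self):
        """NJ is consistent on additive matrices (100 random trees, n<=8)."""
        rng = np.random.default_rng(77)
        for trial in range(100):
            n = int(rng.integers(4, 9))
            labels, mat, true_bips = random_tree_distances(n, rng)
            tree = nj_tree(DistanceMatrix(tuple(labels), mat))
            assert tree_bipartitions(tree, labels) == true_bips, trial

    def test_label_order_invariance(self):
        rng = np.random.default_rng(5)
        labels, mat, _ = random_tree_distances(7, rng)
        perm = rng.permutation(7)
        tree1 = nj_tree(DistanceMatrix(tuple(labels), mat))
        tree2 = nj_tree(
            DistanceMatrix(tuple(labels[i] for i in perm), mat[np.ix_(perm, perm)])
        )
        assert tree_bipartitions(tree1, labels) == tree_bipartitions(tree2, labels)

    def test_agrees_with_skbio(self):
        """Independent cross-check against scikit-bio's NJ on random
        additive matrices."""
        skbio_nj = pytest.importorskip("skbio.tree").nj
        from skbio import DistanceMatrix as SkbioDM

        rng = np.random.default_rng(13)
        for _ in range(10):
            labels, mat, _ = random_tree_distances(6, rng)
            ours = tree_bipartitions(nj_tree(DistanceMatrix(tuple(labels), mat)), labels)
            sk = skbio_nj(SkbioDM(mat, ids=labels))
            sk_tree = dendropy.Tree.get(data=str(sk), schema="newick", preserve_underscores=True)
            assert ours == tree_bipartitions(sk_tree, labels)


FIXTURE = "((A:1,B:1):1,((C:1,D:1):1,E:2):1,F:4);"


def fixture_tree(rooted=False):
    t = dendropy.Tree.get(data=FIXTURE, schema="newick", preserve_underscores=True)
    t.is_rooted = rooted
    return t


class TestRootingAndMonophyly:
    def test_root_with_outgroup_splits_tree(self):
        rooted = root_with_outgroup(fixture_tree(), ["F"])
        kids = rooted.seed_node.child_nodes()
        sides = [sorted(l.taxon.label for l in k.leaf_iter()) for k in kids]
        assert ["F"] in sides
        assert sorted(leaf_labels(rooted)) == list("ABCDEF")

    def test_outgroup_not_a_clade_raises(self):
        with pytest.raises(ValueError):
            root_with_outgroup(fixture_tree(), ["A", "C"])

    def test_missing_outgroup_raises(self):
        with pytest.raises(ValueError):
            root_with_outgroup(fixture_tree(), ["Z"])

    def test_monophyly_enumeration_matches_hand_reading(self):
        rooted = root_with_outgroup(fixture_tree(), ["F"])
        assert is_monophyletic(rooted, ["A", "B"])
        assert is_monophyletic(rooted, ["C", "D"])
        assert is_monophyletic(rooted, ["C", "D", "E"])
        assert not is_monophyletic(rooted, ["A", "C"])
        assert not is_monophyletic(rooted, ["B", "C", "D"])

    def test_single_tip_and_full_set(self):
        rooted = root_with_outgroup(fixture_tree(), ["F"])
        assert is_monophyletic(rooted, ["E"])
        assert is_monophyletic(rooted, list("ABCDEF"))


class TestBootstrap:
    def test_supports_on_clean_signal(self, rng):
        """A long alignment with two obvious groups gets high support."""
        block_a = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        block_b = "".join("ACGT"[i] for i in rng.integers(0, 4, 120))
        def noisy(block, k):
            s = list(block)
            for i in rng.integers(0, 120, 4 + k):
                s[i] = "ACGT"[rng.integers(4)]
            return "".join(s)
        rows = {f"a{k}": noisy(block_a, k) for k in range(3)}
        rows.update({f"b{k}": noisy(block_b, k) for k in range(3)})
        tree = bootstrap_support(rows, replicates=50, seed=4)
        supports = [
            float(n.label)
            for n in tree.preorder_node_iter()
            if n.label and not n.is_leaf()
        ]
        assert supports and max(supports) >= 0.9
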