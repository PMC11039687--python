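import numpy as np
import pytest
from skbio import TreeNode

from edcscan.alignment import progressive_align
from edcscan.io_formats import translate
from edcscan.phylogenetics import (
    bootstrap_support,
    canonical_bipartition,
    is_monophyletic,
    neighbor_joining,
    pdistance_matrix,
    tree_bipartitions,
)
from edcscan.synthetic_edc import amplify_tandem


def random_additive_tree(n, rng):
    nodes = [TreeNode(name=f"L{i}") for i in range(n)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.5, 2))
        b.length = float(rng.uniform(0.5, 2))
        p = TreeNode()
        p.append(b)
        p.append(a)
        nodes = [x for k, x in enumerate(nodes) if k not in (i, j)] + [p]
    root = TreeNode()
    for x in nodes:
        x.length = float(rng.uniform(0.5, 2))
        root.append(x)
    return root


def distances_from_tree(tree):
    labels = [t.name for t in tree.tips()]
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tree.find(labels[i]).distance(tree.find(labels[j]))
    return labels, d


class TestPDistance:
    def test_identical_sequences_zero(self):
        labels, d = pdistance_matrix({"a": "AAAA", "b": "AAAA", "c": "AAAA"})
        assert d.sum() == 0

    def test_half_mismatches(self):
        labels, d = pdistance_matrix({"a": "AAAA", "b": "AATT", "c": "AAAA"})
        i, j = labels.index("a"), labels.index("b")
        assert d[i, j] == 0.5

    def test_pairwise_deletion_of_gaps(self):
        labels, d = pdistance_matrix({"a": "A-AA", "b": "ATAT", "c": "AAAA"})
        i, j = labels.index("a"), labels.index("b")
        assert d[i, j] == pytest.approx(1 / 3)

    def test_fully_gapped_pair_rejected(self):
        with pytest.raises(ValueError):
            pdistance_matrix({"a": "--AA", "b": "TT--", "c": "AAAA"})

    def test_symmetry_zero_diagonal(self, rng):
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACGT"), 50)) for i in range(5)
        }
        _, d = pdistance_matrix(seqs)
        assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)


class TestNeighborJoining:
    def test_four_point_example(self):
        # additive matrix from tree ((A:1,B:1):1,(C:1,D:1))
        labels = ["A", "B", "C", "D"]
        d = np.array(
            [[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], float
        )
        tree = neighbor_joining(labels, d)
        assert tree_bipartitions(tree) == {frozenset({"A", "B"})}

    def test_three_leaves_star(self):
        labels = ["A", "B", "C"]
        d = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], float)
        tree = neighbor_joining(labels, d)
        assert {t.name for t in tree.tips()} == set(labels)
        # closed-form three-point branch lengths: a=1, b=1, c=2
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["C"] == pytest.approx(2.0)

    def test_row_permutation_invariance(self, rng):
        tree = random_additive_tree(6, rng)
        labels, d = distances_from_tree(tree)
        t1 = neighbor_joining(labels, d)
        perm = list(rng.permutation(len(labels)))
        t2 = neighbor_joining([labels[i] for i in perm], d[np.ix_(perm, perm)])
        assert tree_bipartitions(t1) == tree_bipartitions(t2)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(["a", "b", "c"], np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0.0]]))

    def test_additive_recovery_random_trees(self, rng):
        ok = 0
        for _ in range(30):
            tree = random_additive_tree(int(rng.integers(5, 9)), rng)
            labels, d = distances_from_tree(tree)
            nj_tree = neighbor_joining(labels, d)
            ok += tree_bipartitions(nj_tree) == tree_bipartitions(tree)
        assert ok == 30


class TestMonophyly:
    def tree(self):
        return TreeNode.read(["((A:1,B:1):1,(C:1,D:1):1);"])

    def test_clade_found(self):
        flag, _ = is_monophyletic(self.tree(), {"A", "B"}, "D")
        assert flag

    def test_non_clade_rejected(self):
        flag, _ = is_monophyletic(self.tree(), {"A", "C"}, "D")
        assert not flag

    def test_singleton_trivially_true(self):
        flag, _ = is_monophyletic(self.tree(), {"A"}, "D")
        assert flag

    def test_outgroup_in_set_rejected(self):
        with pytest.raises(ValueError):
            is_monophyletic(self.tree(), {"A", "D"}, "D")


class TestBootstrap:
    def make_alignment(self, rng, n_copies=8, divergence=0.02, og_div=0.30):
        founder_prot = "M" + "".join(rng.choice(list("CQKPSGVAHT"), 99))
        from edcscan.synthetic_edc import _encode

        founder = _encode(founder_prot, rng)

        def plain(seq, rate, r):
            s = list(seq)
            for p in np.nonzero(r.random(len(s)) < rate)[0]:
                alts = [b for b in "ACGT" if b != s[p]]
                s[p] = alts[r.integers(0, 3)]
            return "".join(s)

        outgroups = {f"OG{i}": plain(founder, og_div, rng) for i in (1, 2, 3)}
        copies, _ = amplify_tandem(founder, n_copies, divergence, rng)
        seqs = {n: translate(s) for n, s in copies}
        seqs |= {k: translate(v) for k, v in outgroups.items()}
        return progressive_align(seqs), {n for n, _ in copies}

    def test_array_clade_supported(self, rng):
        aln, array = self.make_alignment(rng)
        tree, supports, informative = bootstrap_support(aln, 100, seed=7)
        assert informative
        flag, _ = is_monophyletic(tree, array, "OG1")
        assert flag
        canon = canonical_bipartition(frozenset(aln), frozenset(array))
        assert supports[canon] >= 70.0

    def test_deterministic_given_seed(self, rng):
        aln, _ = self.make_alignment(rng)
        _, s1, _ = bootstrap_support(aln, 50, seed=3)
        _, s2, _ = bootstrap_support(aln, 50, seed=3)
        assert s1 == s2

    def test_identical_sequences_flagged_uninformative(self):
        aln = {f"s{i}": "MKVLE" * 10 for i in range(5)}
        _, supports, informative = bootstrap_support(aln, 20, seed=1)
        assert not informative
        assert all(v == 0.0 for v in supports.values())
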