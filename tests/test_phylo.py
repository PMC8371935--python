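import math

import numpy as np
import pytest

from melcensus.phylo import (
    GeneTree,
    bootstrap_support,
    check_monophyly,
    kimura_distance,
    nj_tree,
    parse_newick,
    progressive_msa,
    protein_distance,
)
from melcensus.simulate import evolve_protein_coding, random_cds
from melcensus.core_io import translate
from tests.oracles import (
    four_taxon_split_oracle,
    random_additive_tree,
    tree_splits,
)


class TestKimuraDistance:
    def test_identical_sequences_zero(self):
        assert protein_distance("MKLVW", "MKLVW") == 0.0

    def test_closed_form_at_p_ten_percent(self):
        # -ln(1 - 0.1 - 0.2*0.01) = 0.107580...
        assert kimura_distance(0.1) == pytest.approx(-math.log(0.898), abs=1e-12)
        a = "A" * 90 + "C" * 10
        b = "A" * 90 + "D" * 10
        assert protein_distance(a, b) == pytest.approx(-math.log(0.898))

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(0)
        aas = list("ARNDCQEGHILKMFPSTWYV")
        for _ in range(10):
            a = "".join(rng.choice(aas, size=50))
            b = "".join(rng.choice(aas, size=50))
            assert protein_distance(a, b) == protein_distance(b, a)

    def test_saturation_capped(self):
        a = "A" * 100
        b = "C" * 100
        assert protein_distance(a, b) == 10.0

    def test_gapped_columns_excluded(self):
        assert protein_distance("MK-V", "MKLV") == 0.0


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        D = np.array([[0.0, 5.0, 9.0], [5.0, 0.0, 8.0], [9.0, 8.0, 0.0]])
        tree = nj_tree(D, ["a", "b", "c"])
        lengths = {n.name: n.length for n in tree.root.children}
        assert lengths["a"] == pytest.approx((5 + 9 - 8) / 2, abs=1e-9)
        assert lengths["b"] == pytest.approx((5 + 8 - 9) / 2, abs=1e-9)
        assert lengths["c"] == pytest.approx((9 + 8 - 5) / 2, abs=1e-9)

    def test_four_taxon_additive_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            labels, D, true_splits = random_additive_tree(rng, 4)
            tree = nj_tree(D, labels)
            got = tree_splits(tree.root, labels)
            assert got == {four_taxon_split_oracle(D, labels)} == true_splits

    def test_additive_topology_recovery_up_to_eight_taxa(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(5, 9))
            labels, D, true_splits = random_additive_tree(rng, n)
            tree = nj_tree(D, labels)
            assert tree_splits(tree.root, labels) == true_splits

    def test_agrees_with_skbio_on_additive_matrix(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        labels, D, true_splits = random_additive_tree(rng, 8)
        mine = tree_splits(nj_tree(D, labels).root, labels)
        sk_tree = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        sk_splits = set()
        for node in sk_tree.non_tips():
            tips = frozenset(t.name for t in node.tips())
            if 1 < len(tips) < len(labels) - 1:
                sk_splits.add(tips)
        canon = lambda ss: {
            frozenset(set(labels) - set(s)) if labels[0] in s else frozenset(s)
            for s in ss
        }
        assert canon(sk_splits) == mine == true_splits

    def test_ultrametric_matrix_matches_nested_clusters(self):
        labels = list("abcdef")
        # clusters: ((a,b),(c,d)) at depths 1 < 2, (e,f) at 1, root depth 3
        D = np.full((6, 6), 6.0)
        np.fill_diagonal(D, 0.0)
        for i, j in [(0, 1), (2, 3), (4, 5)]:
            D[i, j] = D[j, i] = 2.0
        for i in (0, 1):
            for j in (2, 3):
                D[i, j] = D[j, i] = 4.0
        splits = tree_splits(nj_tree(D, labels).root, labels)
        assert frozenset({"c", "d"}) in splits
        assert frozenset({"e", "f"}) in splits
        assert frozenset({"c", "d", "e", "f"}) in splits or frozenset({"a", "b", "c", "d"}) in {
            frozenset(set(labels) - set(s)) for s in splits
        } | splits

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 1.0, 2.0], [1.1, 0.0, 1.0], [2.0, 1.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(D, list("abc"))

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.zeros((2, 2)), ["a", "b"])

    def test_outgroup_rooting(self):
        rng = np.random.default_rng(4)
        labels, D, _ = random_additive_tree(rng, 6)
        tree = nj_tree(D, labels, outgroup=labels[-1])
        assert len(tree.root.children) == 2
        sides = [set(c.leaves()) for c in tree.root.children]
        assert {labels[-1]} in sides


class TestMonophyly:
    @pytest.fixture()
    def tree(self):
        return GeneTree(parse_newick("(((a:1,b:1):1,c:1):1,d:1);"))

    def test_full_leaf_set_true(self, tree):
        assert check_monophyly(tree, {"a", "b", "c", "d"})

    def test_singleton_true(self, tree):
        assert check_monophyly(tree, {"c"})

    def test_clade_and_non_clade(self, tree):
        assert check_monophyly(tree, {"a", "b"})
        assert not check_monophyly(tree, {"b", "c"})

    def test_unknown_leaf_rejected(self, tree):
        with pytest.raises(ValueError, match="unknown"):
            check_monophyly(tree, {"a", "zzz"})


class TestBootstrap:
    def _family_msa(self, seed=5):
        """Two clearly separated clades of 3 sequences each."""
        rng = np.random.default_rng(seed)
        root = random_cds(rng, 120)
        anc_a = evolve_protein_coding(root, 0.25, rng)
        anc_b = evolve_protein_coding(root, 0.25, rng)
        seqs = {}
        for i in range(3):
            seqs[f"a{i}"] = translate(evolve_protein_coding(anc_a, 0.04, rng))[:-1]
            seqs[f"b{i}"] = translate(evolve_protein_coding(anc_b, 0.04, rng))[:-1]
        return progressive_msa(seqs)

    def test_clear_clades_get_high_support(self):
        labels, rows = self._family_msa()
        tree = bootstrap_support(rows, labels, 50, seed=1, outgroup="b0")
        a_clade = {"a0", "a1", "a2"}
        assert check_monophyly(tree, a_clade)

        def find(node):
            if set(node.leaves()) == a_clade:
                return node.support
            for c in node.children:
                r = find(c)
                if r is not None:
                    return r
            return None

        assert find(tree.root) >= 90.0

    def test_same_seed_reproduces_supports(self):
        labels, rows = self._family_msa()
        t1 = bootstrap_support(rows, labels, 30, seed=9)
        t2 = bootstrap_support(rows, labels, 30, seed=9)
        assert t1.newick() == t2.newick()

    def test_replicate_count_validated(self):
        labels, rows = self._family_msa()
        with pytest.raises(ValueError):
            bootstrap_support(rows, labels, 0, seed=1)


class TestProgressiveMsa:
    def test_identical_sequences_align_gapless(self):
        seqs = {f"s{i}": "MKLVWAAR" * 5 for i in range(4)}
        labels, rows = progressive_msa(seqs)
        assert all(r == rows[0] and "-" not in r for r in rows)

    def test_degapped_rows_reproduce_inputs(self):
        rng = np.random.default_rng(6)
        root = random_cds(rng, 80)
        seqs = {
            f"s{i}": translate(evolve_protein_coding(root, 0.1, rng))[:-1]
            for i in range(5)
        }
        labels, rows = progressive_msa(seqs)
        assert len({len(r) for r in rows}) == 1
        for lab, row in zip(labels, rows):
            assert row.replace("-", "") == seqs[lab]


def test_newick_round_trip():
    text = "((a:0.1,b:0.2)95:0.05,(c:0.3,d:0.1)80:0.02,e:0.4);"
    tree = parse_newick(text)
    assert sorted(tree.leaves()) == list("abcde")
    back = parse_newick(tree.newick())
    assert sorted(back.leaves()) == list("abcde")
    assert back.children[0].support in (95.0, 80.0)
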