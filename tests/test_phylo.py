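import math
import random

import numpy as np
import pytest

from oracles import random_additive_tree
from taxogenomics.phylo import (
    DistanceMatrix,
    bootstrap_consensus,
    distance_from_msa,
    neighbor_joining,
    read_newick,
    write_newick,
)


class TestDistanceFromMsa:
    def test_identical_rows_give_zero(self):
        msa = [(x, "ACGTACGTAC") for x in "ABC"]
        assert (distance_from_msa(msa).d == 0).all()

    def test_p_distance_arithmetic(self):
        msa = [("A", "AAAAAAAAAA"), ("B", "AACCAAAAAA"), ("C", "AAAAAAAAAA")]
        dm = distance_from_msa(msa, "p_distance")
        assert dm.d[0, 1] == pytest.approx(0.2)

    def test_jukes_cantor_closed_form(self):
        msa = [("A", "AAAAAAAAAA"), ("B", "AACCAAAAAA"), ("C", "AAAAAAAAAA")]
        dm = distance_from_msa(msa, "jukes_cantor")
        expected = -0.75 * math.log(1 - 4 / 3 * 0.2)
        assert dm.d[0, 1] == pytest.approx(expected)

    def test_kimura_2p_separates_transitions(self):
        # one transition (A<->G) and one transversion (A<->C) in 10 columns
        msa = [("A", "AAAAAAAAAA"), ("B", "GACAAAAAAA"), ("C", "AAAAAAAAAA")]
        dm = distance_from_msa(msa, "kimura_2p")
        P, Q = 0.1, 0.1
        expected = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert dm.d[0, 1] == pytest.approx(expected)

    def test_pairwise_deletion_skips_gapped_columns(self):
        msa = [("A", "A-GT"), ("B", "ACGT"), ("C", "ACGT")]
        dm = distance_from_msa(msa)
        assert dm.d[0, 1] == 0.0  # gap column excluded, remaining 3 identical

    def test_unequal_row_lengths_rejected(self):
        with pytest.raises(ValueError, match="unequal"):
            distance_from_msa([("A", "ACG"), ("B", "AC"), ("C", "ACG")])

    def test_all_gap_pair_names_the_pair(self):
        msa = [("A", "--GT"), ("B", "AC--"), ("C", "ACGT")]
        with pytest.raises(ValueError, match="'A', 'B'"):
            distance_from_msa(msa)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        tree = neighbor_joining(DistanceMatrix(["A", "B", "C"], d))
        pm = tree.patristic_matrix(["A", "B", "C"])
        assert np.allclose(pm, d)

    def test_four_taxon_additive_matrix_recovered_exactly(self):
        # tree ((A:1,B:2):5,(C:3,D:4))
        d = np.array(
            [[0, 3, 9, 10], [3, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]], float
        )
        ids = ["A", "B", "C", "D"]
        tree = neighbor_joining(DistanceMatrix(ids, d))
        assert np.allclose(tree.patristic_matrix(ids), d)
        assert tree.bipartitions() == {frozenset({"A", "B"})}

    def test_additive_matrices_inverted_up_to_8_taxa(self):
        rng = random.Random(17)
        for _ in range(30):
            n = rng.randint(4, 8)
            ids, d = random_additive_tree(n, rng)
            tree = neighbor_joining(DistanceMatrix(ids, d))
            assert np.allclose(tree.patristic_matrix(ids), d, atol=1e-9)

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float)))

    def test_negative_branch_lengths_clamped(self):
        # non-additive matrix that drives a negative length estimate
        d = np.array([[0, 1, 8, 8], [1, 0, 8, 8], [8, 8, 0, 1], [8, 8, 1, 0]], float)
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), d))
        for edge in tree.tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0


class TestBootstrapConsensus:
    msa_signal = [
        ("A", "G" * 10 + "A" * 10),
        ("B", "G" * 10 + "A" * 10),
        ("C", "T" * 10 + "C" * 10),
        ("D", "T" * 10 + "C" * 10),
    ]

    def test_unambiguous_split_supported_at_100(self):
        tree = bootstrap_consensus(self.msa_signal, n_replicates=100, seed=5)
        assert tree.supports() == {frozenset({"A", "B"}): 100}

    def test_identical_sequences_give_unresolved_star(self):
        msa = [(x, "ACGTACGT") for x in "ABCDE"]
        tree = bootstrap_consensus(msa, n_replicates=50, seed=5)
        assert tree.bipartitions() == set()

    def test_same_seed_reproduces_supports(self):
        t1 = bootstrap_consensus(self.msa_signal, n_replicates=40, seed=9)
        t2 = bootstrap_consensus(self.msa_signal, n_replicates=40, seed=9)
        assert t1.supports() == t2.supports()
        assert t1.newick() == t2.newick()

    def test_supports_invariant_under_taxon_order(self):
        t1 = bootstrap_consensus(self.msa_signal, n_replicates=60, seed=3)
        t2 = bootstrap_consensus(self.msa_signal[::-1], n_replicates=60, seed=3)
        assert t1.supports() == t2.supports()

    def test_single_replicate_matches_point_estimate_topology(self):
        point = neighbor_joining(distance_from_msa(self.msa_signal))
        boot = bootstrap_consensus(self.msa_signal, n_replicates=1, seed=0)
        assert boot.bipartitions() == point.bipartitions()


class TestNewickIO:
    def test_round_trip_preserves_tree(self, tmp_path):
        ids, d = random_additive_tree(6, random.Random(23))
        tree = neighbor_joining(DistanceMatrix(ids, d))
        path = tmp_path / "t.nwk"
        write_newick(tree, path)
        back = read_newick(path)
        assert back.bipartitions() == tree.bipartitions()
        assert np.allclose(back.patristic_matrix(ids), tree.patristic_matrix(ids), atol=1e-6)

    def test_parse_fixed_topology(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("(A:1,B:2,(C:3,D:4):5);\n")
        tree = read_newick(path)
        assert sorted(tree.taxon_labels) == ["A", "B", "C", "D"]
        # the C|D split, normalized to its lexicographically smaller side
        assert tree.bipartitions() == {frozenset({"A", "B"})}
        pm = tree.patristic_matrix(["C", "D"])
        assert pm[0, 1] == pytest.approx(7.0)

    def test_unbalanced_parenthesis_is_parse_error(self, tmp_path):
        path = tmp_path / "bad.nwk"
        path.write_text("((A:1,B:2,(C:3);\n")
        with pytest.raises(ValueError, match="malformed newick"):
            read_newick(path)

    def test_outgroup_rooting_preserves_leaves(self, tmp_path):
        ids, d = random_additive_tree(5, random.Random(4))
        tree = neighbor_joining(DistanceMatrix(ids, d))
        rooted = tree.rooted_on(ids[0])
        assert sorted(rooted.taxon_labels) == sorted(ids)
        with pytest.raises(ValueError, match="not found"):
            tree.rooted_on("nope")
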