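import math

import numpy as np
import pytest

from marinitax.phylo16s import (
    DistanceMatrix,
    PhyloParams,
    SaturationError,
    bipartitions,
    bootstrap_supports,
    distance_matrix,
    neighbor_joining,
    pairwise_identity_16s,
)
from marinitax.seq_io import SequenceRecord, read_newick, write_newick
from marinitax.synthetic_data import (
    additive_distance_matrix,
    evolve_alignment,
    random_tree,
)


def rec(seq, rid="x"):
    return SequenceRecord(id=rid, sequence=seq)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity_16s(rec("ACGTACGT", "a"), rec("ACGTACGT", "b")) == 100.0

    def test_three_of_four(self):
        assert pairwise_identity_16s(rec("ACGT", "a"), rec("ACGA", "b")) == 75.0

    def test_gap_columns_excluded_from_denominator(self):
        a = rec("AC-GT", "a")
        b = rec("ACTGT", "b")
        assert pairwise_identity_16s(a, b) == 100.0
        assert pairwise_identity_16s(a, b, include_gaps=True) == pytest.approx(80.0)

    def test_unaligned_input_aligned_first(self):
        a = rec("ACGTACGTACGT", "a")
        b = rec("ACGTACGT", "b")  # same prefix, needs gapping
        assert pairwise_identity_16s(a, b) == 100.0

    def test_no_overlap_is_an_error(self):
        with pytest.raises(ValueError, match="overlap"):
            pairwise_identity_16s(rec("A--", "a"), rec("--T", "b"), aligned=True)


class TestDistanceMatrix:
    def make_aln(self, seqs):
        return [rec(s, f"t{i}") for i, s in enumerate(seqs)]

    def test_identical_sequences_zero_under_every_model(self):
        aln = self.make_aln(["ACGT" * 25] * 4)
        for model in ("p_distance", "JC69", "K2P"):
            dm = distance_matrix(aln, model)
            assert np.all(dm.data == 0.0)

    def test_single_transition_closed_forms(self):
        base = "ACGT" * 25
        mutated = "G" + base[1:]  # A->G transition at site 0
        aln = self.make_aln([base, mutated, base])
        p = 0.01
        dm_p = distance_matrix(aln, "p_distance")
        assert dm_p.data[0, 1] == pytest.approx(p)
        dm_jc = distance_matrix(aln, "JC69")
        assert dm_jc.data[0, 1] == pytest.approx(-0.75 * math.log(1 - 4 * p / 3))
        dm_k2p = distance_matrix(aln, "K2P")
        P, Q = 0.01, 0.0
        expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
        assert dm_k2p.data[0, 1] == pytest.approx(expected)

    def test_saturated_pair_flagged(self):
        # every site differs -> p = 1 > 3/4, JC log argument <= 0
        aln = self.make_aln(["AAAA" * 10, "CCCC" * 10, "AAAA" * 10])
        dm = distance_matrix(aln, "JC69")
        assert dm.saturated[0, 1]
        with pytest.raises(SaturationError):
            neighbor_joining(dm)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            distance_matrix(self.make_aln(["ACGT", "ACG", "ACGT"]))

    def test_symmetry_and_zero_diagonal(self):
        aln = evolve_alignment(random_tree(6, seed=2), 500, seed=3)
        dm = distance_matrix(aln, "K2P")
        assert np.allclose(dm.data, dm.data.T)
        assert np.all(np.diag(dm.data) == 0.0)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(ids=["A", "B", "C"],
                            data=np.array([[0, 2, 3], [2, 0, 5], [3, 5, 0]], float))
        tree = neighbor_joining(dm)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths == {"A": 0.0, "B": 2.0, "C": 3.0}

    def test_four_taxon_additive_example(self):
        d = np.array(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
        )
        tree = neighbor_joining(DistanceMatrix(ids=list("ABCD"), data=d))
        assert bipartitions(tree) == {frozenset({"C", "D"})}  # == split AB|CD
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)
        assert lengths["D"] == pytest.approx(4.0)
        internal = [n.length for n in tree.non_tips()]
        assert internal == pytest.approx([1.0])

    def test_additive_matrices_recovered_exactly(self):
        for seed in range(30):
            n = 4 + seed % 5
            truth = random_tree(n, seed=seed)
            dm = additive_distance_matrix(truth)
            rebuilt = neighbor_joining(dm)
            assert bipartitions(rebuilt) == bipartitions(truth)
            back = additive_distance_matrix(rebuilt)
            reordered = back.to_frame().loc[dm.ids, dm.ids].to_numpy()
            assert np.allclose(reordered, dm.data, atol=1e-9)

    def test_taxon_order_invariance(self):
        truth = random_tree(7, seed=5)
        dm = additive_distance_matrix(truth)
        rng = np.random.default_rng(1)
        perm = rng.permutation(len(dm.ids))
        dm2 = DistanceMatrix(ids=[dm.ids[k] for k in perm],
                             data=dm.data[np.ix_(perm, perm)])
        assert bipartitions(neighbor_joining(dm)) == bipartitions(neighbor_joining(dm2))

    def test_negative_lengths_clamped(self):
        # non-additive matrix known to produce a negative NJ branch
        d = np.array(
            [[0, 1, 8, 8], [1, 0, 8, 8], [8, 8, 0, 1], [8, 8, 1, 0]], dtype=float
        )
        tree = neighbor_joining(DistanceMatrix(ids=list("ABCD"), data=d))
        for node in tree.traverse(include_self=False):
            assert node.length >= 0.0


class TestBootstrap:
    def strong_alignment(self, n_noise=300, seed=0):
        """Two 5-taxon clades separated by 200 diagnostic columns."""
        rng = np.random.default_rng(seed)
        n_taxa = 10
        diag = np.zeros((n_taxa, 200), dtype="<U1")
        diag[:5, :] = "A"
        diag[5:, :] = "C"
        noise = rng.choice(list("ACGT"), size=(1, n_noise))
        noise = np.repeat(noise, n_taxa, axis=0)
        flip = rng.random((n_taxa, n_noise)) < 0.03
        alt = rng.choice(list("ACGT"), size=(n_taxa, n_noise))
        noise[flip] = alt[flip]
        full = np.concatenate([diag, noise], axis=1)
        return [rec("".join(row), f"t{i}") for i, row in enumerate(full)]

    def test_zero_bootstrap_gives_no_supports(self):
        aln = self.strong_alignment()
        tree = bootstrap_supports(aln, PhyloParams(n_bootstrap=0))
        assert all(n.support is None for n in tree.non_tips())

    def test_same_seed_reproduces_supports(self):
        aln = self.strong_alignment()
        pp = PhyloParams(n_bootstrap=100, seed=11)
        t1 = bootstrap_supports(aln, pp)
        t2 = bootstrap_supports(aln, pp)
        s1 = sorted(n.support for n in t1.non_tips() if n.support is not None)
        s2 = sorted(n.support for n in t2.non_tips() if n.support is not None)
        assert s1 == s2

    def test_strong_signal_central_edge_support(self):
        aln = self.strong_alignment()
        clade = frozenset(f"t{i}" for i in range(5, 10))
        tree = bootstrap_supports(aln, PhyloParams(n_bootstrap=100, seed=4))
        leaves = frozenset(f"t{i}" for i in range(10))
        for node in tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if side in (clade, leaves - clade):
                assert node.support >= 99
                assert node.support_displayed
                break
        else:
            pytest.fail("central bipartition missing from the tree")

    def test_low_supports_flagged_hidden_not_dropped(self):
        aln = self.strong_alignment()
        tree = bootstrap_supports(aln, PhyloParams(n_bootstrap=100, seed=4,
                                                   min_show_support=50))
        supports = [n for n in tree.non_tips() if n.support is not None]
        assert supports
        for n in supports:
            assert n.support_displayed == (n.support >= 50)

    def test_newick_round_trip_preserves_bipartitions(self):
        aln = self.strong_alignment()
        tree = bootstrap_supports(aln, PhyloParams(n_bootstrap=50, seed=2))
        back = read_newick(write_newick(tree))
        assert bipartitions(back) == bipartitions(tree)
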