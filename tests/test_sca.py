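"""SCA frequency model, coupling scores, and cluster extraction."""

import numpy as np
import pytest

from coev import sca
from coev.msa import Alignment
from coev.sca import (
    ScaError,
    cluster_coupling_matrix,
    coupling_matrix,
    coupling_matrix_bruteforce,
    fraction_above,
    sequence_weights,
    weighted_frequencies,
)


def _aln(seqs):
    return Alignment(ids=[f"s{i}" for i in range(len(seqs))], seqs=seqs)


class TestSequenceWeights:
    def test_mutually_distinct_sequences_weight_one(self):
        w, meff = sequence_weights(_aln(["ACDEG", "GGGGG", "KLKLK"]), 0.8)
        assert np.allclose(w, 1.0) and meff == pytest.approx(3.0)

    def test_duplicate_pair_half_weight(self):
        w, meff = sequence_weights(_aln(["ACDEG", "ACDEG", "KLKLK"]), 0.8)
        assert np.allclose(w, [0.5, 0.5, 1.0]) and meff == pytest.approx(2.0)

    def test_n_copies_collapse_to_meff_one(self):
        w, meff = sequence_weights(_aln(["ACDE"] * 7), 0.8)
        assert np.allclose(w, 1 / 7) and meff == pytest.approx(1.0)


class TestWeightedFrequencies:
    def test_single_sequence_no_pseudocount(self):
        fm = weighted_frequencies(_aln(["AA"]), lam=0.0)
        assert fm.f1[0, 0] == pytest.approx(1.0)  # A at index 0
        assert fm.f1[0, 1:].sum() == pytest.approx(0.0)

    def test_single_sequence_pseudocount_formula(self):
        fm = weighted_frequencies(_aln(["AA"]), lam=0.03)
        # (1-0.03)*1 + 0.03/20 = 0.9715
        assert fm.f1[0, 0] == pytest.approx(0.9715)

    def test_two_state_symmetry(self):
        fm = weighted_frequencies(_aln(["A", "C"]), lam=0.0)
        a, c = 0, 1
        assert fm.f1[0, a] == pytest.approx(0.5)
        assert fm.f1[0, c] == pytest.approx(0.5)

    def test_residue_mass_plus_gap_residual_is_one(self, rng):
        aa = "ACDEFGHIKLMNPQRSTVWY-"
        seqs = ["".join(rng.choice(list(aa), size=12)) for _ in range(30)]
        aln = _aln(seqs)
        fm = weighted_frequencies(aln, lam=0.03)
        arr = aln.to_array()
        gap_frac = (arr == 20).mean(axis=0)
        total = fm.f1.sum(axis=1) + (1 - fm.lam) * gap_frac
        assert np.allclose(total, 1.0, atol=1e-9)

    def test_pairwise_marginalizes_to_single_site_gap_free(self, rng):
        seqs = ["".join(rng.choice(list("ACDEFG"), size=6)) for _ in range(40)]
        fm = weighted_frequencies(_aln(seqs), lam=0.03)
        marg = fm.f2.sum(axis=3)  # sum over b
        for i in range(6):
            for j in range(6):
                assert np.allclose(marg[i, j], fm.f1[i], atol=1e-9)


class TestCouplingMatrix:
    def test_vectorized_equals_quadruple_loop_oracle(self, rng):
        # L <= 4, alphabet restricted to 3 residues
        for _ in range(3):
            seqs = ["".join(rng.choice(list("ACD"), size=4))
                    for _ in range(25)]
            fm = weighted_frequencies(_aln(seqs), lam=0.03)
            cm = coupling_matrix(fm)
            oracle = coupling_matrix_bruteforce(fm)
            np.fill_diagonal(oracle, 0.0)
            assert np.abs(cm.scores - oracle).max() < 1e-10

    def test_independent_columns_give_small_couplings(self, rng):
        n = 4000
        seqs = ["".join(rng.choice(list("ACDEFGHIKL"), size=5))
                for _ in range(n)]
        cm = coupling_matrix(weighted_frequencies(_aln(seqs), lam=0.03))
        iu = np.triu_indices(5, 1)
        # sampling noise shrinks as 1/sqrt(n)
        assert cm.scores[iu].max() < 0.5

    def test_covarying_pair_beats_independent_pairs(self, rng):
        n = 800
        pair = ["AA" if rng.random() < 0.5 else "CC" for _ in range(n)]
        noise = ["".join(rng.choice(list("ACDEFGHIKL"), size=2))
                 for _ in range(n)]
        seqs = [p + q for p, q in zip(pair, noise)]
        cm = coupling_matrix(weighted_frequencies(_aln(seqs), lam=0.03))
        others = [cm.scores[i, j] for i in range(4) for j in range(i + 1, 4)
                  if (i, j) != (0, 1)]
        assert cm.scores[0, 1] > max(others)

    def test_l2_matrix_shape_and_symmetry(self):
        cm = coupling_matrix(weighted_frequencies(
            _aln(["AC", "CA", "AC", "CA"]), lam=0.03))
        assert cm.scores.shape == (2, 2)
        assert cm.scores[0, 1] == cm.scores[1, 0]
        assert cm.scores[0, 0] == 0.0 and cm.scores[1, 1] == 0.0

    def test_conserved_position_without_pseudocount_is_error(self):
        fm = weighted_frequencies(_aln(["AC", "AG", "AD"]), lam=0.0)
        with pytest.raises(ScaError, match="lambda"):
            coupling_matrix(fm)

    def test_sequence_order_invariance(self, planted_msa_small):
        aln, _ = planted_msa_small
        perm = np.random.default_rng(3).permutation(aln.n_seqs)
        shuffled = Alignment(
            ids=[aln.ids[i] for i in perm],
            seqs=[aln.seqs[i] for i in perm],
        )
        cm1 = coupling_matrix(weighted_frequencies(aln, lam=0.03))
        cm2 = coupling_matrix(weighted_frequencies(shuffled, lam=0.03))
        assert np.allclose(cm1.scores, cm2.scores, atol=1e-12)

    def test_column_permutation_equivariance(self, rng):
        seqs = ["".join(rng.choice(list("ACDEFG"), size=6))
                for _ in range(60)]
        aln = _aln(seqs)
        perm = rng.permutation(6)
        permuted = Alignment(
            ids=aln.ids, seqs=["".join(s[i] for i in perm) for s in aln.seqs])
        cm = coupling_matrix(weighted_frequencies(aln, lam=0.03))
        cmp_ = coupling_matrix(weighted_frequencies(permuted, lam=0.03))
        assert np.allclose(cmp_.scores, cm.scores[np.ix_(perm, perm)],
                           atol=1e-12)

    def test_column_shuffle_destroys_coupling(self, planted_msa_small):
        # shuffling each column independently preserves conservation but
        # kills covariation; the planted top score must drop almost always
        aln, truth = planted_msa_small
        cm = coupling_matrix(weighted_frequencies(aln, lam=0.03))
        planted = truth["planted"]
        pre = sca._mean_intra_coupling(cm.scores, np.array(planted))
        drops = 0
        arr = aln.to_array()
        aa = "ACDEFGHIKLMNPQRSTVWY-"
        for seed in range(20):
            r = np.random.default_rng(seed)
            shuf = arr.copy()
            for c in range(shuf.shape[1]):
                r.shuffle(shuf[:, c])
            seqs = ["".join(aa[v] for v in row) for row in shuf]
            cm_s = coupling_matrix(weighted_frequencies(_aln(seqs), lam=0.03))
            post = sca._mean_intra_coupling(cm_s.scores, np.array(planted))
            drops += post < pre
        assert drops >= 19  # >= 95% of 20 shuffles


class TestFractionAbove:
    def test_all_zero_matrix(self):
        cm = sca.CouplingMatrix(np.zeros((4, 4)), np.arange(4), np.zeros((4, 20)))
        assert fraction_above(cm, 0.25) == 0.0

    def test_three_by_three_enumeration(self):
        scores = np.zeros((3, 3))
        scores[0, 1] = scores[1, 0] = 0.3
        scores[0, 2] = scores[2, 0] = 0.1
        scores[1, 2] = scores[2, 1] = 0.2
        cm = sca.CouplingMatrix(scores, np.arange(3), np.zeros((3, 20)))
        assert fraction_above(cm, 0.25) == pytest.approx(1 / 3)

    def test_threshold_below_minimum_gives_one(self):
        scores = np.full((3, 3), 0.4)
        np.fill_diagonal(scores, 0.0)
        cm = sca.CouplingMatrix(scores, np.arange(3), np.zeros((3, 20)))
        assert fraction_above(cm, 0.1) == 1.0


class TestClustering:
    def _cm(self, scores):
        L = scores.shape[0]
        return sca.CouplingMatrix(scores, np.arange(L), np.zeros((L, 20)))

    def test_block_diagonal_top_cluster(self, rng):
        L = 20
        scores = np.zeros((L, L))
        block = [2, 5, 9, 14, 18]
        for i in block:
            for j in block:
                if i != j:
                    scores[i, j] = 1.0
        # brute-force check: the block has the best mean intra-coupling
        # (default largest-gap cut; an explicit k=2 cut is degenerate here
        # because background-background and background-block distances tie)
        cl = cluster_coupling_matrix(self._cm(scores))
        assert sorted(cl.top_cluster) == block
        assert cl.top_cluster_score == pytest.approx(1.0)

    def test_planted_msa_recovery_single_seed(self, planted_msa_small):
        aln, truth = planted_msa_small
        w, _ = sequence_weights(aln)
        cm = coupling_matrix(weighted_frequencies(aln, w, lam=0.03))
        cl = cluster_coupling_matrix(cm)
        assert sorted(cl.top_cluster) == sorted(truth["planted"])

    def test_two_positions_single_merge(self):
        scores = np.array([[0.0, 0.8], [0.8, 0.0]])
        cl = cluster_coupling_matrix(self._cm(scores))
        assert sorted(cl.top_cluster) == [0, 1]

    def test_constant_matrix_no_signal_error(self):
        with pytest.raises(ScaError, match="no coupling signal"):
            cluster_coupling_matrix(self._cm(np.zeros((5, 5))))

    def test_posmap_reports_residue_numbers(self):
        from coev.msa import PositionMap
        scores = np.zeros((4, 4))
        scores[0, 1] = scores[1, 0] = 1.0
        pm = PositionMap(pairs=[(0, 200), (1, 201), (2, 202), (3, 203)],
                         ref_id="r", numbering_start=200)
        cl = cluster_coupling_matrix(self._cm(scores), posmap=pm)
        assert cl.top_cluster == [200, 201]
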