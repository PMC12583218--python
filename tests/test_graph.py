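"""Graph construction: fingerprints, similarity measures (with an
independent dynamic-programming alignment oracle), thresholding, edge-type
aggregation, unified assembly and masked row-softmax normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from heterodti.graph import (EdgeTypeSet, Fingerprint, aggregate_edge_types,
                             assemble_unified, build_similarity_matrix,
                             circular_fingerprint, kmer_fingerprint,
                             normalized_seq_similarity, row_softmax_normalize,
                             smith_waterman, tanimoto, threshold_adjacency)


def sw_oracle(a, b, match=2, mismatch=-1, gap=-1):
    """Independent full-DP Smith-Waterman with linear gaps."""
    H = np.zeros((len(a) + 1, len(b) + 1))
    best = 0.0
    for i in range(1, len(a) + 1):
        for j in range(1, len(b) + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            H[i, j] = max(0, H[i - 1, j - 1] + sub, H[i - 1, j] + gap,
                          H[i, j - 1] + gap)
            best = max(best, H[i, j])
    return best


class TestFingerprints:
    def test_tanimoto_identical_and_disjoint(self):
        a = Fingerprint(frozenset({1, 2, 3}), 16)
        assert tanimoto(a, a) == 1.0
        b = Fingerprint(frozenset({4, 5}), 16)
        assert tanimoto(a, b) == 0.0

    def test_tanimoto_partial_overlap(self):
        # intersection {2,3} = 2, union {1,2,3,4} = 4
        a = Fingerprint(frozenset({1, 2, 3}), 16)
        b = Fingerprint(frozenset({2, 3, 4}), 16)
        assert tanimoto(a, b) == 0.5

    def test_tanimoto_empty_pair_is_zero(self):
        e = Fingerprint(frozenset(), 16)
        assert tanimoto(e, e) == 0.0

    def test_tanimoto_rejects_mismatched_width(self):
        with pytest.raises(ValueError):
            tanimoto(Fingerprint(frozenset({1}), 16),
                     Fingerprint(frozenset({1}), 32))

    def test_circular_fingerprint_deterministic_nonempty(self):
        rdkit = pytest.importorskip("rdkit")  # noqa: F841
        fp1 = circular_fingerprint("CCO", radius=2, nbits=2048)
        fp2 = circular_fingerprint("CCO", radius=2, nbits=2048)
        assert fp1.bits == fp2.bits and len(fp1.bits) >= 1
        assert tanimoto(fp1, fp2) == 1.0

    def test_circular_fingerprint_rejects_bad_smiles(self):
        pytest.importorskip("rdkit")
        with pytest.raises(ValueError, match="not-a-molecule"):
            circular_fingerprint("not-a-molecule")

    def test_kmer_fingerprint_deterministic(self):
        a = kmer_fingerprint("CCO-toy", k=3, nbits=256)
        b = kmer_fingerprint("CCO-toy", k=3, nbits=256)
        assert a.bits == b.bits and len(a.bits) >= 1


class TestAlignment:
    def test_exact_match_score(self):
        # "ACGT" self-alignment: 4 matches x 2
        assert smith_waterman("ACGT", "ACGT", (2, -1), 1, 1) == 8.0

    def test_no_positive_pair_scores_zero(self):
        assert smith_waterman("AAAA", "CCCC", (2, -1), 1, 1) == 0.0

    @given(st.text(alphabet="ACDEFGHIK", min_size=1, max_size=12),
           st.text(alphabet="ACDEFGHIK", min_size=1, max_size=12))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_matches_dp_oracle(self, a, b):
        got = smith_waterman(a, b, (2, -1), 1, 1)
        assert got == sw_oracle(a, b)

    def test_self_alignment_equals_diagonal_sum(self):
        seq = "MKVLAW"
        from Bio.Align import substitution_matrices
        blosum = substitution_matrices.load("BLOSUM62")
        expected = sum(blosum[ch, ch] for ch in seq)
        assert smith_waterman(seq, seq) == expected

    def test_normalized_self_similarity_is_one(self):
        assert normalized_seq_similarity("MKVLAW", "MKVLAW") == 1.0

    def test_normalized_similarity_symmetric_and_bounded(self):
        rng = np.random.default_rng(5)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        seqs = ["".join(rng.choice(list(aa), 20)) for _ in range(4)]
        for i in range(4):
            for j in range(4):
                sij = normalized_seq_similarity(seqs[i], seqs[j])
                sji = normalized_seq_similarity(seqs[j], seqs[i])
                assert sij == sji and 0.0 <= sij <= 1.0

    def test_empty_sequence_scores_zero(self):
        assert smith_waterman("", "ACGT", (2, -1), 1, 1) == 0.0
        assert normalized_seq_similarity("", "ACGT", (2, -1), 1, 1) == 0.0


class TestMatrices:
    def test_single_entity_matrix(self):
        S = build_similarity_matrix(["x"], lambda a, b: 0.0)
        np.testing.assert_array_equal(S.values, [[1.0]])

    def test_identical_fingerprints_give_all_ones(self):
        fp = Fingerprint(frozenset({1, 2}), 8)
        S = build_similarity_matrix([fp] * 3, tanimoto)
        np.testing.assert_array_equal(S.values, np.ones((3, 3)))

    def test_symmetry_on_random_fixture(self, rng):
        fps = [Fingerprint(frozenset(rng.choice(32, 8, replace=False)
                                     .tolist()), 32) for _ in range(6)]
        S = build_similarity_matrix(fps, tanimoto)
        np.testing.assert_array_equal(S.values, S.values.T)
        np.testing.assert_array_equal(np.diag(S.values), np.ones(6))

    def test_threshold_removes_self_loops_and_selects_edges(self):
        S = np.eye(3)
        S[0, 1] = S[1, 0] = 0.6
        A = threshold_adjacency(S, 0.5)
        assert A[0, 1] == 1 and A[1, 0] == 1
        assert A.sum() == 2  # only that symmetric pair
        assert np.all(np.diag(A) == 0)

    def test_threshold_monotone(self, rng):
        S = rng.random((6, 6))
        S = (S + S.T) / 2
        lo = threshold_adjacency(S, 0.3)
        hi = threshold_adjacency(S, 0.7)
        assert np.all(hi <= lo)

    def test_threshold_above_one_gives_empty_graph(self, rng):
        A = threshold_adjacency(rng.random((4, 4)), 1.01)
        assert A.sum() == 0

    def test_aggregate_single_type_identity(self, rng):
        A = (rng.random((4, 4)) > 0.5).astype(float)
        out = aggregate_edge_types(EdgeTypeSet([A], weights=[1.0]))
        np.testing.assert_array_equal(out, A)

    def test_aggregate_linear_in_weights(self, rng):
        A1 = (rng.random((4, 4)) > 0.5).astype(float)
        A2 = (rng.random((4, 4)) > 0.5).astype(float)
        out = aggregate_edge_types(EdgeTypeSet([A1, A2], weights=[2.0, 3.0]))
        np.testing.assert_array_equal(out, 2 * A1 + 3 * A2)
        w1 = aggregate_edge_types(EdgeTypeSet([A1, A2], weights=[2.0, 0.0]))
        w2 = aggregate_edge_types(EdgeTypeSet([A1, A2], weights=[0.0, 3.0]))
        np.testing.assert_array_equal(out, w1 + w2)

    def test_aggregate_rejects_shape_mismatch(self):
        with pytest.raises(ValueError):
            aggregate_edge_types(EdgeTypeSet([np.eye(2), np.eye(3)]))

    def test_unified_shape_and_transpose(self, rng):
        A_DD = (rng.random((2, 2)) > 0.5).astype(float)
        A_DD = np.triu(A_DD, 1) + np.triu(A_DD, 1).T
        A_TT = np.zeros((3, 3))
        A_DT = (rng.random((2, 3)) > 0.5).astype(float)
        g = assemble_unified(A_DD, A_TT, A_DT)
        assert g.full_matrix().shape == (5, 5)
        np.testing.assert_array_equal(g.A_TD, A_DT.T)
        np.testing.assert_array_equal(g.full_matrix(), g.full_matrix().T)

    def test_unified_zero_interactions(self):
        g = assemble_unified(np.zeros((2, 2)), np.zeros((3, 3)),
                             np.zeros((2, 3)))
        assert g.full_matrix().sum() == 0

    def test_unified_rejects_dimension_mismatch(self):
        with pytest.raises(ValueError):
            assemble_unified(np.zeros((2, 2)), np.zeros((3, 3)),
                             np.zeros((3, 2)))


class TestRowSoftmax:
    def test_equal_supported_weights_split_evenly(self):
        block = np.array([[1.0, 1.0, 0.0]])
        support = np.array([[True, True, False]])
        out = row_softmax_normalize(block, support)
        np.testing.assert_allclose(out, [[0.5, 0.5, 0.0]])

    def test_closed_form_log_weights(self):
        block = np.array([[0.0, np.log(2.0)]])
        support = np.array([[True, True]])
        out = row_softmax_normalize(block, support)
        np.testing.assert_allclose(out, [[1 / 3, 2 / 3]], atol=1e-12)

    def test_empty_support_row_is_zero(self):
        out = row_softmax_normalize(np.ones((2, 2)),
                                    np.array([[True, True],
                                              [False, False]]))
        np.testing.assert_allclose(out[0], [0.5, 0.5])
        np.testing.assert_array_equal(out[1], [0.0, 0.0])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_supported_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        block = rng.normal(size=(5, 5))
        support = rng.random((5, 5)) > 0.5
        out = row_softmax_normalize(block, support)
        assert np.all(out >= 0)
        assert np.all(out[~support] == 0)
        for i in range(5):
            if support[i].any():
                assert abs(out[i].sum() - 1.0) < 1e-8
            else:
                assert np.all(out[i] == 0)
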