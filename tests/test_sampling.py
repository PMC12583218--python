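"""Reliability scores, importance weights, weighted loss and refinement."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from heterodti import sampling
from heterodti.sampling import (NegativeSampleSet, SamplerConfig, chem_dissim,
                                importance_weights, initial_negative_set,
                                refine_negatives, reliability_matrix,
                                seq_dissim, weighted_interaction_loss)


class TestDissimilarities:
    def test_identical_binder_gives_zero(self):
        S = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert chem_dissim(0, [1], S) == 0.0

    def test_empty_binder_set_is_maximally_dissimilar(self):
        assert chem_dissim(0, [], np.eye(2)) == 1.0
        assert seq_dissim(0, [], np.eye(2)) == 1.0

    def test_max_over_binders(self):
        # similarities {0.2, 0.7} -> dissimilarity 0.3
        S = np.array([[1.0, 0.2, 0.7], [0.2, 1, 0], [0.7, 0, 1]])
        assert chem_dissim(0, [1, 2], S) == pytest.approx(0.3)

    def test_seq_dissim_enumerates_max(self):
        S = np.array([[1.0, 0.1, 0.4], [0.1, 1, 0], [0.4, 0, 1]])
        assert seq_dissim(0, [1, 2], S) == pytest.approx(0.6)


class TestReliability:
    def test_extremes(self):
        cfg = SamplerConfig(alpha=0.5, beta=0.5)
        # both dissimilarities 1 (no binders/targets known) -> r = 1
        Y = np.zeros((2, 2))
        R = reliability_matrix(Y, np.eye(2), np.eye(2), cfg)
        np.testing.assert_allclose(R, 1.0)

    def test_weighted_mixture(self):
        # alpha 0.7 * 0.5 + beta 0.3 * 1.0 = 0.65
        cfg = SamplerConfig(alpha=0.7, beta=0.3)
        S_chem = np.array([[1.0, 0.5], [0.5, 1.0]])
        S_seq = np.array([[1.0, 0.0], [0.0, 1.0]])
        Y = np.array([[0.0, 0.0], [1.0, 0.0]])  # drug 1 binds target 0
        R = reliability_matrix(Y, S_chem, S_seq, cfg, cold_adaptation=False)
        # pair (0, 0): binder of t0 is d1 (sim 0.5); d0 has no known targets
        assert R[0, 0] == pytest.approx(0.7 * 0.5 + 0.3 * 1.0)

    def test_cold_adaptation_imputes_mean_not_maximum(self):
        """Entities without training interactions get the mean dissimilarity
        of informative pairs instead of the maximal one, so their whole
        block is not branded top-reliability negative."""
        cfg = SamplerConfig(alpha=1.0, beta=0.0)
        S_chem = np.array([[1.0, 0.8, 0.2],
                           [0.8, 1.0, 0.2],
                           [0.2, 0.2, 1.0]])
        S_seq = np.eye(3)
        # targets 0 and 2 have binders; target 1 is cold
        Y = np.zeros((3, 3))
        Y[0, 0] = 1
        Y[2, 2] = 1
        R_raw = reliability_matrix(Y, S_chem, S_seq, cfg,
                                   cold_adaptation=False)
        R_adapted = reliability_matrix(Y, S_chem, S_seq, cfg)
        assert np.all(R_raw[:, 1] == 1.0)  # cold column maxed out
        # adapted cold column equals each drug's mean over informative cols
        np.testing.assert_allclose(R_adapted[:, 1],
                                   R_adapted[:, [0, 2]].mean(axis=1))

    def test_planted_negatives_more_reliable_than_masked_positives(
            self, standard_dataset, standard_data):
        """The separation assumption: true negatives score higher reliability
        than held-out (masked) positives."""
        ds, data = standard_dataset, standard_data
        rng = np.random.default_rng(0)
        pos = np.argwhere(ds.Y_clean == 1)
        masked = pos[rng.choice(len(pos), 50, replace=False)]
        Y_train = ds.Y_clean.copy()
        Y_train[masked[:, 0], masked[:, 1]] = 0
        R = reliability_matrix(Y_train, data.S_chem, data.S_seq,
                               SamplerConfig())
        true_neg = (ds.Y_clean == 0)
        assert (R[true_neg].mean()
                > R[masked[:, 0], masked[:, 1]].mean())


class TestImportanceWeights:
    def test_equal_reliabilities_uniform(self):
        np.testing.assert_allclose(importance_weights(np.array([0.4, 0.4]),
                                                      1.0), [0.5, 0.5])

    def test_zero_temperature_uniform(self):
        w = importance_weights(np.array([0.1, 0.5, 0.9]), 0.0)
        np.testing.assert_allclose(w, 1 / 3)

    def test_closed_form_two_points(self):
        w = importance_weights(np.array([0.0, 1.0]), 1.0)
        np.testing.assert_allclose(w, [1 / (1 + np.e), np.e / (1 + np.e)])

    def test_empty_set_raises(self):
        with pytest.raises(ValueError):
            importance_weights(np.array([]), 1.0)

    @given(st.floats(0.01, 0.99), st.floats(0.0, 0.99),
           st.floats(0.1, 5.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_reliability(self, hi, frac, gamma):
        lo = hi * frac
        w = importance_weights(np.array([hi, lo]), gamma)
        assert w[0] > w[1] or lo == hi
        assert abs(w.sum() - 1.0) < 1e-8

    def test_sharpness_increases_with_temperature(self):
        r = np.array([0.9, 0.2])
        w1 = importance_weights(r, 1.0)
        w2 = importance_weights(r, 3.0)
        assert w2[0] / w2[1] > w1[0] / w1[1]


class TestWeightedLoss:
    def test_single_positive_at_zero_is_log_two(self):
        loss = weighted_interaction_loss(np.array([0.0]), [True])
        assert loss == pytest.approx(np.log(2.0))

    def test_single_negative_weight_one_at_zero_is_log_two(self):
        loss = weighted_interaction_loss(np.array([0.0]), [False],
                                         weights=np.array([1.0]))
        assert loss == pytest.approx(np.log(2.0))

    def test_confident_correct_predictions_vanish(self):
        loss = weighted_interaction_loss(np.array([50.0, -50.0]),
                                         [True, False],
                                         weights=np.array([1.0]))
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_and_finite(self, rng):
        scores = rng.normal(scale=5, size=20)
        mask = rng.random(20) > 0.5
        w = rng.random(int((~mask).sum()))
        loss = weighted_interaction_loss(scores, mask, w)
        assert np.isfinite(loss) and loss >= 0


class TestRefinement:
    cfg = SamplerConfig(theta_neg=0.5, theta_rel=0.5)

    def _unlabeled(self):
        return np.array([[0, 1], [2, 3]])

    def test_filter_keeps_qualifying_pair_only(self):
        # sigmoid scale: raw score -2 -> prob 0.12 < 0.5 kept; +2 -> dropped
        prev = NegativeSampleSet(self._unlabeled(), np.array([0.9, 0.9]),
                                 np.array([0.5, 0.5]))
        out = refine_negatives(self._unlabeled(), np.array([-2.0, 2.0]),
                               np.array([0.9, 0.9]), self.cfg, prev)
        np.testing.assert_array_equal(out.pairs, [[0, 1]])
        assert out.generation == 1

    def test_empty_selection_falls_back_to_previous(self):
        prev = NegativeSampleSet(self._unlabeled(), np.array([0.9, 0.9]),
                                 np.array([0.5, 0.5]), generation=2)
        out = refine_negatives(self._unlabeled(), np.array([3.0, 3.0]),
                               np.array([0.9, 0.9]), self.cfg, prev)
        np.testing.assert_array_equal(out.pairs, prev.pairs)
        assert out.generation == 3

    def test_weights_renormalized_after_refinement(self):
        prev = NegativeSampleSet(self._unlabeled(), np.array([0.9, 0.8]),
                                 None)
        out = refine_negatives(self._unlabeled(), np.array([-2.0, -2.0]),
                               np.array([0.9, 0.8]), self.cfg, prev)
        assert abs(out.weight.sum() - 1.0) < 1e-8

    def test_refined_set_satisfies_thresholds_elementwise(self, rng):
        pairs = np.column_stack([np.arange(50), np.arange(50)])
        preds = rng.normal(size=50)
        rel = rng.random(50)
        prev = NegativeSampleSet(pairs, rel, None)
        out = refine_negatives(pairs, preds, rel, self.cfg, prev)
        from scipy.special import expit
        kept = {tuple(p) for p in out.pairs}
        for p, pr, r in zip(pairs, preds, rel):
            if tuple(p) in kept:
                assert expit(pr) < 0.5 and r > 0.5


class TestInitialSet:
    def test_takes_top_reliability(self, rng):
        pairs = np.column_stack([np.arange(10), np.zeros(10, int)])
        rel = np.linspace(0, 1, 10)
        out = initial_negative_set(pairs, rel, n_positives=3,
                                   config=SamplerConfig(ratio=1.0), rng=rng)
        assert len(out) == 3
        assert set(out.pairs[:, 0]) == {7, 8, 9}
        assert abs(out.weight.sum() - 1.0) < 1e-8

    def test_disjoint_from_positives_by_construction(self, small_dataset,
                                                     small_data):
        ds, data = small_dataset, small_data
        cfg = SamplerConfig()
        R = reliability_matrix(ds.Y, data.S_chem, data.S_seq, cfg)
        unl = np.argwhere(ds.Y == 0)
        out = initial_negative_set(unl, R[ds.Y == 0],
                                   int(ds.Y.sum()), cfg,
                                   np.random.default_rng(0))
        pos = {tuple(p) for p in np.argwhere(ds.Y == 1)}
        assert not pos & {tuple(p) for p in out.pairs}
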