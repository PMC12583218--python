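"""Positive-unlabeled negative sampling with reliability scores.

Missing drug-target interactions are not known negatives.  Each unlabeled
pair (d_i, t_j) gets a reliability score

    r_ij = alpha * ChemDissim(d_i, binders(t_j)) + beta * SeqDissim(t_j, targets(d_i))

where the dissimilarities are one minus the maximal Tanimoto / normalized
Smith-Waterman similarity to the known interactors.  Negatives are drawn from
the most reliable unlabeled pairs, weighted by a temperature softmax of their
reliabilities, and periodically refined once the model's own predictions can
veto pairs it already believes are positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, softmax

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig", "NegativeSampleSet", "chem_dissim", "seq_dissim",
    "reliability_score", "reliability_matrix", "importance_weights",
    "weighted_interaction_loss", "initial_negative_set", "refine_negatives",
]


@dataclass
class SamplerConfig:
    """Knobs of the reliability-based sampler.

    alpha / beta mix the chemical and sequence dissimilarities; gamma_temp is
    the softmax temperature of the importance weights; theta_neg and theta_rel
    are the prediction (sigmoid-scale) and reliability thresholds of the
    refinement filter; refresh_interval is in epochs; ratio is negatives per
    positive in the initial set.
    """

    alpha: float = 0.5
    beta: float = 0.5
    gamma_temp: float = 1.0
    theta_neg: float = 0.5
    theta_rel: float = 0.5
    refresh_interval: int = 50
    ratio: float = 1.0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or self.gamma_temp < 0:
            raise ValueError("alpha, beta, gamma_temp must be nonnegative")
        for name in ("theta_neg", "theta_rel"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


@dataclass
class NegativeSampleSet:
    """Unlabeled pairs currently used as negatives, with weights summing to 1."""

    pairs: np.ndarray  # (N, 2) int array of (drug index, target index)
    reliability: np.ndarray
    weight: np.ndarray = field(default=None)
    generation: int = 0

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        self.reliability = np.asarray(self.reliability, dtype=float)
        if self.weight is not None:
            self.weight = np.asarray(self.weight, dtype=float)

    def __len__(self) -> int:
        return len(self.pairs)


def chem_dissim(drug_index: int, binder_indices, S_chem: np.ndarray) -> float:
    """1 - max Tanimoto similarity of the drug to the target's known binders.

    An empty binder set means the target has no known chemistry to compare
    against; the drug is maximally dissimilar by convention (1.0).
    """
    binder_indices = np.asarray(binder_indices, dtype=int)
    if binder_indices.size == 0:
        return 1.0
    return float(1.0 - S_chem[drug_index, binder_indices].max())


def seq_dissim(target_index: int, known_target_indices,
               S_seq: np.ndarray) -> float:
    """1 - max normalized alignment similarity to the drug's known targets."""
    known_target_indices = np.asarray(known_target_indices, dtype=int)
    if known_target_indices.size == 0:
        return 1.0
    return float(1.0 - S_seq[target_index, known_target_indices].max())


def reliability_score(drug_index: int, target_index: int, Y: np.ndarray,
                      S_chem: np.ndarray, S_seq: np.ndarray,
                      config: SamplerConfig) -> float:
    """alpha * ChemDissim + beta * SeqDissim for one unlabeled pair."""
    binders = np.nonzero(Y[:, target_index] == 1)[0]
    known_targets = np.nonzero(Y[drug_index, :] == 1)[0]
    return (config.alpha * chem_dissim(drug_index, binders, S_chem)
            + config.beta * seq_dissim(target_index, known_targets, S_seq))


def reliability_matrix(Y: np.ndarray, S_chem: np.ndarray, S_seq: np.ndarray,
                       config: SamplerConfig,
                       cold_adaptation: bool = True) -> np.ndarray:
    """Vectorized reliability of every (i, j) pair given training positives Y.

    Entities with no training interactions (cold drugs/targets) have an
    empty interactor set, where the per-pair convention of maximal
    dissimilarity would brand every one of their pairs a top-reliability
    negative and train the model to suppress the whole cold block.  With
    `cold_adaptation` (default) the missing dissimilarity is instead imputed
    by the entity's mean over informative pairs, leaving cold pairs neither
    preferred nor excluded.
    """
    m, n = Y.shape
    pos = Y == 1
    # chem: for each target j, max over its binders of S_chem[i, binder]
    chem = np.ones((m, n))
    cold_t = np.ones(n, dtype=bool)
    for j in range(n):
        binders = np.nonzero(pos[:, j])[0]
        if binders.size:
            chem[:, j] = 1.0 - S_chem[:, binders].max(axis=1)
            cold_t[j] = False
    seq = np.ones((m, n))
    cold_d = np.ones(m, dtype=bool)
    for i in range(m):
        known = np.nonzero(pos[i, :])[0]
        if known.size:
            seq[i, :] = 1.0 - S_seq[:, known].max(axis=1)
            cold_d[i] = False
    if cold_adaptation:
        if cold_t.any() and not cold_t.all():
            chem[:, cold_t] = chem[:, ~cold_t].mean(axis=1, keepdims=True)
        if cold_d.any() and not cold_d.all():
            seq[cold_d, :] = seq[~cold_d, :].mean(axis=0, keepdims=True)
    return config.alpha * chem + config.beta * seq


def importance_weights(reliabilities: np.ndarray,
                       gamma_temp: float) -> np.ndarray:
    """Softmax of gamma * r over the negative set; sums to 1.

    gamma_temp = 0 degenerates to uniform weights; larger temperatures
    concentrate mass on the most reliable negatives.
    """
    r = np.asarray(reliabilities, dtype=float)
    if r.size == 0:
        raise ValueError("importance weights need a nonempty negative set")
    return softmax(gamma_temp * r)


def weighted_interaction_loss(pred_scores: np.ndarray, positive_mask,
                              weights: np.ndarray | None = None) -> float:
    """- sum_P log sigma(yhat) - sum_N w * log(1 - sigma(yhat)).

    `pred_scores` are raw scores over the concatenated P then N pairs;
    `positive_mask` marks the P entries; `weights` apply to the N entries
    (defaults to 1 each).
    """
    scores = np.asarray(pred_scores, dtype=float)
    mask = np.asarray(positive_mask, dtype=bool)
    pos_term = -_log_sigmoid(scores[mask]).sum()
    neg_scores = scores[~mask]
    if weights is None:
        weights = np.ones(neg_scores.size)
    neg_term = -(np.asarray(weights) * _log_sigmoid(-neg_scores)).sum()
    return float(pos_term + neg_term)


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, -np.log1p(np.exp(-np.abs(x))),
                    x - np.log1p(np.exp(-np.abs(x))))


def initial_negative_set(unlabeled_pairs: np.ndarray,
                         reliabilities: np.ndarray, n_positives: int,
                         config: SamplerConfig,
                         rng: np.random.Generator) -> NegativeSampleSet:
    """Round-0 negatives: top-(ratio * |P|) unlabeled pairs by reliability.

    No model predictions exist yet, so the refinement filter cannot run;
    reliability alone seeds the set.  Ties are broken by a seeded shuffle so
    the selection is deterministic given the stream.
    """
    unlabeled_pairs = np.asarray(unlabeled_pairs, dtype=int).reshape(-1, 2)
    k = min(int(round(config.ratio * n_positives)), len(unlabeled_pairs))
    if k < 1:
        raise ValueError("no unlabeled pairs available for negative sampling")
    perm = rng.permutation(len(unlabeled_pairs))
    order = perm[np.argsort(-reliabilities[perm], kind="stable")]
    chosen = order[:k]
    rel = reliabilities[chosen]
    return NegativeSampleSet(
        pairs=unlabeled_pairs[chosen], reliability=rel,
        weight=importance_weights(rel, config.gamma_temp), generation=0)


def refine_negatives(unlabeled_pairs: np.ndarray, predictions: np.ndarray,
                     reliabilities: np.ndarray, config: SamplerConfig,
                     previous: NegativeSampleSet) -> NegativeSampleSet:
    """Refinement step: keep unlabeled pairs with sigma(yhat) < theta_neg and
    r > theta_rel; recompute weights; fall back to the previous set when the
    filter empties."""
    unlabeled_pairs = np.asarray(unlabeled_pairs, dtype=int).reshape(-1, 2)
    probs = expit(np.asarray(predictions, dtype=float))
    keep = (probs < config.theta_neg) & (reliabilities > config.theta_rel)
    if not np.any(keep):
        logger.warning("negative refinement selected no pairs; keeping "
                       "previous generation %d", previous.generation)
        return NegativeSampleSet(
            pairs=previous.pairs, reliability=previous.reliability,
            weight=importance_weights(previous.reliability, config.gamma_temp),
            generation=previous.generation + 1)
    rel = reliabilities[keep]
    return NegativeSampleSet(
        pairs=unlabeled_pairs[keep], reliability=rel,
        weight=importance_weights(rel, config.gamma_temp),
        generation=previous.generation + 1)
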