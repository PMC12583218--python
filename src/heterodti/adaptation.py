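"""Dataset-specific network adaptation.

A study rarely uses the full global auxiliary networks: its drug and target
sets are a subset, its edge-weight distribution differs, and the relative
usefulness of each network type varies.  This module (i) extracts the exact
submatrices for the dataset's entities, (ii) reweights edges so their
empirical distribution matches the dataset's own (w' = w * Q_D(F_global(w))),
(iii) learns nonnegative per-network combination weights on a validation
objective, and (iv) penalizes divergence of the adapted networks from the
global ones with a Frobenius regularizer whose per-network coefficients are
proportional to edge counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = ["MetaConfig", "filter_subnetwork", "cdf_reweight",
           "learn_combination_weights", "adapt_adjacency",
           "adaptation_regularizer", "alpha_coefficients"]


@dataclass
class MetaConfig:
    """Settings of the two-stage meta-optimization of combination weights."""

    learning_rate: float = 0.01
    decay: float = 0.95
    decay_every: int = 50
    max_iter: int = 500
    patience: int = 20
    fd_step: float = 1e-4  # central-difference step for the gradient


def filter_subnetwork(global_adjacency: np.ndarray, entity_subset,
                      global_index: dict[str, int]) -> np.ndarray:
    """Exact submatrix of the global network on the subset's ordering."""
    try:
        idx = np.asarray([global_index[e] for e in entity_subset], dtype=int)
    except KeyError as exc:
        raise KeyError(f"unknown entity id {exc.args[0]!r}") from None
    return np.asarray(global_adjacency)[np.ix_(idx, idx)]


def _empirical_cdf(values: np.ndarray, collection: np.ndarray) -> np.ndarray:
    """F(v) = average rank of v within `collection` / N.

    Closed form (count_less + (count_equal + 1) / 2) / N; for v a member of
    a tie-free collection this is the usual rank/N.
    """
    s = np.sort(np.asarray(collection, float))
    n = len(s)
    less = np.searchsorted(s, values, side="left")
    less_eq = np.searchsorted(s, values, side="right")
    equal = less_eq - less
    return (less + (equal + 1) / 2.0) / n


def _empirical_quantile(q: np.ndarray, sample: np.ndarray) -> np.ndarray:
    """Inverted-CDF (step) quantile: Q(q) = w_(ceil(q n)).

    This convention inverts `_empirical_cdf` exactly on tie-free samples
    (Q(i/n) = w_(i)) and is invariant to duplicating the sample, which an
    interpolating quantile is not.
    """
    s = np.sort(np.asarray(sample, float))
    n = len(s)
    idx = np.clip(np.ceil(np.asarray(q, float) * n).astype(int) - 1, 0, n - 1)
    return s[idx]


def cdf_reweight(edge_weights_dataset: np.ndarray,
                 edge_weights_global: np.ndarray) -> np.ndarray:
    """w' = w * Q_D(F_global(w)) for each dataset edge weight.

    F_global is the empirical CDF over all datasets (average ranks / N) and
    Q_D the dataset's empirical quantile function (linear interpolation
    between order statistics, chosen so Q_D inverts F when the distributions
    coincide).  Rank order within the dataset is preserved.
    """
    w = np.asarray(edge_weights_dataset, dtype=float)
    g = np.asarray(edge_weights_global, dtype=float)
    if w.size == 0 or g.size == 0:
        raise ValueError("weight collections must be nonempty")
    if np.ptp(g) == 0:
        logger.warning("constant global edge weights; reweighting factor 1")
        return w.copy()
    factor = _empirical_quantile(_empirical_cdf(w, g), w)
    return w * factor


def learn_combination_weights(networks: list[np.ndarray],
                              validation_objective,
                              meta_config: MetaConfig | None = None,
                              init: np.ndarray | None = None
                              ) -> tuple[np.ndarray, list[float]]:
    """Minimize a validation loss over nonnegative combination weights.

    `validation_objective(lambdas) -> loss` is treated as a black box; the
    gradient is estimated by central finite differences (the weight vector is
    short), each step projects onto the nonnegative orthant, the learning
    rate decays multiplicatively, and early stopping tracks the best loss.
    Returns (weights, loss trace).
    """
    cfg = meta_config or MetaConfig()
    K = len(networks)
    if K == 1:
        return np.ones(1), [float(validation_objective(np.ones(1)))]
    lam = (np.full(K, 1.0 / K) if init is None
           else np.asarray(init, float).copy())
    lr = cfg.learning_rate
    best_loss = np.inf
    best_lam = lam.copy()
    stall = 0
    trace: list[float] = []
    for it in range(cfg.max_iter):
        loss = float(validation_objective(lam))
        trace.append(loss)
        if loss < best_loss - 1e-12:
            best_loss, best_lam, stall = loss, lam.copy(), 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
        grad = np.empty(K)
        for k in range(K):
            step = np.zeros(K)
            step[k] = cfg.fd_step
            grad[k] = (float(validation_objective(lam + step))
                       - float(validation_objective(
                           np.maximum(lam - step, 0.0)))) / (2 * cfg.fd_step)
        lam = np.maximum(lam - lr * grad, 0.0)
        if np.all(lam == 0):
            logger.warning("all combination weights projected to zero; "
                           "resetting to uniform")
            lam = np.full(K, 1.0 / K)
        if (it + 1) % cfg.decay_every == 0:
            lr *= cfg.decay
    return best_lam, trace


def adapt_adjacency(networks: list[np.ndarray], lambdas: np.ndarray,
                    reweights: list[np.ndarray] | None = None) -> np.ndarray:
    """Adapted adjacency sum_k lambda_k * (W_k ⊙ A_k)."""
    lambdas = np.asarray(lambdas, dtype=float)
    if len(lambdas) != len(networks):
        raise ValueError("one lambda per network required")
    shapes = {np.asarray(a).shape for a in networks}
    if len(shapes) != 1:
        raise ValueError(f"network shape mismatch: {shapes}")
    out = np.zeros(next(iter(shapes)))
    for k, A in enumerate(networks):
        W = np.ones_like(out) if reweights is None else reweights[k]
        out += lambdas[k] * (W * np.asarray(A, float))
    return out


def adaptation_regularizer(adapted_networks: list[np.ndarray],
                           global_networks: list[np.ndarray],
                           alphas: np.ndarray) -> float:
    """sum_k alpha_k * ||A_adapted_k - A_global_k||_F^2 (zero-padded to the
    global index by the caller when shapes differ)."""
    total = 0.0
    for alpha, A_d, A_g in zip(alphas, adapted_networks, global_networks):
        diff = np.asarray(A_d, float) - np.asarray(A_g, float)
        total += alpha * float(np.sum(diff * diff))
    return total


def alpha_coefficients(networks: list[np.ndarray]) -> np.ndarray:
    """Regularization coefficients proportional to per-network edge counts."""
    counts = np.array([float(np.count_nonzero(A)) for A in networks])
    total = counts.sum()
    if total == 0:
        raise ValueError("no edges in any network")
    return counts / total
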