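"""Knowledge-graph regularization of the learned embeddings.

Each triple (h, r, t) is scored by a relation-diagonal bilinear form
f_r(h, t) = z_h^T diag(R_r) z_t; a margin ranking loss pushes true triples to
outscore randomly corrupted ones.  Entities that are drugs or targets share
the encoder embeddings, so the ranking gradient flows back into the encoder;
pure ontology terms (GO-like categories) get free embedding vectors of the
same width trained only by this loss.  An additive translation (TransE-style)
score is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .io import KnowledgeGraph

__all__ = ["KgLossConfig", "RelationParams", "init_relation_params",
           "score_triple", "score_triples", "corrupt", "kg_ranking_loss",
           "combined_loss"]


@dataclass
class KgLossConfig:
    margin: float = 1.0
    corruptions_per_triple: int = 1
    lambda_kg: float = 0.1
    scoring: str = "bilinear"  # bilinear (default) | transe

    def __post_init__(self):
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if self.corruptions_per_triple < 1:
            raise ValueError("need at least one corruption per triple")
        if self.lambda_kg < 0:
            raise ValueError("lambda_kg must be nonnegative")
        if self.scoring not in ("bilinear", "transe"):
            raise ValueError(f"unknown scoring {self.scoring!r}")


@dataclass
class RelationParams:
    """Per-relation parameter vectors of length h (the diagonal of R_r, or
    the translation vector under the additive scoring)."""

    relations: list[str]
    vectors: dict[str, Tensor]

    def parameters(self) -> list[Tensor]:
        return list(self.vectors.values())


def init_relation_params(relations, h: int,
                         rng: np.random.Generator) -> RelationParams:
    relations = list(relations)
    vectors = {
        r: Tensor(rng.uniform(-np.sqrt(6.0 / (2 * h)),
                              np.sqrt(6.0 / (2 * h)), size=h),
                  requires_grad=True)
        for r in relations
    }
    return RelationParams(relations=relations, vectors=vectors)


def score_triple(z_h, relation: str, z_t, params: RelationParams,
                 scoring: str = "bilinear") -> float:
    """Plausibility of a single triple from plain embedding vectors."""
    if relation not in params.vectors:
        raise KeyError(f"unknown relation {relation!r}")
    zh = np.asarray(z_h.data if isinstance(z_h, Tensor) else z_h, float)
    zt = np.asarray(z_t.data if isinstance(z_t, Tensor) else z_t, float)
    diag = params.vectors[relation].data
    if scoring == "bilinear":
        return float(np.sum(zh * diag * zt))
    return float(-np.linalg.norm(zh + diag - zt))


def score_triples(Z_all: Tensor, heads: np.ndarray, rel_matrix: Tensor,
                  tails: np.ndarray, scoring: str = "bilinear") -> Tensor:
    """Batched differentiable triple scores.

    `rel_matrix` holds one relation vector per triple (row-aligned with
    heads/tails); returns a length-N tensor of scores.
    """
    zh = Z_all.take_rows(heads)
    zt = Z_all.take_rows(tails)
    if scoring == "bilinear":
        return (zh * rel_matrix * zt).sum(axis=1)
    diff = zh + rel_matrix - zt
    return -((diff * diff).sum(axis=1) + 1e-12) ** 0.5


def corrupt(triple_indices: np.ndarray, n_entities: int, k: int,
            known: set, rng: np.random.Generator,
            max_resample: int = 100) -> np.ndarray:
    """k corruptions per triple: replace head or tail (uniformly chosen) with
    a random entity; corruptions colliding with known true triples are
    resampled (filtered setting).

    `triple_indices` is (N, 3) of (head, relation, tail) integer indices;
    `known` is the set of true (h, r, t) index tuples.  Returns (N*k, 3).
    """
    if n_entities < 2:
        raise ValueError("entity pool must contain more than one entity")
    triple_indices = np.asarray(triple_indices, dtype=int).reshape(-1, 3)
    out = np.empty((len(triple_indices) * k, 3), dtype=int)
    row = 0
    for h, r, t in triple_indices:
        for _ in range(k):
            for attempt in range(max_resample):
                replace_head = bool(rng.integers(2))
                e = int(rng.integers(n_entities))
                cand = (e, r, t) if replace_head else (h, r, e)
                if cand != (h, r, t) and cand not in known:
                    out[row] = cand
                    break
            else:
                raise RuntimeError(
                    "corruption pool exhausted: every candidate is a known "
                    f"true triple for ({h}, {r}, {t})")
            row += 1
    return out


def kg_ranking_loss(true_scores: Tensor, corrupt_scores: Tensor,
                    margin: float, corruptions_per_triple: int = 1) -> Tensor:
    """Hinge sum max(0, margin + f(corrupt) - f(true)) over matched pairs.

    When k corruptions per triple are used, true scores are repeated to align
    with the corrupt score vector.
    """
    if corruptions_per_triple > 1:
        idx = np.repeat(np.arange(true_scores.shape[0]),
                        corruptions_per_triple)
        true_scores = true_scores.take_rows(idx)
    return (corrupt_scores - true_scores + margin).relu().sum()


def combined_loss(L_rec, L_kg, lambda_kg: float):
    """Total representation objective L_rec + lambda * L_kg."""
    return L_rec + lambda_kg * L_kg


def triples_to_indices(kg: KnowledgeGraph,
                       entity_index: dict[str, int]) -> np.ndarray:
    """Map string triples onto (head, relation, tail) integer index rows
    using a caller-supplied entity index and the KG's relation ordering."""
    rel_index = {r: i for i, r in enumerate(kg.relations)}
    rows = [
        (entity_index[h], rel_index[r], entity_index[t])
        for h, r, t in kg.triples
    ]
    return np.asarray(rows, dtype=int).reshape(-1, 3)
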