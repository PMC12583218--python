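"""Ranking metrics for interaction prediction.

AUROC and AUPR go through scikit-learn (average ranks for AUROC ties,
step-wise precision-recall area for AUPR); F1 and precision-at-K are computed
directly, with a deterministic tie-break by pair identifier for P@K.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = ["MetricReport", "auroc", "aupr", "f1_at_threshold",
           "best_f1", "precision_at_k", "evaluate_ranking"]


@dataclass
class MetricReport:
    """Per-fold metrics with cross-fold mean and standard deviation."""

    folds: list[dict] = field(default_factory=list)

    def add(self, **metrics):
        self.folds.append(dict(metrics))

    def summary(self) -> dict:
        if not self.folds:
            return {}
        keys = self.folds[0].keys()
        out = {}
        for key in keys:
            vals = np.array([f[key] for f in self.folds], dtype=float)
            out[f"{key}_mean"] = float(vals.mean())
            out[f"{key}_std"] = float(vals.std())
        return out


def _check(labels, scores):
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("labels and scores must align")
    return labels, scores


def auroc(labels, scores) -> float:
    """Probability a random positive outscores a random negative (ties count
    half); requires both classes present."""
    labels, scores = _check(labels, scores)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, scores))


def aupr(labels, scores) -> float:
    """Step-wise interpolated area under the precision-recall curve."""
    labels, scores = _check(labels, scores)
    if labels.sum() == 0:
        raise ValueError("AUPR needs at least one positive")
    return float(average_precision_score(labels, scores))


def f1_at_threshold(labels, scores, threshold: float) -> float:
    """2PR/(P+R) at a fixed score threshold; 0 when P + R = 0."""
    labels, scores = _check(labels, scores)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    if 2 * tp + fp + fn == 0:
        return 0.0
    return 2 * tp / (2 * tp + fp + fn)


def best_f1(labels, scores) -> tuple[float, float]:
    """(best F1, threshold achieving it) over the observed score levels."""
    labels, scores = _check(labels, scores)
    best, best_thr = 0.0, np.inf
    for thr in np.unique(scores):
        f1 = f1_at_threshold(labels, scores, thr)
        if f1 > best:
            best, best_thr = f1, float(thr)
    return best, best_thr


def precision_at_k(labels, scores, k: int, pair_ids=None) -> float:
    """Fraction of positives among the top-k scores.

    Ties at the score boundary are broken deterministically by pair id
    (lexicographic) when given, else by position.
    """
    labels, scores = _check(labels, scores)
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(labels):
        raise ValueError("k exceeds the number of pairs")
    if pair_ids is None:
        pair_ids = np.arange(len(labels))
    order = sorted(range(len(labels)),
                   key=lambda i: (-scores[i], pair_ids[i]))
    top = order[:k]
    return float(labels[top].sum() / k)


def evaluate_ranking(labels, scores, k: int = 10,
                     f1_threshold: float | None = None,
                     pair_ids=None) -> dict:
    """All four metrics at once; F1 at the given threshold or its best
    operating point when none is supplied."""
    labels, scores = _check(labels, scores)
    if f1_threshold is None:
        f1, _ = best_f1(labels, scores)
    else:
        f1 = f1_at_threshold(labels, scores, f1_threshold)
    return {
        "auroc": auroc(labels, scores),
        "aupr": aupr(labels, scores),
        "f1": f1,
        "p_at_k": precision_at_k(labels, scores, min(k, len(labels)),
                                 pair_ids=pair_ids),
    }
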