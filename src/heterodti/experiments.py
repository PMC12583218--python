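"""Evaluation drivers: k-fold cross-validation, cold-start scenarios, and
ablation studies over the synthetic fixture.

Evaluation follows the standard link-prediction protocol: observed
interactions are positives, and every pair without an observed interaction in
the evaluation block is treated as a negative.  Pairs (positive and negative)
are partitioned into folds so validation and test negatives stay disjoint.
"""

from __future__ import annotations

import numpy as np

from . import metrics as metrics_mod
from .model import DTIData, DTIPredictor
from .splits import cold_start_splits, kfold_splits

__all__ = ["all_pairs_and_labels", "evaluate_rotation", "cross_validate",
           "cold_start_evaluate", "ablation_study", "random_baseline"]


def all_pairs_and_labels(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Every (i, j) pair with its observed 0/1 label."""
    m, n = Y.shape
    pairs = np.column_stack([np.repeat(np.arange(m), n),
                             np.tile(np.arange(n), m)])
    return pairs, Y.ravel().astype(int)


def _pair_ids(pairs: np.ndarray) -> list:
    return [(int(i), int(j)) for i, j in pairs]


def evaluate_rotation(data: DTIData, Y: np.ndarray, seed: int,
                      k: int = 10, rotation: int = 0, p_at: int = 10,
                      **estimator_kwargs) -> dict:
    """Train on k-2 folds, early-stop on one, report metrics on the test
    fold.  Returns the metric dict plus the fitted model under "model"."""
    pairs, labels = all_pairs_and_labels(Y)
    plan = kfold_splits(pairs, k, seed)
    rot = plan.rotation(rotation)
    model = DTIPredictor(random_state=seed, **estimator_kwargs)
    model.fit(pairs[rot["train"]], labels[rot["train"]], data=data,
              val_X=pairs[rot["val"]], val_y=labels[rot["val"]])
    test_pairs = pairs[rot["test"]]
    test_labels = labels[rot["test"]]
    scores = model.decision_function(test_pairs)
    out = metrics_mod.evaluate_ranking(test_labels, scores, k=p_at,
                                       pair_ids=_pair_ids(test_pairs))
    out["prevalence"] = float(test_labels.mean())
    out["n_test"] = int(len(test_labels))
    out["model"] = model
    return out


def cross_validate(data: DTIData, Y: np.ndarray, seed: int, k: int = 10,
                   n_rotations: int | None = None, p_at: int = 10,
                   **estimator_kwargs) -> metrics_mod.MetricReport:
    """Full k-fold protocol: every pair is tested exactly once when all k
    rotations run (n_rotations trims that for quick studies)."""
    report = metrics_mod.MetricReport()
    for r in range(n_rotations or k):
        res = evaluate_rotation(data, Y, seed, k=k, rotation=r, p_at=p_at,
                                **estimator_kwargs)
        res.pop("model")
        res.pop("n_test")
        report.add(**res)
    return report


def cold_start_evaluate(data: DTIData, Y: np.ndarray, scenario: str,
                        seed: int, fraction: float = 0.2, p_at: int = 10,
                        **estimator_kwargs) -> dict:
    """Hold out entities (S1 drugs / S2 targets) or pairs (S3), train on the
    rest, and score the held-out block."""
    pos_pairs = np.argwhere(Y == 1)
    plan = cold_start_splits(pos_pairs, scenario, fraction=fraction,
                             seed=seed)
    train_pos = pos_pairs[plan.train_idx]
    test_pos = pos_pairs[plan.test_idx]

    m, n = Y.shape
    if scenario == "S1":
        held = set(plan.held_out_entities.tolist())
        neg = np.argwhere(Y == 0)
        test_neg = neg[np.isin(neg[:, 0], list(held))]
    elif scenario == "S2":
        held = set(plan.held_out_entities.tolist())
        neg = np.argwhere(Y == 0)
        test_neg = neg[np.isin(neg[:, 1], list(held))]
    else:
        rng = np.random.default_rng(seed + 1)
        neg = np.argwhere(Y == 0)
        take = min(len(neg), 20 * len(test_pos))
        test_neg = neg[rng.choice(len(neg), size=take, replace=False)]

    model = DTIPredictor(random_state=seed, **estimator_kwargs)
    X_train = train_pos
    y_train = np.ones(len(train_pos), dtype=int)
    model.fit(X_train, y_train, data=data)
    test_pairs = np.vstack([test_pos, test_neg])
    test_labels = np.concatenate([np.ones(len(test_pos)),
                                  np.zeros(len(test_neg))]).astype(int)
    scores = model.decision_function(test_pairs)
    out = metrics_mod.evaluate_ranking(test_labels, scores, k=p_at,
                                       pair_ids=_pair_ids(test_pairs))
    out["prevalence"] = float(test_labels.mean())
    out["scenario"] = scenario
    return out


VARIANTS = {
    "full": {},
    "no_kg": {"use_kg": False},
    "no_attention": {"use_attention": False},
    "random_sampling": {"negative_sampling": "random"},
}


def ablation_study(data: DTIData, Y: np.ndarray, seeds,
                   variants: dict | None = None, k: int = 10,
                   **estimator_kwargs) -> dict:
    """Per-variant metrics over several seeds plus across-seed medians."""
    variants = variants or VARIANTS
    results: dict = {name: {"auroc": [], "aupr": []} for name in variants}
    for seed in seeds:
        for name, overrides in variants.items():
            kwargs = dict(estimator_kwargs)
            kwargs.update(overrides)
            res = evaluate_rotation(data, Y, int(seed), k=k, **kwargs)
            results[name]["auroc"].append(res["auroc"])
            results[name]["aupr"].append(res["aupr"])
    for name in variants:
        results[name]["auroc_median"] = float(
            np.median(results[name]["auroc"]))
        results[name]["aupr_median"] = float(
            np.median(results[name]["aupr"]))
    return results


def random_baseline(labels, seed: int) -> dict:
    """Metrics of uniform random scores on the same labels."""
    rng = np.random.default_rng(seed)
    scores = rng.random(len(labels))
    return {
        "auroc": metrics_mod.auroc(labels, scores),
        "aupr": metrics_mod.aupr(labels, scores),
    }
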