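"""Cross-validation and cold-start split plans over drug-target pairs.

The k-fold plan partitions pairs into k disjoint folds; each rotation uses
one fold for testing, one for validation and the remaining k-2 for training,
so every pair is tested exactly once across rotations.  Cold-start scenarios
hold out entities rather than pairs: S1 removes a fraction of drugs with all
their pairs, S2 does the same for targets, and S3 removes pairs while
guaranteeing both endpoints stay visible in training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SplitPlan", "kfold_splits", "cold_start_splits"]


@dataclass
class SplitPlan:
    """Fold assignment per pair, or a single cold-start scenario split."""

    pairs: np.ndarray  # (N, 2) int pairs the plan covers
    fold_of: np.ndarray | None = None  # k-fold assignment per pair
    k: int | None = None
    scenario: str | None = None  # S1 | S2 | S3
    train_idx: np.ndarray | None = None
    test_idx: np.ndarray | None = None
    held_out_entities: np.ndarray | None = None
    seed: int | None = None
    rotations: list[dict] = field(default_factory=list)

    def rotation(self, r: int) -> dict:
        """Train/validation/test pair indices of rotation r (k-fold plans)."""
        if self.k is None:
            raise ValueError("not a k-fold plan")
        test_fold = r % self.k
        val_fold = (r + 1) % self.k
        test = np.nonzero(self.fold_of == test_fold)[0]
        val = np.nonzero(self.fold_of == val_fold)[0]
        train = np.nonzero((self.fold_of != test_fold)
                           & (self.fold_of != val_fold))[0]
        return {"train": train, "val": val, "test": test}


def kfold_splits(pairs: np.ndarray, k: int, seed: int) -> SplitPlan:
    """Shuffle pairs into k disjoint folds of near-equal size."""
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if k < 2:
        raise ValueError("k-fold needs k >= 2")
    if len(pairs) < k:
        raise ValueError(f"fewer pairs ({len(pairs)}) than folds ({k})")
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(pairs), dtype=int)
    perm = rng.permutation(len(pairs))
    for pos, idx in enumerate(perm):
        fold_of[idx] = pos % k
    return SplitPlan(pairs=pairs, fold_of=fold_of, k=k, seed=seed)


def cold_start_splits(pairs: np.ndarray, scenario: str,
                      fraction: float = 0.2, seed: int = 0) -> SplitPlan:
    """Cold-start hold-out plan.

    S1 (cold drug): a fraction of drugs and every pair touching them moves to
    test.  S2 (cold target): symmetric for targets.  S3 (cold pair): a
    fraction of pairs moves to test subject to each test pair's drug and
    target still occurring in at least one training pair.
    """
    pairs = np.asarray(pairs, dtype=int).reshape(-1, 2)
    if scenario not in ("S1", "S2", "S3"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)

    if scenario in ("S1", "S2"):
        col = 0 if scenario == "S1" else 1
        entities = np.unique(pairs[:, col])
        n_hold = max(1, int(round(fraction * len(entities))))
        held = rng.choice(entities, size=n_hold, replace=False)
        held_set = set(held.tolist())
        is_test = np.array([p[col] in held_set for p in pairs])
        return SplitPlan(pairs=pairs, scenario=scenario,
                         train_idx=np.nonzero(~is_test)[0],
                         test_idx=np.nonzero(is_test)[0],
                         held_out_entities=np.sort(held), seed=seed)

    # S3: remove pairs while keeping both endpoints covered in training
    n_hold = max(1, int(round(fraction * len(pairs))))
    drug_count: dict[int, int] = {}
    target_count: dict[int, int] = {}
    for d, t in pairs:
        drug_count[d] = drug_count.get(d, 0) + 1
        target_count[t] = target_count.get(t, 0) + 1
    order = rng.permutation(len(pairs))
    test: list[int] = []
    for idx in order:
        if len(test) == n_hold:
            break
        d, t = pairs[idx]
        if drug_count[d] > 1 and target_count[t] > 1:
            test.append(idx)
            drug_count[d] -= 1
            target_count[t] -= 1
    if len(test) < n_hold:
        raise ValueError(
            f"cold-pair constraint unsatisfiable at fraction {fraction}; "
            "try a smaller fraction")
    test_idx = np.asarray(sorted(test), dtype=int)
    mask = np.ones(len(pairs), dtype=bool)
    mask[test_idx] = False
    return SplitPlan(pairs=pairs, scenario="S3",
                     train_idx=np.nonzero(mask)[0], test_idx=test_idx,
                     seed=seed)
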