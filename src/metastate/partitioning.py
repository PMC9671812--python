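"""Spatially nested cross-validation over recruitment centers.

Each fold holds out every participant of one center as the test set; the
remaining centers are pooled and a uniform random 10% (configurable) becomes
the validation set, the rest the training set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

__all__ = ["Fold", "PartitionPlan", "make_partitions", "audit_partitions"]


@dataclass
class Fold:
    test_center_id: int
    train_ids: np.ndarray
    valid_ids: np.ndarray
    test_ids: np.ndarray


@dataclass
class PartitionPlan:
    folds: List[Fold]
    valid_fraction: float
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "valid_fraction": self.valid_fraction,
            "seed": self.seed,
            "folds": [
                {
                    "test_center_id": int(f.test_center_id),
                    "train_ids": [int(i) for i in f.train_ids],
                    "valid_ids": [int(i) for i in f.valid_ids],
                    "test_ids": [int(i) for i in f.test_ids],
                }
                for f in self.folds
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PartitionPlan":
        with open(path) as fh:
            payload = json.load(fh)
        folds = [
            Fold(
                test_center_id=f["test_center_id"],
                train_ids=np.asarray(f["train_ids"], dtype=np.int64),
                valid_ids=np.asarray(f["valid_ids"], dtype=np.int64),
                test_ids=np.asarray(f["test_ids"], dtype=np.int64),
            )
            for f in payload["folds"]
        ]
        return cls(folds=folds, valid_fraction=payload["valid_fraction"],
                   seed=payload["seed"])


def make_partitions(cohort: pd.DataFrame, valid_fraction: float = 0.10,
                    seed: int = 0) -> PartitionPlan:
    """One fold per center; validation is a uniform draw from the pooled rest.

    The validation size uses floor(valid_fraction * pooled size).
    """
    if not 0.0 < valid_fraction < 1.0:
        raise ValueError("valid_fraction must be in (0,1)")
    centers = np.sort(cohort["center_id"].unique())
    if len(centers) < 2:
        raise ValueError("need at least 2 distinct centers for spatial folds")
    rng = np.random.default_rng(seed)
    ids = cohort["participant_id"].to_numpy()
    center = cohort["center_id"].to_numpy()
    folds = []
    for c in centers:
        test_ids = ids[center == c]
        pool = ids[center != c]
        n_valid = int(np.floor(valid_fraction * len(pool)))
        valid_ids = rng.choice(pool, size=n_valid, replace=False)
        valid_set = set(valid_ids.tolist())
        train_ids = np.array([i for i in pool if i not in valid_set], dtype=np.int64)
        folds.append(Fold(test_center_id=int(c), train_ids=train_ids,
                          valid_ids=np.sort(valid_ids), test_ids=test_ids))
    plan = PartitionPlan(folds=folds, valid_fraction=valid_fraction, seed=seed)
    audit_partitions(plan, cohort)
    return plan


def audit_partitions(plan: PartitionPlan, cohort: pd.DataFrame) -> dict:
    """Leakage audit: disjointness within folds, full test coverage across folds.

    Raises AssertionError on violation; returns a summary dict otherwise.
    """
    all_ids = set(cohort["participant_id"].tolist())
    seen_test: set = set()
    for f in plan.folds:
        tr, va, te = set(f.train_ids.tolist()), set(f.valid_ids.tolist()), set(f.test_ids.tolist())
        assert not (tr & te), f"fold {f.test_center_id}: train/test overlap"
        assert not (va & te), f"fold {f.test_center_id}: valid/test overlap"
        assert not (tr & va), f"fold {f.test_center_id}: train/valid overlap"
        assert tr | va | te == all_ids, f"fold {f.test_center_id}: ids lost"
        assert not (seen_test & te), "test sets overlap across folds"
        seen_test |= te
    assert seen_test == all_ids, "union of test sets != cohort"
    return {"n_folds": len(plan.folds), "n_participants": len(all_ids), "passed": True}
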