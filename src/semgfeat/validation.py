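"""Repetition-split classification harness.

Offline myoelectric studies hold out whole movement repetitions: every
window from a training repetition goes to the training set and every
window from a held-out repetition to the test set, so train and test
windows never overlap in time.  The default split trains on repetitions
{1, 3, 4, 6} and tests on {2, 5}.

Rest windows carry repetition 0; they are assigned to a side by the
repetition id of the nearest *following* movement window (trailing rest
inherits the preceding one), so the rest class is represented in both
sets.  Classification uses a 100-tree random forest over all classes
(rest included) and reports both plain accuracy and the class-balanced
(macro-averaged per-class) accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .engine import FeatureMatrix

__all__ = ["SplitSpec", "AccuracySummary", "split_by_repetition", "evaluate_classification"]


@dataclass(frozen=True)
class SplitSpec:
    """Which repetition ids train and which test."""

    train_repetitions: frozenset = frozenset({1, 3, 4, 6})
    test_repetitions: frozenset = frozenset({2, 5})
    rest_assignment: str = "nearest_following"  # or "drop"

    def __post_init__(self) -> None:
        train = frozenset(self.train_repetitions)
        test = frozenset(self.test_repetitions)
        if not train or not test:
            raise ValueError("train and test repetition sets must be nonempty")
        if train & test:
            raise ValueError(f"repetitions {sorted(train & test)} in both sets")
        if self.rest_assignment not in ("nearest_following", "drop"):
            raise ValueError("rest_assignment must be 'nearest_following' or 'drop'")
        object.__setattr__(self, "train_repetitions", train)
        object.__setattr__(self, "test_repetitions", test)


def _effective_repetitions(featRep: np.ndarray, rest_assignment: str) -> np.ndarray:
    """Repetition id used for splitting; rest rows (0) inherit the next
    movement window's repetition, trailing rest the previous one."""
    rep = np.asarray(featRep, dtype=np.int64).copy()
    if rest_assignment == "drop":
        return rep
    nz = np.flatnonzero(rep)
    if nz.size == 0:
        return rep
    # backward-fill the next nonzero repetition onto rest rows
    nxt = np.full(rep.size, -1, dtype=np.int64)
    nxt[nz] = rep[nz]
    for i in range(rep.size - 2, -1, -1):
        if nxt[i] == -1:
            nxt[i] = nxt[i + 1]
    last = rep[nz[-1]]
    nxt[nxt == -1] = last  # trailing rest
    rep[rep == 0] = nxt[rep == 0]
    return rep


def _subset(fm: FeatureMatrix, mask: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        feat=fm.feat[mask],
        featStim=fm.featStim[mask],
        featRep=fm.featRep[mask],
        feature_name=fm.feature_name,
        column_layout=fm.column_layout,
    )


def split_by_repetition(
    fm: FeatureMatrix, spec: SplitSpec = SplitSpec()
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Partition a feature matrix into (train, test) by repetition id.

    Windows whose (effective) repetition is in neither set are dropped.
    Raises if either side ends up empty.
    """
    eff = _effective_repetitions(fm.featRep, spec.rest_assignment)
    train_mask = np.isin(eff, list(spec.train_repetitions))
    test_mask = np.isin(eff, list(spec.test_repetitions))
    if not train_mask.any() or not test_mask.any():
        raise ValueError(
            f"empty split: {int(train_mask.sum())} train / "
            f"{int(test_mask.sum())} test windows"
        )
    return _subset(fm, train_mask), _subset(fm, test_mask)


@dataclass(frozen=True)
class AccuracySummary:
    """Classification outcome on the held-out repetitions."""

    overall_accuracy: float
    balanced_accuracy: float
    per_class_accuracy: dict = field(default_factory=dict)
    n_train: int = 0
    n_test: int = 0

    def as_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "per_class_accuracy": {int(k): float(v) for k, v in self.per_class_accuracy.items()},
            "n_train": self.n_train,
            "n_test": self.n_test,
        }


def evaluate_classification(
    train: FeatureMatrix,
    test: FeatureMatrix,
    n_trees: int = 100,
    seed: int = 0,
    classifier=None,
) -> AccuracySummary:
    """Fit a bagged-tree ensemble on the training windows and score the
    held-out ones.

    Labels are the per-window stimulus ids (rest class 0 included).
    ``balanced_accuracy`` is the unweighted mean of per-class accuracies
    so rare classes weigh as much as frequent ones.  All stochastic
    steps (row shuffling, tree bootstraps) derive from ``seed``.
    """
    if train.feat.shape[1] != test.feat.shape[1]:
        raise ValueError("train and test feature column counts differ")
    y_train = train.featStim
    if np.unique(y_train).size < 2:
        raise ValueError("training set has fewer than 2 classes")
    rng = np.random.default_rng(seed)
    order = rng.permutation(y_train.size)
    clf = classifier
    if clf is None:
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(rng.integers(0, 2**31 - 1))
        )
    clf.fit(train.feat[order], y_train[order])
    pred = clf.predict(test.feat)
    y_test = test.featStim
    per_class = {}
    for cls in np.unique(y_test):
        mask = y_test == cls
        per_class[int(cls)] = float(np.mean(pred[mask] == cls))
    return AccuracySummary(
        overall_accuracy=float(np.mean(pred == y_test)),
        balanced_accuracy=float(np.mean(list(per_class.values()))),
        per_class_accuracy=per_class,
        n_train=int(y_train.size),
        n_test=int(y_test.size),
    )
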