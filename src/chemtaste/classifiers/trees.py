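"""Tree-ensemble backends: gradient boosting, random forest, and a
class-balanced random forest built on per-tree majority undersampling.

All three operate on Morgan-fingerprint (optionally +descriptor) features,
so their predictions are invariant to the SMILES form of a molecule.
"""

from __future__ import annotations

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from ..labels import N_CLASSES


def _expand_proba(probs: np.ndarray, present_classes: np.ndarray) -> np.ndarray:
    """Spread probabilities over the full 5-class vector; absent classes get 0."""
    out = np.zeros((probs.shape[0], N_CLASSES))
    out[:, present_classes] = probs
    return out


class SklearnStyleBackend:
    """Common predict path for backends exposing classes_ / predict_proba."""

    def __init__(self, estimator):
        self.estimator = estimator
        self.classes_override = None  # original 5-class indices when labels were remapped

    def fit(self, X, y):
        self.estimator.fit(X, y)
        return self

    def predict_proba(self, X) -> np.ndarray:
        probs = self.estimator.predict_proba(X)
        if self.classes_override is not None:
            classes = np.asarray(self.classes_override, dtype=int)
        else:
            classes = np.asarray(self.estimator.classes_, dtype=int)
        return _expand_proba(probs, classes)


def make_gbt(n_trees: int, max_depth: int, learning_rate: float, seed: int):
    return SklearnStyleBackend(
        XGBClassifier(
            n_estimators=n_trees,
            max_depth=max_depth,
            learning_rate=learning_rate,
            objective="multi:softprob",
            eval_metric="mlogloss",
            tree_method="hist",
            random_state=seed,
            n_jobs=1,
        )
    )


def make_rf(n_trees: int, seed: int):
    return SklearnStyleBackend(
        RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    )


class BalancedRandomForest:
    """Random forest whose every bootstrap under-samples to the minority size.

    Each of the ``n_trees`` trees is fit on a resample containing exactly
    ``min_class_count`` examples of every present class (drawn with
    replacement), so every class is equally represented during training.
    The per-tree resampled indices are retained in ``resampled_indices_``
    so the balance property can be audited.
    """

    def __init__(self, n_trees: int = 150, seed: int = 0):
        self.n_trees = n_trees
        self.seed = seed
        self.trees_: list[DecisionTreeClassifier] = []
        self.resampled_indices_: list[np.ndarray] = []
        self.classes_: np.ndarray | None = None

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        if any((y == c).sum() == 0 for c in self.classes_):
            raise ValueError("balanced_rf requires every class nonempty")
        n_min = min(int((y == c).sum()) for c in self.classes_)
        rng = np.random.default_rng(self.seed)
        self.trees_, self.resampled_indices_ = [], []
        class_indices = {c: np.flatnonzero(y == c) for c in self.classes_}
        for t in range(self.n_trees):
            idx = np.concatenate(
                [
                    rng.choice(class_indices[c], size=n_min, replace=True)
                    for c in self.classes_
                ]
            )
            tree = DecisionTreeClassifier(random_state=int(rng.integers(2**31)))
            tree.fit(X[idx], y[idx])
            self.trees_.append(tree)
            self.resampled_indices_.append(idx)
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X)
        acc = np.zeros((X.shape[0], N_CLASSES))
        for tree in self.trees_:
            probs = tree.predict_proba(X)
            acc += _expand_proba(probs, np.asarray(tree.classes_, dtype=int))
        return acc / len(self.trees_)
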