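"""Supervised forest feature detector.

A random forest is fitted on the labelled expression matrix, but instead
of being used as a classifier its M per-tree hard class votes become a
learned, low-dimensional feature representation: each sample is mapped
from p raw features to an M-vector of binary votes, which downstream
models consume one-hot encoded as an ``n x M x 2`` tensor.

Alongside the votes, the detector records the ``p x M`` tree importance
matrix ``S`` whose column m holds tree m's impurity-decrease feature
importances (normalized to sum to one per tree).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .data import ExpressionDataset

__all__ = ["ForestDetector", "TreeFeatureMatrix", "one_hot_encode", "flatten_one_hot"]


@dataclass
class TreeFeatureMatrix:
    """Per-tree binary votes for a batch of samples."""

    predictions: np.ndarray  # (n, M) in {0, 1}

    def __post_init__(self) -> None:
        self.predictions = np.asarray(self.predictions)
        if not np.isin(self.predictions, (0, 1)).all():
            raise ValueError("tree votes must be binary 0/1")
        self.predictions = self.predictions.astype(int)

    @property
    def one_hot(self) -> np.ndarray:
        return one_hot_encode(self.predictions)

    def majority_vote(self) -> np.ndarray:
        """Hard forest prediction: class 1 iff strictly more than half the votes."""
        return (self.predictions.mean(axis=1) > 0.5).astype(int)


def one_hot_encode(votes: np.ndarray) -> np.ndarray:
    """Encode binary votes as an ``n x M x 2`` tensor: 0 -> (1,0), 1 -> (0,1)."""
    votes = np.asarray(votes)
    if not np.isin(votes, (0, 1)).all():
        raise ValueError("one_hot_encode expects binary 0/1 input")
    votes = votes.astype(int)
    tensor = np.zeros(votes.shape + (2,), dtype=float)
    np.put_along_axis(tensor, votes[..., None], 1.0, axis=-1)
    return tensor


def flatten_one_hot(tensor: np.ndarray) -> np.ndarray:
    """Flatten ``n x M x 2`` to ``n x 2M``, channel-major per tree.

    Tree m occupies columns ``2m`` (class-0 channel) and ``2m+1``
    (class-1 channel).  This fixed convention defines the dense-layer
    interface of the neural head.
    """
    tensor = np.asarray(tensor)
    if tensor.ndim != 3 or tensor.shape[-1] != 2:
        raise ValueError(f"expected an (n, M, 2) tensor, got shape {tensor.shape}")
    return tensor.reshape(tensor.shape[0], -1)


class ForestDetector:
    """Random-forest stage of the classifier.

    Parameters mirror scikit-learn's random forest: bootstrap rows,
    sqrt(p) candidate features per split, unlimited depth by default.
    """

    def __init__(
        self,
        num_trees: int = 300,
        max_depth: int | None = None,
        min_samples_split: int = 2,
        max_features: str | int | float = "sqrt",
        seed: int | None = None,
    ):
        if num_trees < 1:
            raise ValueError("num_trees must be >= 1")
        self.num_trees = num_trees
        self.max_depth = max_depth
        self.min_samples_split = min_samples_split
        self.max_features = max_features
        self.seed = seed
        self.forest_: RandomForestClassifier | None = None
        self.tree_importance_: np.ndarray | None = None
        self.feature_count_: int | None = None

    @property
    def fitted(self) -> bool:
        return self.forest_ is not None

    def fit(self, dataset: ExpressionDataset) -> "ForestDetector":
        if dataset.n_samples < 2:
            raise ValueError("need at least 2 samples to fit the forest")
        if not dataset.both_classes_present():
            raise ValueError("both classes must be present in the training labels")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.num_trees,
            max_depth=self.max_depth,
            min_samples_split=self.min_samples_split,
            max_features=self.max_features,
            bootstrap=True,
            random_state=self.seed,
            n_jobs=1,
        )
        self.forest_.fit(dataset.X, dataset.y)
        self.feature_count_ = dataset.n_features
        self.tree_importance_ = self._collect_tree_importances()
        return self

    def _collect_tree_importances(self) -> np.ndarray:
        # sklearn already normalizes each tree's impurity decreases to sum 1
        # (degenerate single-leaf trees yield all zeros)
        cols = [tree.feature_importances_ for tree in self.forest_.estimators_]
        return np.column_stack(cols)

    def predict_trees(self, X: np.ndarray) -> TreeFeatureMatrix:
        """Hard class vote of every tree for every sample."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != self.feature_count_:
            raise ValueError(
                f"X has {X.shape[1]} features, detector was fitted on {self.feature_count_}"
            )
        votes = np.column_stack(
            [tree.predict(X) for tree in self.forest_.estimators_]
        )
        return TreeFeatureMatrix(predictions=votes)

    def tree_importance_matrix(self) -> np.ndarray:
        """The ``p x M`` matrix S; column m sums to 1 (or 0 for a stump-less tree)."""
        self._check_fitted()
        return self.tree_importance_

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class-1 probability as the fraction of trees voting 1 (forest baseline)."""
        return self.predict_trees(X).predictions.mean(axis=1)

    def _check_fitted(self) -> None:
        if not self.fitted:
            raise RuntimeError("ForestDetector is not fitted; call fit() first")
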