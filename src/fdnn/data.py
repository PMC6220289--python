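"""Core in-memory container for labelled expression matrices.

The package works on the usual bulk / single-cell convention of an
``n x p`` numeric matrix (samples in rows, features/genes in columns)
with a binary outcome per sample.  ``n << p`` is the regime of interest
but nothing here enforces it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ExpressionDataset:
    """An ``n x p`` expression matrix with binary labels.

    Parameters
    ----------
    X : ndarray of shape (n, p)
        Numeric expression values, samples in rows.
    y : ndarray of shape (n,)
        Binary class labels in {0, 1}.
    feature_names : list of str, optional
        Length-p feature (gene) names; defaults to ``f0001``-style names.
    sample_ids : list of str, optional
        Length-n sample identifiers; defaults to ``s0001``-style ids.
    provenance : dict
        Free-form description of how the data was produced (generator
        parameters, seed, file of origin, transforms applied).
    """

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] | None = None
    sample_ids: list[str] | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError(f"X must be 2-dimensional, got shape {self.X.shape}")
        n, p = self.X.shape
        if self.y.shape != (n,):
            raise ValueError(f"y has shape {self.y.shape}, expected ({n},)")
        if not np.isfinite(self.X).all():
            raise ValueError("X contains non-finite values")
        uniq = set(np.unique(self.y).tolist())
        if not uniq <= {0, 1}:
            raise ValueError(f"labels must be binary 0/1, found {sorted(uniq)}")
        self.y = self.y.astype(int)
        if self.feature_names is None:
            width = max(4, len(str(p)))
            self.feature_names = [f"f{j:0{width}d}" for j in range(p)]
        if self.sample_ids is None:
            width = max(4, len(str(n)))
            self.sample_ids = [f"s{i:0{width}d}" for i in range(n)]
        if len(self.feature_names) != p:
            raise ValueError("feature_names length does not match number of columns")
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match number of rows")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def both_classes_present(self) -> bool:
        return 0 in self.y and 1 in self.y

    def subset(self, indices: np.ndarray) -> "ExpressionDataset":
        """Row-subset (samples) preserving metadata."""
        indices = np.asarray(indices)
        return ExpressionDataset(
            X=self.X[indices],
            y=self.y[indices],
            feature_names=list(self.feature_names),
            sample_ids=[self.sample_ids[i] for i in indices],
            provenance=dict(self.provenance),
        )
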