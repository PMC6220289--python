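"""Two-stage forest + neural-network classifier and its feature importance.

Stage 1 fits a random forest on the labelled expression matrix; stage 2
trains a small softmax MLP on the one-hot encoded per-tree votes of the
same training rows.  Prediction composes the two stages.  Feature
importance combines them: the forest side contributes the p x M per-tree
impurity-importance matrix S, the network side contributes the
Connection Weights score of each tree's input unit, normalized to v*
with sum 1, and the final per-gene score is

    lambda = S v*

so a gene is important if it splits high up in trees that the network
itself relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ExpressionDataset
from .forest import ForestDetector, flatten_one_hot
from .nn import DNNHead, TrainConfig, normalize_importance

__all__ = ["FDNNModel", "ImportanceReport", "top_genes"]

#: architectures used in the published experiments
PRESETS = {
    "simulation": {"num_trees": 300, "hidden_sizes": (256, 64, 16)},
    "gse99095": {"num_trees": 400, "hidden_sizes": (256, 64, 16)},
    "gse106291": {"num_trees": 500, "hidden_sizes": (256, 64, 16)},
}


@dataclass
class ImportanceReport:
    """Combined importance of every original feature."""

    S: np.ndarray            # (p, M) per-tree impurity importances
    v: np.ndarray            # (M,) raw Connection Weights tree scores
    v_star: np.ndarray       # (M,) normalized, sums to 1
    lam: np.ndarray          # (p,) final scores, lam = S @ v_star
    feature_names: list[str]

    def ranking(self) -> np.ndarray:
        """Feature indices ordered by descending score, ties broken by index."""
        # stable sort on -lam keeps the lower index first among ties
        return np.argsort(-self.lam, kind="stable")

    def ranked_features(self) -> list[tuple[str, float]]:
        order = self.ranking()
        return [(self.feature_names[i], float(self.lam[i])) for i in order]


def top_genes(report: ImportanceReport, fraction: float) -> list[str]:
    """The ceil(fraction * p) highest-scoring features, ties broken by index."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    p = report.lam.size
    k = int(np.ceil(fraction * p))
    order = report.ranking()
    return [report.feature_names[i] for i in order[:k]]


class FDNNModel:
    """Forest feature detector + fully-connected softmax head."""

    def __init__(
        self,
        num_trees: int = 300,
        hidden_sizes: tuple[int, ...] = (256, 64, 16),
        forest_params: dict | None = None,
        train_config: TrainConfig | None = None,
        seed: int | None = None,
    ):
        self.num_trees = num_trees
        self.hidden_sizes = tuple(hidden_sizes)
        self.forest_params = dict(forest_params or {})
        self.train_config = train_config
        self.seed = seed
        self.detector: ForestDetector | None = None
        self.head: DNNHead | None = None

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "FDNNModel":
        if name not in PRESETS:
            raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
        params = {**PRESETS[name], **overrides}
        return cls(**params)

    @property
    def fitted(self) -> bool:
        return self.head is not None and self.head.fitted

    def fit(self, dataset: ExpressionDataset) -> "FDNNModel":
        """Two-stage training on the same rows: forest first, then the head."""
        ss = np.random.SeedSequence(self.seed)
        forest_seed, head_seed, train_seed = (
            int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(3)
        )
        self.detector = ForestDetector(
            num_trees=self.num_trees, seed=forest_seed, **self.forest_params
        )
        self.detector.fit(dataset)

        votes = self.detector.predict_trees(dataset.X)
        inputs = flatten_one_hot(votes.one_hot)
        layer_sizes = (2 * self.num_trees, *self.hidden_sizes, 2)
        self.head = DNNHead(layer_sizes, seed=head_seed)
        cfg = self.train_config or TrainConfig()
        cfg = TrainConfig(**{**cfg.__dict__, "seed": cfg.seed if cfg.seed is not None else train_seed})
        self.head.train(inputs, dataset.y, cfg)
        self._feature_names = list(dataset.feature_names)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class-1 probability: tree votes -> one-hot -> head forward."""
        self._check_fitted()
        votes = self.detector.predict_trees(X)
        return self.head.predict_proba(flatten_one_hot(votes.one_hot))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.predict_proba(X) > 0.5).astype(int)

    def feature_importance(self) -> ImportanceReport:
        """Combined per-gene importance lambda = S v*."""
        self._check_fitted()
        S = self.detector.tree_importance_matrix()
        v = self.head.connection_weight_importance(pooled_channels=True)
        v_star = normalize_importance(v)
        lam = S @ v_star
        return ImportanceReport(
            S=S, v=v, v_star=v_star, lam=lam, feature_names=self._feature_names
        )

    def _check_fitted(self) -> None:
        if not self.fitted:
            raise RuntimeError("model is not fitted; call fit() first")
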