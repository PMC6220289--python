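"""Simulation benchmark: replicated datasets, 4:1 splits, AUC comparison grid.

The grid reproduces the simulation study design: for each predictor
regime (clustered / scattered) and each number of true predictors, R
replicate datasets are generated, each split 4:1 into train and test
(stratified), and five methods are scored by test AUC:

* ``fDNN``       — forest detector + neural head,
* ``RF_300``     — the very forest fitted inside fDNN, scored directly,
* ``RF_500``     — an independent 500-tree random forest,
* ``DNN_3_256``  — plain MLP on the raw expression matrix, hidden 256/64/16,
* ``DNN_4_1024`` — plain MLP with an extra 1024-unit layer on top.

Mean AUC per (case, p0, method) cell mirrors the benchmark table layout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve
from sklearn.model_selection import train_test_split

from .data import ExpressionDataset
from .forest import ForestDetector
from .model import FDNNModel
from .nn import DNNHead, TrainConfig
from .synthetic import SimulationConfig, generate_dataset

__all__ = [
    "ExperimentGrid",
    "split_train_test",
    "auc",
    "roc_curve",
    "run_experiment_grid",
    "evaluate_replicate",
    "METHODS",
]

METHODS = ("fDNN", "DNN_3_256", "DNN_4_1024", "RF_300", "RF_500")


def split_train_test(
    dataset: ExpressionDataset, ratio: float = 0.8, seed: int | None = None
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Stratified train/test split; ``ratio`` is the training fraction (4:1 -> 0.8)."""
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must lie in (0, 1), got {ratio}")
    idx = np.arange(dataset.n_samples)
    train_idx, test_idx = train_test_split(
        idx, train_size=ratio, stratify=dataset.y, random_state=seed
    )
    train, test = dataset.subset(train_idx), dataset.subset(test_idx)
    if not (train.both_classes_present() and test.both_classes_present()):
        raise ValueError("split left a partition with a single class")
    return train, test


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC: P(random positive outranks random negative), ties count 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if len(set(np.unique(labels).tolist())) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(labels, scores))


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ROC points (FPR, TPR) from (0,0) to (1,1); trapezoidal area equals auc()."""
    labels = np.asarray(labels)
    if len(set(np.unique(labels).tolist())) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, _ = _sk_roc_curve(labels, np.asarray(scores, dtype=float),
                                drop_intermediate=False)
    return fpr, tpr


@dataclass
class ExperimentGrid:
    """Full factorial benchmark: cases x predictor counts x replicates x methods."""

    cases: tuple[str, ...] = ("clustered", "scattered")
    p0_values: tuple[int, ...] = (10, 20, 30, 40, 50)
    replicates: int = 10
    methods: tuple[str, ...] = METHODS
    base_seed: int = 0
    p: int = 5000
    n: int = 400
    train_config: TrainConfig | None = None

    def simulation_config(self, case: str, p0: int) -> SimulationConfig:
        # one core per ~10 true predictors, matching the 1-5 core design
        return SimulationConfig(p=self.p, n=self.n, p0=p0, case=case,
                                num_cores=max(1, p0 // 10))


def _fit_dnn_baseline(
    train: ExpressionDataset,
    test: ExpressionDataset,
    hidden: tuple[int, ...],
    cfg: TrainConfig,
    seed: int,
) -> float:
    head = DNNHead((train.n_features, *hidden, 2), seed=seed)
    head.train(train.X, train.y, replace(cfg, seed=seed))
    return auc(head.predict_proba(test.X), test.y)


def evaluate_replicate(
    dataset: ExpressionDataset,
    methods: tuple[str, ...] = METHODS,
    seed: int = 0,
    train_config: TrainConfig | None = None,
) -> dict[str, float]:
    """Fit every requested method on one 4:1 split and return test AUCs.

    RF_300 is scored from the same fitted forest that feeds fDNN, so the
    fDNN-vs-RF_300 comparison is paired within a replicate.
    """
    cfg = train_config or TrainConfig()
    train, test = split_train_test(dataset, ratio=0.8, seed=seed)
    out: dict[str, float] = {}

    if "fDNN" in methods:
        model = FDNNModel(num_trees=300, hidden_sizes=(256, 64, 16),
                          train_config=cfg, seed=seed)
        model.fit(train)
        out["fDNN"] = auc(model.predict_proba(test.X), test.y)
        if "RF_300" in methods:
            out["RF_300"] = auc(model.detector.predict_proba(test.X), test.y)
    elif "RF_300" in methods:
        rf = ForestDetector(num_trees=300, seed=seed).fit(train)
        out["RF_300"] = auc(rf.predict_proba(test.X), test.y)
    if "RF_500" in methods:
        rf = ForestDetector(num_trees=500, seed=seed + 1).fit(train)
        out["RF_500"] = auc(rf.predict_proba(test.X), test.y)
    if "DNN_3_256" in methods:
        out["DNN_3_256"] = _fit_dnn_baseline(train, test, (256, 64, 16), cfg, seed + 2)
    if "DNN_4_1024" in methods:
        out["DNN_4_1024"] = _fit_dnn_baseline(
            train, test, (1024, 256, 64, 16), cfg, seed + 3
        )
    return out


def run_experiment_grid(grid: ExperimentGrid, output_path=None) -> pd.DataFrame:
    """Run the full grid; returns tidy rows (case, p0, method, replicate, auc).

    If ``output_path`` is given, results stream to CSV as cells complete and a
    rerun skips cells already present (resumable).
    """
    done: set[tuple[str, int, int]] = set()
    rows: list[dict] = []
    path = Path(output_path) if output_path is not None else None
    if path is not None and path.exists():
        existing = pd.read_csv(path)
        rows = existing.to_dict("records")
        done = {
            (r["case"], int(r["p0"]), int(r["replicate"]))
            for r in rows
        }

    for case in grid.cases:
        for p0 in grid.p0_values:
            sim = grid.simulation_config(case, p0)
            for rep in range(grid.replicates):
                if (case, p0, rep) in done:
                    continue
                # deterministic per-replicate seed derived from the base seed
                case_key = sum(ord(c) for c in case)
                rep_seed = int(
                    np.random.SeedSequence(
                        [grid.base_seed, case_key, p0, rep]
                    ).generate_state(1)[0]
                    % (2**31 - 1)
                )
                dataset, _, _ = generate_dataset(sim, seed=rep_seed)
                aucs = evaluate_replicate(
                    dataset, grid.methods, seed=rep_seed, train_config=grid.train_config
                )
                for method, value in aucs.items():
                    rows.append(
                        {"case": case, "p0": p0, "method": method,
                         "replicate": rep, "auc": value}
                    )
                if path is not None:
                    pd.DataFrame(rows).to_csv(path, index=False)
    return pd.DataFrame(rows)


def pivot_results(results: pd.DataFrame) -> pd.DataFrame:
    """Benchmark-table-shaped pivot: methods x (case, p0) mean AUCs."""
    return results.pivot_table(
        index="method", columns=["case", "p0"], values="auc", aggfunc="mean"
    )
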