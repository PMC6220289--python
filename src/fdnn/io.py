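"""Reading, writing and preprocessing expression matrices.

Canonical on-disk form is TSV with samples in rows: first column the
sample id, then one column per feature, last column the binary label.
Files with features in rows are accepted with a declared orientation.
Preprocessing utilities implement the usual per-gene Z-score transform
and the zero-fraction gene filter used for RNA-seq matrices.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import ExpressionDataset

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "zscore_features",
    "filter_zero_fraction",
]

LABEL_COLUMN = "label"
SAMPLE_COLUMN = "sample_id"


def read_expression_matrix(
    path,
    orientation: str = "samples-in-rows",
    label_column: str = LABEL_COLUMN,
    positive_class=None,
    labels=None,
) -> ExpressionDataset:
    """Load a delimited expression matrix into an ExpressionDataset.

    With ``features-in-rows`` the file is transposed after reading (its first
    column is then the feature name and its header the sample ids), and labels
    must be supplied via ``labels`` since a label row is not stored in that
    orientation here.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "features-in-rows":
        frame = frame.T
    elif orientation != "samples-in-rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    if label_column in frame.columns:
        y_raw = frame[label_column]
        frame = frame.drop(columns=[label_column])
    elif labels is not None:
        y_raw = pd.Series(labels, index=frame.index)
    else:
        raise ValueError(f"no label column {label_column!r} and no labels given")

    bad = frame.map(lambda v: not _is_number(v))
    if bad.any().any():
        r, c = np.argwhere(bad.values)[0]
        raise ValueError(
            f"non-numeric cell at row {frame.index[r]!r}, column {frame.columns[c]!r}"
        )
    X = frame.astype(float).values
    y = _encode_labels(y_raw, positive_class)
    return ExpressionDataset(
        X=X,
        y=y,
        feature_names=[str(c) for c in frame.columns],
        sample_ids=[str(i) for i in frame.index],
        provenance={"source": str(path), "orientation": orientation},
    )


def write_expression_matrix(dataset: ExpressionDataset, path, sidecar: dict | None = None):
    """Write the canonical TSV plus an optional YAML sidecar of parameters."""
    path = Path(path)
    frame = pd.DataFrame(dataset.X, columns=dataset.feature_names)
    frame.insert(0, SAMPLE_COLUMN, dataset.sample_ids)
    frame[LABEL_COLUMN] = dataset.y
    frame.to_csv(path, sep="\t", index=False)
    if sidecar is not None:
        sidecar_path = path.with_suffix(path.suffix + ".yaml")
        with open(sidecar_path, "w") as fh:
            yaml.safe_dump(_jsonable(sidecar), fh, sort_keys=False)


def zscore_features(dataset: ExpressionDataset) -> ExpressionDataset:
    """Center and scale every feature to mean 0, sd 1; drop constant features."""
    sd = dataset.X.std(axis=0, ddof=0)
    keep = sd > 0
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"dropping {dropped} zero-variance feature(s)", stacklevel=2)
    X = dataset.X[:, keep]
    X = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    return ExpressionDataset(
        X=X,
        y=dataset.y,
        feature_names=[n for n, k in zip(dataset.feature_names, keep) if k],
        sample_ids=list(dataset.sample_ids),
        provenance={**dataset.provenance, "zscored": True, "dropped_constant": dropped},
    )


def filter_zero_fraction(dataset: ExpressionDataset, max_zero_fraction: float = 0.1):
    """Remove features whose fraction of exact zeros strictly exceeds the threshold."""
    if not 0 <= max_zero_fraction <= 1:
        raise ValueError("max_zero_fraction must lie in [0, 1]")
    zero_frac = (dataset.X == 0).mean(axis=0)
    keep = zero_frac <= max_zero_fraction
    return ExpressionDataset(
        X=dataset.X[:, keep],
        y=dataset.y,
        feature_names=[n for n, k in zip(dataset.feature_names, keep) if k],
        sample_ids=list(dataset.sample_ids),
        provenance={
            **dataset.provenance,
            "zero_fraction_filter": max_zero_fraction,
            "features_removed": int((~keep).sum()),
        },
    )


def _encode_labels(y_raw: pd.Series, positive_class) -> np.ndarray:
    values = y_raw.values
    if positive_class is not None:
        return (values.astype(str) == str(positive_class)).astype(int)
    try:
        numeric = pd.to_numeric(y_raw)
    except (ValueError, TypeError):
        raise ValueError(
            "labels are not numeric; pass positive_class to map string labels"
        )
    uniq = set(np.unique(numeric).tolist())
    if not uniq <= {0, 1}:
        raise ValueError(f"labels must be 0/1 (or use positive_class), found {sorted(uniq)}")
    return numeric.astype(int).values


def _is_number(v) -> bool:
    try:
        float(v)
        return np.isfinite(float(v))
    except (TypeError, ValueError):
        return False


def _jsonable(obj):
    return json.loads(json.dumps(obj, default=str))
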