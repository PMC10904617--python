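"""Seeded k-fold model selection on mean absolute error."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = ["LabelledDataset", "kfold_best_model", "mean_absolute_error"]


@dataclass(frozen=True)
class LabelledDataset:
    """A feature matrix (or SMILES list) with numeric targets."""

    inputs: np.ndarray | Sequence
    targets: np.ndarray
    name: str = "dataset"

    def __post_init__(self) -> None:
        y = np.asarray(self.targets, dtype=float)
        if len(self.inputs) != len(y):
            raise ValueError("inputs and targets must have equal length")
        if np.any(~np.isfinite(y)):
            raise ValueError("targets must be finite (no missing values)")
        object.__setattr__(self, "targets", y)

    def __len__(self) -> int:
        return len(self.targets)


def mean_absolute_error(y_true, y_pred) -> float:
    return float(np.mean(np.abs(np.asarray(y_true) - np.asarray(y_pred))))


def _r_squared(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float)
    ss_res = np.sum((y_true - np.asarray(y_pred)) ** 2)
    ss_tot = np.sum((y_true - y_true.mean()) ** 2)
    return float(1.0 - ss_res / ss_tot) if ss_tot > 0 else float("nan")


def kfold_best_model(
    data: LabelledDataset,
    fit_fn: Callable,
    predict_fn: Callable,
    k: int = 10,
    metric: Callable = mean_absolute_error,
    seed: int = 0,
):
    """Cross-validate and keep the fold model with the smallest MAE.

    The data are shuffled once with the seed and split into k folds whose
    sizes differ by at most one; each fold in turn is the validation set
    for a model fitted on the remaining folds.  Returns ``(best_model,
    table)`` where the table lists the validation MAE and R-squared per
    fold; the best model is the one fitted on the fold split with the
    smallest validation MAE.
    """
    n = len(data)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available instances")
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    X = np.asarray(data.inputs)
    y = data.targets
    rows = []
    models = []
    for i, val_idx in enumerate(folds):
        train_idx = np.concatenate([f for j, f in enumerate(folds) if j != i])
        model = fit_fn(X[train_idx], y[train_idx])
        pred = predict_fn(model, X[val_idx])
        rows.append(
            {
                "fold": i,
                "mae": metric(y[val_idx], pred),
                "r_squared": _r_squared(y[val_idx], pred),
            }
        )
        models.append(model)
    table = pd.DataFrame(rows)
    best = int(table["mae"].idxmin())
    return models[best], table
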