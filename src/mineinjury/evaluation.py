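"""Evaluation: stratified 70/30 splitting, classification and regression metrics.

The confusion matrix follows the rows-are-actual, columns-are-predicted
convention. Per-class precision, recall and F1 use the zero-division
convention precision = recall = 0 when a denominator is zero; the overall
F1 is support-weighted. Regression quality is mean squared error and its
square root.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class EvalReport:
    classes: list[str]
    confusion: np.ndarray  # (k, k) ints; rows actual, columns predicted
    per_class: dict[str, dict[str, float]]  # precision, recall, f1, support
    weighted_f1: float
    accuracy: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "classes": self.classes,
                "confusion": self.confusion.tolist(),
                "per_class": self.per_class,
                "weighted_f1": self.weighted_f1,
                "accuracy": self.accuracy,
            },
            indent=2,
        )

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion, index=self.classes, columns=self.classes)


@dataclass
class RegressionReport:
    mse: float
    rmse: float
    n: int

    def to_json(self) -> str:
        return json.dumps({"mse": self.mse, "rmse": self.rmse, "n": self.n}, indent=2)


def stratified_split(
    df: pd.DataFrame,
    target_column: str,
    train_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split rows into train/test preserving per-class proportions.

    Per-class training counts use largest-remainder rounding so the overall
    training size is exactly round(train_fraction * n). Classes with fewer
    than two rows cannot be split and raise an error naming them.
    """
    y = df[target_column].astype(str)
    counts = y.value_counts().sort_index()
    singletons = [c for c, n in counts.items() if n < 2]
    if singletons:
        raise ValueError(f"classes with fewer than 2 rows cannot be split: {singletons}")
    total_train = int(round(train_fraction * len(df)))
    raw = counts.to_numpy() * train_fraction
    base = np.floor(raw).astype(int)
    remainder = total_train - base.sum()
    order = np.argsort(-(raw - base), kind="stable")
    take = base.copy()
    for i in order[: max(0, remainder)]:
        take[i] += 1
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    for cls, n_train in zip(counts.index, take):
        idx = df.index[y == cls].to_numpy()
        perm = rng.permutation(len(idx))
        train_idx.append(idx[perm[:n_train]])
    train_set = set(np.concatenate(train_idx).tolist())
    is_train = df.index.isin(train_set)
    return df.loc[is_train], df.loc[~is_train]


def classification_report(actual: Sequence, predicted: Sequence) -> EvalReport:
    a = np.asarray([str(v) for v in actual])
    p = np.asarray([str(v) for v in predicted])
    if len(a) != len(p):
        raise ValueError("actual and predicted must have equal length")
    classes = sorted(set(a.tolist()) | set(p.tolist()))
    cindex = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    conf = np.zeros((k, k), dtype=int)
    for av, pv in zip(a, p):
        conf[cindex[av], cindex[pv]] += 1
    per_class: dict[str, dict[str, float]] = {}
    f1s, supports = [], []
    for c in classes:
        i = cindex[c]
        tp = conf[i, i]
        fp = conf[:, i].sum() - tp
        fn = conf[i, :].sum() - tp
        prec = tp / (tp + fp) if tp + fp > 0 else 0.0
        rec = tp / (tp + fn) if tp + fn > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        support = int(conf[i, :].sum())
        per_class[c] = {
            "precision": float(prec),
            "recall": float(rec),
            "f1": float(f1),
            "support": support,
        }
        f1s.append(f1)
        supports.append(support)
    supports_arr = np.asarray(supports, float)
    weighted_f1 = float(np.average(f1s, weights=supports_arr)) if supports_arr.sum() else 0.0
    accuracy = float(np.trace(conf) / len(a))
    return EvalReport(classes, conf, per_class, weighted_f1, accuracy)


def regression_report(actual: Sequence[float], predicted: Sequence[float]) -> RegressionReport:
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if len(a) == 0:
        raise ValueError("cannot compute regression metrics on empty input")
    if len(a) != len(p):
        raise ValueError("actual and predicted must have equal length")
    mse = float(np.mean((a - p) ** 2))
    return RegressionReport(mse=mse, rmse=float(np.sqrt(mse)), n=len(a))
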