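"""Categorical encoding: target statistics with shrinkage, plus one-hot.

A high-cardinality categorical predictor X is replaced by derived numeric
columns holding smoothed estimates of P(Y = Y_j | X = X_i):

    S_i(Y_j) = lambda(n_i) * n_iY / n_i + (1 - lambda(n_i)) * n_Y / n_TR,
    lambda(n) = n / (n + m),

where n_i is the number of training rows with category X_i, n_iY of those
in class Y_j, n_Y the class count, n_TR the training-set size, and m > 0 a
smoothing constant. Rare categories are shrunk toward the class prior;
lambda(0) = 0, so unseen categories map to the prior exactly. Because the
k per-class probabilities sum to one, only k − 1 derived columns are kept
(one class's column is redundant and dropped).

The encoder is fitted on training rows only, so no information about
held-out targets leaks into the features.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd


def shrinkage(n: np.ndarray | float, m: float) -> np.ndarray | float:
    """lambda(n) = n / (n + m): weight on the empirical conditional."""
    return n / (n + m)


@dataclass
class TargetEncoderModel:
    """Fitted per-column, per-class smoothed probability tables."""

    m: float
    classes: list[str]
    priors: dict[str, float]
    tables: dict[str, dict[str, dict[str, float]]]
    n_tr: int
    category_counts: dict[str, dict[str, int]]
    dropped_class: str

    @property
    def kept_classes(self) -> list[str]:
        return [c for c in self.classes if c != self.dropped_class]

    def to_json(self) -> str:
        return json.dumps(
            {
                "m": self.m,
                "classes": self.classes,
                "priors": self.priors,
                "tables": self.tables,
                "n_tr": self.n_tr,
                "category_counts": self.category_counts,
                "dropped_class": self.dropped_class,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "TargetEncoderModel":
        return cls(**json.loads(text))


def fit_target_encoder(
    df: pd.DataFrame,
    categorical_columns: Sequence[str],
    target_column: str,
    m: float = 10.0,
    dropped_class: Optional[str] = None,
) -> TargetEncoderModel:
    """Fit smoothed class-probability tables from training rows only."""
    if df.empty:
        raise ValueError("cannot fit a target encoder on an empty training set")
    if m <= 0:
        raise ValueError(f"smoothing constant m must be > 0, got {m}")
    y = df[target_column].astype(str)
    classes = sorted(y.unique())
    if len(classes) == 1:
        warnings.warn(
            f"target column {target_column!r} is constant; "
            "encoded probabilities degenerate to all ones for that class"
        )
    n_tr = len(df)
    priors = {c: float((y == c).sum()) / n_tr for c in classes}
    if dropped_class is None:
        dropped_class = classes[-1]
    elif dropped_class not in classes:
        raise ValueError(f"dropped_class {dropped_class!r} not among target classes")

    tables: dict[str, dict[str, dict[str, float]]] = {}
    counts: dict[str, dict[str, int]] = {}
    for col in categorical_columns:
        x = df[col].astype(str)
        tab: dict[str, dict[str, float]] = {}
        cnt: dict[str, int] = {}
        grouped = pd.crosstab(x, y)  # rows: categories, cols: classes present
        n_i = grouped.sum(axis=1)
        for cat in grouped.index:
            ni = int(n_i.loc[cat])
            lam = shrinkage(ni, m)
            row: dict[str, float] = {}
            for c in classes:
                niy = int(grouped.loc[cat, c]) if c in grouped.columns else 0
                row[c] = float(lam * (niy / ni) + (1.0 - lam) * priors[c])
            tab[cat] = row
            cnt[cat] = ni
        tables[col] = tab
        counts[col] = cnt
    return TargetEncoderModel(
        m=float(m),
        classes=classes,
        priors=priors,
        tables=tables,
        n_tr=n_tr,
        category_counts=counts,
        dropped_class=dropped_class,
    )


def transform(model: TargetEncoderModel, df: pd.DataFrame) -> pd.DataFrame:
    """Replace each fitted categorical column by its k − 1 derived columns.

    Categories never seen during fitting receive the class prior (the
    lambda(0) = 0 limit of the shrinkage formula). All other columns pass
    through unchanged.
    """
    out = df.copy()
    kept = model.kept_classes
    for col, tab in model.tables.items():
        values = out[col].astype(str)
        derived = {c: np.empty(len(out), float) for c in kept}
        for i, v in enumerate(values):
            row = tab.get(v)
            for c in kept:
                derived[c][i] = row[c] if row is not None else model.priors[c]
        idx = out.columns.get_loc(col)
        out = out.drop(columns=[col])
        for offset, c in enumerate(kept):
            out.insert(idx + offset, f"{col}__{c}", derived[c])
    return out


def one_hot_encode(df: pd.DataFrame, column: str) -> pd.DataFrame:
    """One binary indicator column per category of ``column``."""
    values = df[column].astype(str)
    cats = sorted(values.unique())
    out = pd.DataFrame(
        {f"{column}__{c}": (values == c).astype(int).to_numpy() for c in cats},
        index=df.index,
    )
    return out
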