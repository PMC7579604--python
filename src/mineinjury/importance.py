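"""Leave-one-feature-out importance by full retraining.

The classifier is trained on the complete feature table, then once more
per original variable with that variable removed; the importance of a
feature is the drop in held-out weighted F1 (baseline minus ablated; it
may be negative). A target-encoded categorical variable contributes k − 1
derived columns, and all of them are removed together — the unit of
ablation is the original variable, not a derived column. Every retrain
reuses the identical train/test partition and model seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import classification_report, stratified_split
from .modeling import ModelSpec, train


@dataclass
class ImportanceTable:
    """Features ordered by decreasing delta in held-out weighted F1."""

    entries: list[tuple[str, float]]
    baseline_f1: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "baseline_f1": self.baseline_f1,
                "entries": [{"feature": f, "delta_f1": d} for f, d in self.entries],
            },
            indent=2,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["feature", "delta_f1"])


def group_columns(feature_names: Sequence[str], columns: Sequence[str]) -> dict[str, list[str]]:
    """Map each original variable to its derived columns.

    Derived columns are named ``<variable>__<class>`` by the target
    encoder; plain numeric variables appear under their own name.
    """
    groups: dict[str, list[str]] = {name: [] for name in feature_names}
    for col in columns:
        base = col.split("__", 1)[0]
        if base in groups:
            groups[base].append(col)
    missing = [name for name, cols in groups.items() if not cols]
    if missing:
        raise ValueError(f"unknown feature name(s): {missing}")
    return groups


def loo_importance(
    spec: ModelSpec,
    features: pd.DataFrame,
    targets: Sequence,
    feature_names: Sequence[str],
    split_seed: int = 0,
    train_fraction: float = 0.7,
) -> ImportanceTable:
    """Retrain once per variable and measure the held-out weighted-F1 drop."""
    if spec.task != "classification":
        raise ValueError("leave-one-feature-out importance is defined for classification")
    if len(feature_names) < 2:
        raise ValueError("need at least two features to ablate")
    groups = group_columns(feature_names, features.columns)

    frame = features.copy()
    frame["__target__"] = np.asarray(targets)
    train_df, test_df = stratified_split(frame, "__target__", train_fraction, seed=split_seed)
    train_df, test_df = train_df.copy(), test_df.copy()
    y_train = train_df.pop("__target__")
    y_test = test_df.pop("__target__")

    def fit_f1(cols: list[str]) -> float:
        model = train(spec, train_df[cols], y_train)
        pred = model.predict(test_df[cols])
        return classification_report(y_test, pred).weighted_f1

    all_cols = [c for c in features.columns]
    baseline = fit_f1(all_cols)
    entries = []
    for name in feature_names:
        drop = set(groups[name])
        kept = [c for c in all_cols if c not in drop]
        entries.append((name, baseline - fit_f1(kept)))
    entries.sort(key=lambda e: (-e[1], e[0]))
    return ImportanceTable(entries=entries, baseline_f1=baseline)
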