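"""Record filtering, narrative normalization and time-feature engineering.

Cleaning drops rows with any empty retained field and rows describing
non-employee injuries. Narratives are lowercased, punctuation-stripped,
stop-word-filtered and Porter-stemmed. The two clock-time variables are
combined into an hours-into-shift feature (with midnight wrap-around) that
is kept *alongside* the raw times, which remain predictors in their own
right.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .records import (
    CATEGORICAL_FIELDS,
    CLASS_FIELD,
    DAYS_FIELD,
    NARRATIVE_FIELD,
    NONEMPLOYEE_LABEL,
    NUMERIC_FIELDS,
)
from .text import STOPWORDS, stem, tokenize

#: fields that must be non-empty for a row to survive cleaning
REQUIRED_FIELDS: tuple[str, ...] = (
    CATEGORICAL_FIELDS + NUMERIC_FIELDS + (NARRATIVE_FIELD, CLASS_FIELD)
)

TASKS = ("outcome_fixed_field", "outcome_narrative", "dafw")

HOURS_FIELD = "hours"


@dataclass
class CleanDataset:
    """A filtered dataset plus an itemized account of what was dropped."""

    records: pd.DataFrame
    dropped_counts: dict[str, int] = field(default_factory=dict)

    def report_json(self) -> str:
        return json.dumps(
            {
                "rows_retained": int(len(self.records)),
                "dropped_counts": {k: int(v) for k, v in self.dropped_counts.items()},
            },
            indent=2,
        )


def clean_records(df: pd.DataFrame) -> CleanDataset:
    """Drop rows with empty retained fields or the non-employee outcome.

    ``days_away`` is an outcome, not a retained predictor: its missingness
    is handled by :func:`select_task_rows` for the DAFW task, never here.
    """
    if df.empty:
        return CleanDataset(df.copy(), {})
    present = [c for c in REQUIRED_FIELDS if c in df.columns]
    is_empty = df[present].isna()
    for c in present:
        if df[c].dtype == object:
            is_empty[c] = is_empty[c] | (df[c].astype(str).str.strip() == "")
    missing_mask = is_empty.any(axis=1)
    nonemp_mask = (df[CLASS_FIELD] == NONEMPLOYEE_LABEL) & ~missing_mask
    keep = ~missing_mask & ~nonemp_mask
    dropped: dict[str, int] = {}
    if int(missing_mask.sum()):
        dropped["missing_field"] = int(missing_mask.sum())
    if int(nonemp_mask.sum()):
        dropped["nonemployee"] = int(nonemp_mask.sum())
    return CleanDataset(df.loc[keep].reset_index(drop=True), dropped)


def normalize_narrative(text: str, stopword_list: Optional[Iterable[str]] = None) -> list[str]:
    """Lowercase, strip punctuation, drop stop words, Porter-stem each token."""
    stops = STOPWORDS if stopword_list is None else frozenset(stopword_list)
    return [stem(t) for t in tokenize(text) if t not in stops]


def engineer_time_features(df: pd.DataFrame) -> pd.DataFrame:
    """Add hours-into-shift: ((accident − shift start) mod 1440) / 60.

    Overnight shifts wrap through midnight, so the difference is taken
    modulo one day; the result lies in [0, 24). Raw times are retained.
    """
    for c in ("accident_time", "shift_start_time"):
        vals = df[c].to_numpy(float)
        if ((vals < 0) | (vals >= 1440)).any():
            raise ValueError(f"{c} out of range [0, 1440)")
    out = df.copy()
    out[HOURS_FIELD] = (
        (df["accident_time"].to_numpy(float) - df["shift_start_time"].to_numpy(float)) % 1440
    ) / 60.0
    return out


def hours_between(accident_time: float, shift_start_time: float) -> float:
    """Scalar form of the hours-into-shift feature."""
    for name, t in (("accident_time", accident_time), ("shift_start_time", shift_start_time)):
        if not (0 <= t < 1440):
            raise ValueError(f"{name} out of range [0, 1440)")
    return ((accident_time - shift_start_time) % 1440) / 60.0


def select_task_rows(
    df: pd.DataFrame,
    task: str,
    min_class_fraction: float = 0.01,
    keep_classes: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Restrict a cleaned dataset to the rows one modelling task uses.

    ``outcome_fixed_field`` drops classes holding less than
    ``min_class_fraction`` of the rows (computed on the full dataset before
    any split); ``keep_classes`` overrides the rule with an explicit class
    list. ``outcome_narrative`` keeps all classes. ``dafw`` keeps rows with
    a positive, non-missing days-away-from-work count.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {TASKS}")
    if task == "outcome_narrative":
        return df.copy()
    if task == "dafw":
        days = df[DAYS_FIELD]
        return df.loc[days.notna() & (days > 0)].reset_index(drop=True)
    # outcome_fixed_field
    if keep_classes is not None:
        keep = set(keep_classes)
    else:
        frac = df[CLASS_FIELD].value_counts(normalize=True)
        keep = set(frac.index[frac >= min_class_fraction])
    return df.loc[df[CLASS_FIELD].isin(keep)].reset_index(drop=True)
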