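"""Record schema for mining accident-injury data and its CSV dialect.

A dataset is a :class:`pandas.DataFrame` with one row per accident. The
fifteen retained explanatory variables are eight high-cardinality
categorical fields, a coal/metal flag, two clock times, three experience
variables and a free-text narrative; the two outcomes are the degree of
injury (a nine-class label) and days away from work (DAFW, a non-negative
integer count that may be missing).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Optional, Sequence

import numpy as np
import pandas as pd

CATEGORICAL_FIELDS: tuple[str, ...] = (
    "subunit",
    "classification",
    "accident_type",
    "occupation",
    "activity",
    "injury_source",
    "nature_of_injury",
    "injured_body_part",
)

#: numeric explanatory variables; coal_metal is 0 = coal, 1 = metal
NUMERIC_FIELDS: tuple[str, ...] = (
    "coal_metal",
    "accident_time",
    "shift_start_time",
    "total_experience",
    "mine_experience",
    "job_experience",
)

NARRATIVE_FIELD = "narrative"
CLASS_FIELD = "degree_of_injury"
DAYS_FIELD = "days_away"

#: explanatory fields + narrative, i.e. everything a model may see
PREDICTOR_FIELDS: tuple[str, ...] = CATEGORICAL_FIELDS + NUMERIC_FIELDS + (NARRATIVE_FIELD,)

ALL_COLUMNS: tuple[str, ...] = PREDICTOR_FIELDS + (CLASS_FIELD, DAYS_FIELD)

#: the nine degree-of-injury classes, in their conventional order
CLASS_LABELS: tuple[str, ...] = (
    "All Other Cases (Including 1st Aid)",
    "Days Away From Work Only",
    "Days Restricted Activity Only",
    "Days Away From Work & Restricted Activity",
    "Fatality",
    "Injuries due to Natural Causes",
    "No Days Away From Work, No Restricted Activity",
    "Occupational Illness not DEG 1-6",
    "Permanent Total or Permanent Partial Disability",
)

#: rows with this outcome describe non-employees and are dropped on cleaning
NONEMPLOYEE_LABEL = "Injuries involving non-employees"

#: classes whose records carry lost workdays (positive DAFW)
LOST_TIME_CLASSES: frozenset[str] = frozenset(
    {
        "Days Away From Work Only",
        "Days Away From Work & Restricted Activity",
        "Permanent Total or Permanent Partial Disability",
    }
)


@dataclass
class InjuryRecord:
    """A single accident record; mirrors one row of the tabular dataset."""

    subunit: str
    classification: str
    accident_type: str
    occupation: str
    activity: str
    injury_source: str
    nature_of_injury: str
    injured_body_part: str
    coal_metal: int
    accident_time: float
    shift_start_time: float
    total_experience: float
    mine_experience: float
    job_experience: float
    narrative: str
    degree_of_injury: str
    days_away: Optional[int] = None

    def validate(self) -> None:
        if self.coal_metal not in (0, 1):
            raise ValueError(f"coal_metal must be 0 (coal) or 1 (metal), got {self.coal_metal}")
        for name in ("accident_time", "shift_start_time"):
            t = getattr(self, name)
            if not (0 <= t < 1440):
                raise ValueError(f"{name} must lie in [0, 1440) minutes, got {t}")
        for name in ("total_experience", "mine_experience", "job_experience"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.days_away is not None and not (
            isinstance(self.days_away, float) and np.isnan(self.days_away)
        ):
            if self.days_away < 0:
                raise ValueError("days_away must be non-negative")


def records_to_frame(records: Sequence[InjuryRecord]) -> pd.DataFrame:
    """Stack records into the canonical DataFrame layout."""
    names = [f.name for f in dc_fields(InjuryRecord)]
    df = pd.DataFrame([{n: getattr(r, n) for n in names} for r in records], columns=names)
    return _coerce_dtypes(df)


def frame_to_records(df: pd.DataFrame) -> list[InjuryRecord]:
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        days = d.get(DAYS_FIELD)
        if days is not None and pd.isna(days):
            d[DAYS_FIELD] = None
        elif days is not None:
            d[DAYS_FIELD] = int(days)
        out.append(InjuryRecord(**d))
    return out


def _coerce_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    if DAYS_FIELD in df.columns:
        df[DAYS_FIELD] = df[DAYS_FIELD].astype("Int64")
    if "coal_metal" in df.columns:
        df["coal_metal"] = df["coal_metal"].astype("int64")
    return df


def write_records_csv(df: pd.DataFrame, path) -> None:
    """Write the dataset: one header row, narratives quoted, missing DAFW empty."""
    import csv

    df.to_csv(path, index=False, quoting=csv.QUOTE_MINIMAL, lineterminator="\n")


def read_records_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    # empty categorical / narrative cells come back as NaN; keep them NaN so
    # the cleaning stage can count them, but restore dtypes for the rest
    return _coerce_dtypes(df)
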