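"""Synthetic MSHA-like accident dataset generator.

Emulates the structure a mining accident-injuries extract: a nine-class
degree-of-injury outcome with strong imbalance (default proportions follow
the observed class mix of the real data), eight high-cardinality
categorical predictors, short free-text narratives whose vocabulary can
carry class signal, and a non-negative right-skewed days-away-from-work
(DAFW) outcome with multiplicative feature effects and log-normal noise.

Narratives are built from a fixed ~200-token background vocabulary plus
ten-token signal vocabularies unique to each outcome class (disjoint from
each other and from the background), so class-conditional embedding
neighbourhoods are learnable by construction. All vocabulary tokens are
chosen to be stop-word-free and Porter-stable, so narrative normalization
preserves them.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .records import (
    CATEGORICAL_FIELDS,
    CLASS_FIELD,
    CLASS_LABELS,
    DAYS_FIELD,
    LOST_TIME_CLASSES,
    NARRATIVE_FIELD,
    NONEMPLOYEE_LABEL,
    _coerce_dtypes,
)
from .text import STOPWORDS, stem

# ---------------------------------------------------------------------------
# class mix: observed per-class record counts of the source data, normalized
# ---------------------------------------------------------------------------

CLASS_COUNTS: dict[str, int] = {
    "All Other Cases (Including 1st Aid)": 676,
    "Days Away From Work Only": 31653,
    "Days Restricted Activity Only": 16633,
    "Days Away From Work & Restricted Activity": 10025,
    "Fatality": 336,
    "Injuries due to Natural Causes": 444,
    "No Days Away From Work, No Restricted Activity": 27627,
    "Occupational Illness not DEG 1-6": 1346,
    "Permanent Total or Permanent Partial Disability": 895,
}

_TOTAL = sum(CLASS_COUNTS.values())

DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    k: v / _TOTAL for k, v in CLASS_COUNTS.items()
}

#: cardinalities of the categorical predictors in the real data
DEFAULT_CARDINALITIES: dict[str, int] = {
    "subunit": 5,
    "classification": 28,
    "accident_type": 43,
    "occupation": 198,
    "activity": 98,
    "injury_source": 127,
    "nature_of_injury": 38,
    "injured_body_part": 47,
}

# ---------------------------------------------------------------------------
# vocabulary construction (deterministic, module-level)
# ---------------------------------------------------------------------------

_ONSETS = "b bl br c cl cr d dr f fl fr g gr h j k l m n p pl pr r s sc sk sl sm sn sp st str t tr v w".split()
_NUCLEI = "a e i o u ar er ir or ur".split()
_CODAS = "b ck d ft g k l lk lt m mp n nd nk nt p rk rm rn rt sk st t x".split()


def _make_words(rng: np.random.Generator, n: int, taken: set[str]) -> list[str]:
    """Generate pseudo-words that are stop-word-free and Porter-stable."""
    out: list[str] = []
    while len(out) < n:
        parts = []
        for _ in range(int(rng.integers(1, 3))):
            parts.append(str(rng.choice(_ONSETS)) + str(rng.choice(_NUCLEI)))
        word = "".join(parts) + str(rng.choice(_CODAS))
        if word in taken or word in STOPWORDS or stem(word) != word or len(word) < 3:
            continue
        taken.add(word)
        out.append(word)
    return out


def _build_vocabularies() -> tuple[list[str], dict[str, list[str]]]:
    rng = np.random.default_rng(20200927)
    taken: set[str] = set()
    background = _make_words(rng, 200, taken)
    signal = {label: _make_words(rng, 10, taken) for label in CLASS_LABELS}
    return background, signal


BACKGROUND_VOCAB, SIGNAL_VOCAB = _build_vocabularies()


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def default_dafw_effect_map(
    cardinalities: Optional[Mapping[str, int]] = None,
) -> dict[str, float]:
    """Multiplicative DAFW effects: a geometric 0.5x..2x ladder over the levels
    of nature-of-injury, injured body part, and occupation."""
    cards = dict(DEFAULT_CARDINALITIES)
    if cardinalities:
        cards.update(cardinalities)
    out: dict[str, float] = {}
    for fld in ("nature_of_injury", "injured_body_part", "occupation"):
        k = cards[fld]
        for i in range(k):
            frac = i / (k - 1) if k > 1 else 0.0
            out[f"{fld}_{i:03d}"] = math.exp(math.log(0.5) + frac * (math.log(2.0) - math.log(0.5)))
    return out


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Parameters
    ----------
    n_records : number of accident records to draw.
    class_proportions : outcome-class mix; defaults to the observed
        nine-class imbalance of the real data.
    cardinalities : number of levels per categorical field.
    narrative_signal_q : probability that a record's narrative contains
        1-3 tokens from its class's private signal vocabulary.
    narrative_length_range : (min, max) token count of a narrative.
    dafw_effect_map : category label -> multiplicative effect on the
        median DAFW of lost-time records.
    noise_sd : sigma of the log-normal DAFW noise (log scale).
    fixed_field_signal : per-categorical-field probability that the level
        is drawn from a narrow class-specific band instead of uniformly;
        empty means the fixed fields carry no outcome signal.
    late_shift_fraction : fraction of accidents occurring >= 8 h into the
        shift, so the derived hours feature has spread.
    dafw_hours_coef, dafw_job_exp_coef : log-scale linear effects of hours
        into shift and job experience (years) on median DAFW.
    missing_field_rate : per-record probability of blanking one predictor.
    dafw_missing_rate : probability a lost-time record's DAFW is missing.
    nonemployee_rate : probability a record is relabelled as the
        non-employee outcome (removed later by cleaning).
    """

    n_records: int
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    cardinalities: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CARDINALITIES))
    narrative_signal_q: float = 0.9
    narrative_length_range: tuple[int, int] = (8, 20)
    dafw_effect_map: Optional[dict[str, float]] = None
    noise_sd: float = 1.0
    seed: int = 0
    fixed_field_signal: dict[str, float] = field(default_factory=dict)
    late_shift_fraction: float = 0.2
    dafw_hours_coef: float = 0.06
    dafw_job_exp_coef: float = -0.02
    dafw_base_median: float = 6.0
    missing_field_rate: float = 0.01
    dafw_missing_rate: float = 0.02
    nonemployee_rate: float = 0.005

    def __post_init__(self) -> None:
        if self.n_records <= 0:
            raise ValueError("n_records must be positive")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"class_proportions must sum to 1 (got {total!r}); normalize them first"
            )
        lo, hi = self.narrative_length_range
        if lo < 1 or hi < lo:
            raise ValueError("narrative_length_range must satisfy 1 <= min <= max")
        if not (0.0 <= self.narrative_signal_q <= 1.0):
            raise ValueError("narrative_signal_q must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for fld, k in self.cardinalities.items():
            if k < 2:
                raise ValueError(f"cardinality of {fld} must be >= 2")
        if self.dafw_effect_map is None:
            self.dafw_effect_map = default_dafw_effect_map(self.cardinalities)

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        """Load a config from YAML or JSON."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) if str(path).endswith((".yml", ".yaml")) else json.load(fh)
        if "narrative_length_range" in raw:
            raw["narrative_length_range"] = tuple(raw["narrative_length_range"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_SHIFT_STARTS = np.arange(0, 1440, 30)

# Zipf-like background token weights: frequent "workhorse" words plus a tail,
# giving TF-IDF a realistic document-frequency spread.
_BG_WEIGHTS = 1.0 / (np.arange(len(BACKGROUND_VOCAB)) + 2.0)
_BG_WEIGHTS /= _BG_WEIGHTS.sum()


def _draw_categorical(
    rng: np.random.Generator,
    fld: str,
    k: int,
    class_idx: np.ndarray,
    n_classes: int,
    signal_strength: float,
) -> list[str]:
    levels = rng.integers(0, k, size=len(class_idx))
    if signal_strength > 0:
        use_sig = rng.random(len(class_idx)) < signal_strength
        band = max(1, k // (2 * n_classes))
        base = (class_idx * k) // n_classes
        sig_levels = (base + rng.integers(0, band, size=len(class_idx))) % k
        levels = np.where(use_sig, sig_levels, levels)
    return [f"{fld}_{v:03d}" for v in levels]


def generate_dataset(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a complete synthetic accident dataset as a DataFrame.

    Identical config (including seed) yields an identical frame.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_records

    class_names = list(config.class_proportions)
    probs = np.array([config.class_proportions[c] for c in class_names], float)
    class_idx = rng.choice(len(class_names), size=n, p=probs)
    degree = np.array(class_names, object)[class_idx]

    nonemp = rng.random(n) < config.nonemployee_rate
    degree = np.where(nonemp, NONEMPLOYEE_LABEL, degree)

    data: dict[str, object] = {}
    for fld in CATEGORICAL_FIELDS:
        k = config.cardinalities[fld]
        data[fld] = _draw_categorical(
            rng, fld, k, class_idx, len(class_names),
            config.fixed_field_signal.get(fld, 0.0),
        )

    data["coal_metal"] = rng.integers(0, 2, size=n)
    shift_start = rng.choice(_SHIFT_STARTS, size=n).astype(float)
    late = rng.random(n) < config.late_shift_fraction
    hours = np.where(late, rng.uniform(8.0, 12.0, n), rng.uniform(0.0, 8.0, n))
    accident_time = np.round(shift_start + hours * 60.0) % 1440
    data["shift_start_time"] = shift_start
    data["accident_time"] = accident_time

    total_exp = np.round(np.minimum(rng.exponential(8.0, n), 45.0), 2)
    mine_exp = np.round(total_exp * rng.random(n), 2)
    job_exp = np.round(mine_exp * rng.random(n), 2)
    data["total_experience"] = total_exp
    data["mine_experience"] = mine_exp
    data["job_experience"] = job_exp

    # narratives
    lengths = rng.integers(
        config.narrative_length_range[0], config.narrative_length_range[1] + 1, size=n
    )
    has_signal = (rng.random(n) < config.narrative_signal_q) & ~nonemp
    narratives = []
    bg = np.array(BACKGROUND_VOCAB, object)
    for i in range(n):
        toks = list(rng.choice(bg, size=lengths[i], p=_BG_WEIGHTS))
        if has_signal[i]:
            n_sig = min(int(rng.integers(1, 4)), lengths[i])
            positions = rng.choice(lengths[i], size=n_sig, replace=False)
            sig_vocab = SIGNAL_VOCAB[class_names[class_idx[i]]]
            for p in positions:
                toks[p] = sig_vocab[int(rng.integers(0, len(sig_vocab)))]
        narratives.append(" ".join(toks))
    data[NARRATIVE_FIELD] = narratives

    # DAFW: lost-time classes get log-normal days with multiplicative effects
    effect = np.ones(n)
    for fld in ("nature_of_injury", "injured_body_part", "occupation"):
        effect *= np.array([config.dafw_effect_map.get(v, 1.0) for v in data[fld]])
    log_median = (
        np.log(config.dafw_base_median)
        + np.log(effect)
        + config.dafw_hours_coef * hours
        + config.dafw_job_exp_coef * job_exp
    )
    days = np.round(np.exp(log_median + config.noise_sd * rng.standard_normal(n)))
    lost_time = np.isin(degree, list(LOST_TIME_CLASSES))
    days = np.where(lost_time, np.maximum(days, 0.0), 0.0)
    days = days.astype(float)
    dafw_missing = (rng.random(n) < config.dafw_missing_rate) & lost_time
    days[dafw_missing] = np.nan

    df = pd.DataFrame(data)
    df[CLASS_FIELD] = degree
    df[DAYS_FIELD] = days

    # blank one predictor field in a small fraction of rows
    if config.missing_field_rate > 0:
        blank_rows = np.nonzero(rng.random(n) < config.missing_field_rate)[0]
        blankable = list(CATEGORICAL_FIELDS) + [NARRATIVE_FIELD]
        for i in blank_rows:
            fld = blankable[int(rng.integers(0, len(blankable)))]
            df.loc[i, fld] = np.nan

    order = list(CATEGORICAL_FIELDS) + [
        "coal_metal", "accident_time", "shift_start_time",
        "total_experience", "mine_experience", "job_experience",
        NARRATIVE_FIELD, CLASS_FIELD, DAYS_FIELD,
    ]
    return _coerce_dtypes(df[order])
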