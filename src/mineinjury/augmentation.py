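"""Class-conditional synthetic narrative augmentation.

One word2vec model is trained per outcome class, on that class's training
narratives only. For a narrative of a minority class, a fixed number of
token positions (default 6) is chosen at random; each chosen position is
replaced, one variant at a time, by each of the top-k (default 3) cosine
nearest neighbours of the original token in the class's own embedding.
An eligible narrative therefore yields exactly n_words x top_k variants
(18 by default), each identical to the original except at one position.
Narratives shorter than n_words tokens are passed through untouched.

Augmentation applies to training rows only; held-out rows must never be
rewritten or duplicated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .narrative_vectors import EmbeddingModel, EmbeddingParams, nearest_neighbors, train_embedding
from .records import CLASS_FIELD, NARRATIVE_FIELD

#: classes left untouched by augmentation: the well-represented ones
DEFAULT_UNAUGMENTED_CLASSES: frozenset[str] = frozenset(
    {
        "Days Away From Work Only",
        "Days Restricted Activity Only",
        "Days Away From Work & Restricted Activity",
        "No Days Away From Work, No Restricted Activity",
    }
)

PROVENANCE_FIELD = "provenance"
SPLIT_FIELD = "split"


@dataclass
class AugmentationPlan:
    """What to augment and with which per-class embeddings."""

    per_class_models: dict[str, EmbeddingModel]
    classes_to_augment: set[str]
    n_words: int = 6
    top_k: int = 3
    seed: int = 0
    max_new_per_class: Optional[int] = None  # optional cap on synthetic rows

    def __post_init__(self) -> None:
        if self.n_words < 1 or self.top_k < 1:
            raise ValueError("n_words and top_k must be >= 1")


def fit_class_models(
    df: pd.DataFrame,
    params: EmbeddingParams = EmbeddingParams(),
    narratives: Optional[Mapping[int, Sequence[str]]] = None,
) -> dict[str, EmbeddingModel]:
    """Train one embedding per outcome class on that class's narratives only.

    ``narratives`` optionally maps row position -> normalized token list;
    by default the raw narrative strings are whitespace-split.
    """
    models: dict[str, EmbeddingModel] = {}
    for label, group in df.groupby(CLASS_FIELD, sort=True):
        if narratives is None:
            corpus = [str(t).split() for t in group[NARRATIVE_FIELD]]
        else:
            corpus = [list(narratives[i]) for i in group.index]
        corpus = [c for c in corpus if c]
        if not corpus:
            raise ValueError(f"class {label!r} has no narratives to train on")
        models[str(label)] = train_embedding(corpus, params)
    return models


def augment_narrative(
    tokens: Sequence[str],
    class_model: EmbeddingModel,
    n_words: int = 6,
    top_k: int = 3,
    seed: int = 0,
) -> list[list[str]]:
    """Generate single-substitution variants of one narrative.

    Chooses ``n_words`` distinct in-vocabulary positions at random (all of
    them if fewer are eligible) and substitutes each, in turn, by each of
    its ``top_k`` nearest neighbours in the class embedding. Narratives
    shorter than ``n_words`` tokens yield no variants.
    """
    tokens = list(tokens)
    if len(tokens) < n_words:
        return []
    rng = np.random.default_rng(seed)
    eligible = [i for i, t in enumerate(tokens) if t in class_model]
    if len(eligible) > n_words:
        chosen = sorted(rng.choice(len(eligible), size=n_words, replace=False))
        positions = [eligible[i] for i in chosen]
    else:
        positions = eligible
    variants: list[list[str]] = []
    for pos in positions:
        for neighbour in nearest_neighbors(class_model, tokens[pos], top_k):
            variant = tokens.copy()
            variant[pos] = neighbour
            variants.append(variant)
    return variants


def augment_training_set(df: pd.DataFrame, plan: AugmentationPlan) -> pd.DataFrame:
    """Append synthetic narratives for the minority classes of a training set.

    Input rows are returned unchanged (with provenance "original"); each
    synthetic row carries provenance "synthetic:<source row id>" and the
    label of its source narrative. Raises if any row is tagged as test.
    """
    if SPLIT_FIELD in df.columns and (df[SPLIT_FIELD] == "test").any():
        raise ValueError("augmentation received held-out rows; test data must stay untouched")
    unknown = plan.classes_to_augment - set(plan.per_class_models)
    if unknown:
        raise ValueError(f"no embedding model for classes {sorted(unknown)}")

    out = df.copy()
    if PROVENANCE_FIELD not in out.columns:
        out[PROVENANCE_FIELD] = "original"
    synthetic_frames: list[pd.DataFrame] = []
    rng = np.random.default_rng(plan.seed)
    for label in sorted(plan.classes_to_augment):
        model = plan.per_class_models[label]
        rows = out.index[out[CLASS_FIELD] == label]
        new_rows: list[dict] = []
        for rid in rows:
            tokens = str(out.loc[rid, NARRATIVE_FIELD]).split()
            for variant in augment_narrative(
                tokens, model, plan.n_words, plan.top_k, seed=int(rng.integers(2**31))
            ):
                base = out.loc[rid].to_dict()
                base[NARRATIVE_FIELD] = " ".join(variant)
                base[PROVENANCE_FIELD] = f"synthetic:{rid}"
                new_rows.append(base)
                if plan.max_new_per_class is not None and len(new_rows) >= plan.max_new_per_class:
                    break
            if plan.max_new_per_class is not None and len(new_rows) >= plan.max_new_per_class:
                break
        if new_rows:
            synthetic_frames.append(pd.DataFrame(new_rows))
    if synthetic_frames:
        out = pd.concat([out, *synthetic_frames], ignore_index=True)
    return out


def class_counts(df: pd.DataFrame) -> dict[str, int]:
    """Per-class row counts (an after-augmentation report helper)."""
    return {str(k): int(v) for k, v in df[CLASS_FIELD].value_counts().sort_index().items()}
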