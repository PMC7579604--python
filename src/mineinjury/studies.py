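"""Canned study designs for the package's headline comparisons.

Each function runs one self-contained simulation study at a given seed and
returns the measured quantities. The designs are fixed study conditions:

* ``outcome_comparison`` — three outcome classes, class signal planted
  only in the narratives (q = 0.9), fixed fields uninformative: compares
  the narrative-trained random forest against all four fixed-field models
  on weighted F1.
* ``dafw_comparison`` — three lost-time classes, DAFW driven purely by
  fixed-field features (hours into shift and job experience; category
  effects flat), narratives uninformative about DAFW: compares
  fixed-field and narrative regressors on RMSE.
* ``augmentation_benefit`` — a 5% minority class among three; measures
  the minority-class F1 of the narrative ANN with and without
  class-conditional augmentation of the training narratives.
* ``importance_study`` — fixed-field classification where one categorical
  (nature of injury) is made dominant while the rest stay null; returns
  the leave-one-feature-out table of the ANN.

Embedding dimension and epochs are reduced here (50 components, 5 epochs)
relative to the 300-component default of narrative vectorization: the
comparisons concern relative model performance, not embedding capacity,
and the smaller setting keeps each multi-seed study to desk scale.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np
import pandas as pd

from .augmentation import AugmentationPlan, augment_training_set, fit_class_models
from .encoding import fit_target_encoder, transform
from .evaluation import classification_report, regression_report, stratified_split
from .importance import ImportanceTable, loo_importance
from .modeling import ModelSpec, train
from .narrative_vectors import EmbeddingParams, compute_tfidf, train_embedding, vectorize_corpus
from .preprocessing import HOURS_FIELD, engineer_time_features, normalize_narrative
from .records import CATEGORICAL_FIELDS, CLASS_FIELD, CLASS_LABELS, DAYS_FIELD, NARRATIVE_FIELD
from .synthetic import GeneratorConfig, generate_dataset

STUDY_EMBEDDING = EmbeddingParams(dimension=50, window=5, epochs=5, min_count=1)

FIXED_FIELD_COLUMNS = list(CATEGORICAL_FIELDS) + [
    "coal_metal",
    "accident_time",
    "shift_start_time",
    HOURS_FIELD,
    "total_experience",
    "mine_experience",
    "job_experience",
]

_THREE_CLASSES = {CLASS_LABELS[1]: 0.5, CLASS_LABELS[6]: 0.3, CLASS_LABELS[2]: 0.2}
_LOST_TIME_THREE = {CLASS_LABELS[1]: 0.5, CLASS_LABELS[3]: 0.3, CLASS_LABELS[8]: 0.2}


def _prepared(config: GeneratorConfig) -> pd.DataFrame:
    return engineer_time_features(generate_dataset(config))


def _split(df: pd.DataFrame, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    tr, te = stratified_split(df, CLASS_FIELD, 0.7, seed=seed)
    return tr.copy(), te.copy()


def _narrative_matrices(train_df, test_df, params: EmbeddingParams, seed: int):
    train_tokens = [normalize_narrative(t) for t in train_df[NARRATIVE_FIELD]]
    test_tokens = [normalize_narrative(t) for t in test_df[NARRATIVE_FIELD]]
    emb = train_embedding(train_tokens, replace(params, seed=seed))
    stats = compute_tfidf(train_tokens)
    x_train, _ = vectorize_corpus(train_tokens, emb, stats)
    x_test, _ = vectorize_corpus(test_tokens, emb, stats)
    return x_train, x_test


def outcome_comparison(
    n: int = 5000,
    seed: int = 0,
    signal_q: float = 0.9,
    ann_hyperparams: Optional[dict] = None,
) -> dict[str, float]:
    """Weighted F1 of narrative RF vs the four fixed-field models.

    Returns keys ``narrative_random_forest``, ``fixed_<family>`` for the
    four families, and ``majority_baseline``.
    """
    config = GeneratorConfig(
        n_records=n,
        seed=seed,
        class_proportions=dict(_THREE_CLASSES),
        narrative_signal_q=signal_q,
        missing_field_rate=0.0,
        nonemployee_rate=0.0,
    )
    df = _prepared(config)
    train_df, test_df = _split(df, seed)
    y_train, y_test = train_df[CLASS_FIELD], test_df[CLASS_FIELD]

    out: dict[str, float] = {}
    encoder = fit_target_encoder(train_df, CATEGORICAL_FIELDS, CLASS_FIELD, m=10.0)
    xf_train = transform(encoder, train_df[FIXED_FIELD_COLUMNS])
    xf_test = transform(encoder, test_df[FIXED_FIELD_COLUMNS])
    ann_hp = ann_hyperparams or {"epochs": 30, "hidden": (64, 32)}
    for family in ("logistic_regression", "decision_tree", "random_forest", "ann"):
        hp = ann_hp if family == "ann" else {}
        model = train(ModelSpec("classification", family, hyperparams=hp, seed=seed), xf_train, y_train)
        out[f"fixed_{family}"] = classification_report(y_test, model.predict(xf_test)).weighted_f1

    xn_train, xn_test = _narrative_matrices(train_df, test_df, STUDY_EMBEDDING, seed)
    rf = train(ModelSpec("classification", "random_forest", seed=seed), xn_train, y_train)
    out["narrative_random_forest"] = classification_report(
        y_test, rf.predict(xn_test)
    ).weighted_f1
    out["narrative_random_forest_accuracy"] = classification_report(
        y_test, rf.predict(xn_test)
    ).accuracy

    majority = y_train.value_counts().idxmax()
    out["majority_baseline"] = classification_report(
        y_test, [majority] * len(y_test)
    ).weighted_f1
    return out


def dafw_comparison(n: int = 5000, seed: int = 0) -> dict[str, float]:
    """Test-set RMSE of fixed-field vs narrative regressors (RF and ANN).

    DAFW is generated from hours into shift and job experience only: the
    category-effect ladder is flattened so nothing about lost days is
    recoverable from the narrative.
    """
    cards = {"nature_of_injury": 38, "injured_body_part": 47, "occupation": 198}
    flat = {f"{f}_{i:03d}": 1.0 for f, k in cards.items() for i in range(k)}
    config = GeneratorConfig(
        n_records=n,
        seed=seed,
        class_proportions=dict(_LOST_TIME_THREE),
        narrative_signal_q=0.9,
        dafw_effect_map=flat,
        noise_sd=0.5,
        dafw_hours_coef=0.15,
        dafw_job_exp_coef=-0.05,
        missing_field_rate=0.0,
        nonemployee_rate=0.0,
        dafw_missing_rate=0.0,
    )
    df = _prepared(config)
    df = df[df[DAYS_FIELD].astype(float) > 0].reset_index(drop=True)
    train_df, test_df = _split(df, seed)
    y_train = train_df[DAYS_FIELD].astype(float)
    y_test = test_df[DAYS_FIELD].astype(float)

    out: dict[str, float] = {"dafw_sd": float(y_test.std())}
    encoder = fit_target_encoder(train_df, CATEGORICAL_FIELDS, CLASS_FIELD, m=10.0)
    xf_train = transform(encoder, train_df[FIXED_FIELD_COLUMNS])
    xf_test = transform(encoder, test_df[FIXED_FIELD_COLUMNS])
    xn_train, xn_test = _narrative_matrices(train_df, test_df, STUDY_EMBEDDING, seed)

    for label, (xtr, xte) in {"fixed": (xf_train, xf_test), "narrative": (xn_train, xn_test)}.items():
        for family in ("random_forest", "ann"):
            model = train(ModelSpec("regression", family, seed=seed), xtr, y_train)
            out[f"{label}_{family}_rmse"] = regression_report(
                y_test, model.predict(xte)
            ).rmse
    return out


def augmentation_benefit(
    n: int = 3000, seed: int = 0, minority_fraction: float = 0.05
) -> dict[str, float]:
    """Minority-class F1 of the narrative ANN with vs without augmentation."""
    minority = CLASS_LABELS[4]  # fatality: a natural rare class
    majority_share = (1.0 - minority_fraction) / 2.0
    config = GeneratorConfig(
        n_records=n,
        seed=seed,
        class_proportions={
            CLASS_LABELS[1]: majority_share,
            CLASS_LABELS[6]: majority_share,
            minority: minority_fraction,
        },
        narrative_signal_q=0.9,
        missing_field_rate=0.0,
        nonemployee_rate=0.0,
    )
    df = _prepared(config)
    train_df, test_df = _split(df, seed)

    # normalize narratives once; augmentation operates on normalized tokens
    train_df[NARRATIVE_FIELD] = [
        " ".join(normalize_narrative(t)) for t in train_df[NARRATIVE_FIELD]
    ]
    test_tokens = [normalize_narrative(t) for t in test_df[NARRATIVE_FIELD]]
    y_test = test_df[CLASS_FIELD]

    def minority_f1(train_frame: pd.DataFrame) -> float:
        tokens = [str(t).split() for t in train_frame[NARRATIVE_FIELD]]
        emb = train_embedding(tokens, replace(STUDY_EMBEDDING, seed=seed))
        stats = compute_tfidf(tokens)
        x_train, _ = vectorize_corpus(tokens, emb, stats)
        x_test, _ = vectorize_corpus(test_tokens, emb, stats)
        ann = train(
            ModelSpec("classification", "ann", hyperparams={"epochs": 30, "hidden": (64, 32)}, seed=seed),
            x_train,
            train_frame[CLASS_FIELD],
        )
        rep = classification_report(y_test, ann.predict(x_test))
        return rep.per_class.get(minority, {"f1": 0.0})["f1"]

    without = minority_f1(train_df)
    models = fit_class_models(train_df, replace(STUDY_EMBEDDING, seed=seed))
    plan = AugmentationPlan(
        per_class_models=models, classes_to_augment={minority}, seed=seed
    )
    augmented = augment_training_set(train_df, plan)
    with_aug = minority_f1(augmented)
    return {
        "minority_f1_without": without,
        "minority_f1_with": with_aug,
        "train_minority_before": int((train_df[CLASS_FIELD] == minority).sum()),
        "train_minority_after": int((augmented[CLASS_FIELD] == minority).sum()),
    }


def importance_study(
    n: int = 3000,
    seed: int = 0,
    dominant_field: str = "nature_of_injury",
    signal: float = 0.9,
) -> ImportanceTable:
    """LOO importance of the fixed-field ANN under a dominant-feature design."""
    config = GeneratorConfig(
        n_records=n,
        seed=seed,
        class_proportions=dict(_THREE_CLASSES),
        narrative_signal_q=0.0,
        fixed_field_signal={dominant_field: signal},
        missing_field_rate=0.0,
        nonemployee_rate=0.0,
    )
    df = _prepared(config)
    encoder = fit_target_encoder(df, CATEGORICAL_FIELDS, CLASS_FIELD, m=10.0)
    features = transform(encoder, df[FIXED_FIELD_COLUMNS])
    spec = ModelSpec(
        "classification", "ann", hyperparams={"epochs": 30, "hidden": (64, 32)}, seed=seed
    )
    return loo_importance(spec, features, df[CLASS_FIELD], FIXED_FIELD_COLUMNS, split_seed=seed)
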