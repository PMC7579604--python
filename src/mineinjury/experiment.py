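"""End-to-end experiment orchestration.

An experiment is one of five tasks: injury-outcome classification from
fixed-field entries or narratives (optionally with class-conditional
augmentation of the training narratives), or days-away-from-work (DAFW)
regression from fixed-field entries or narratives. Each run executes

    generate/load -> clean -> time features -> task rows -> stratified
    split -> (target-encode | vectorize [| augment]) -> train -> evaluate

and writes, into a run directory: the resolved configuration, an audit log
of row counts at every stage, a JSON report and confusion-matrix CSV per
model family, and (optionally) the leave-one-feature-out importance table.

Everything fitted from data — the target encoder, the embedding, the
TF-IDF statistics, the per-class augmentation models — is fitted on the
training partition only.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import preprocessing
from .augmentation import (
    DEFAULT_UNAUGMENTED_CLASSES,
    AugmentationPlan,
    augment_training_set,
    class_counts,
    fit_class_models,
)
from .encoding import fit_target_encoder, transform
from .evaluation import (
    EvalReport,
    RegressionReport,
    classification_report,
    regression_report,
    stratified_split,
)
from .importance import ImportanceTable, loo_importance
from .modeling import ModelSpec, train
from .narrative_vectors import EmbeddingParams, compute_tfidf, train_embedding, vectorize_corpus
from .preprocessing import (
    HOURS_FIELD,
    clean_records,
    engineer_time_features,
    normalize_narrative,
    select_task_rows,
)
from .records import (
    CATEGORICAL_FIELDS,
    CLASS_FIELD,
    DAYS_FIELD,
    NARRATIVE_FIELD,
    read_records_csv,
    write_records_csv,
)
from .synthetic import GeneratorConfig, generate_dataset

EXPERIMENT_TASKS = (
    "outcome_fixed_field",
    "outcome_narrative",
    "outcome_narrative_augmented",
    "dafw_fixed_field",
    "dafw_narrative",
)

_CLASSIFICATION_FAMILIES = ("logistic_regression", "decision_tree", "random_forest", "ann")
_REGRESSION_FAMILIES = ("random_forest", "ann")

NUMERIC_FEATURES = (
    "coal_metal",
    "accident_time",
    "shift_start_time",
    HOURS_FIELD,
    "total_experience",
    "mine_experience",
    "job_experience",
)


@dataclass
class ExperimentConfig:
    task: str
    generator: GeneratorConfig
    encoder_m: float = 10.0
    embedding: EmbeddingParams = field(default_factory=EmbeddingParams)
    model_families: Optional[Sequence[str]] = None
    model_hyperparams: dict = field(default_factory=dict)
    model_seed: int = 0
    split_seed: int = 0
    train_fraction: float = 0.7
    keep_classes: Optional[Sequence[str]] = None
    n_words: int = 6
    top_k: int = 3
    classes_to_augment: Optional[Sequence[str]] = None
    max_new_per_class: Optional[int] = None
    augment_seed: int = 0
    run_importance: bool = False
    input_csv: Optional[str] = None
    output_dir: str = "runs"

    def __post_init__(self) -> None:
        if self.task not in EXPERIMENT_TASKS:
            raise ValueError(f"task must be one of {EXPERIMENT_TASKS}")
        if self.model_families is None:
            self.model_families = list(
                _CLASSIFICATION_FAMILIES if self.task.startswith("outcome") else _REGRESSION_FAMILIES
            )

    @property
    def is_classification(self) -> bool:
        return self.task.startswith("outcome")

    @classmethod
    def from_file(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        gen = raw.pop("generator")
        if "narrative_length_range" in gen:
            gen["narrative_length_range"] = tuple(gen["narrative_length_range"])
        emb = raw.pop("embedding", {})
        return cls(generator=GeneratorConfig(**gen), embedding=EmbeddingParams(**emb), **raw)

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class ExperimentResult:
    run_dir: Path
    reports: dict[str, object]  # family -> EvalReport | RegressionReport
    audit: list[dict]
    importance: Optional[ImportanceTable] = None


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and snapshot path."""

    def __init__(self, stage: str, snapshot: Optional[Path], cause: Exception):
        super().__init__(f"stage {stage!r} failed ({cause}); input snapshot: {snapshot}")
        self.stage = stage
        self.snapshot = snapshot


def _fixed_field_features(
    train_df: pd.DataFrame, test_df: pd.DataFrame, m: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    encoder = fit_target_encoder(train_df, CATEGORICAL_FIELDS, CLASS_FIELD, m=m)
    cols = list(CATEGORICAL_FIELDS) + list(NUMERIC_FEATURES)
    x_train = transform(encoder, train_df[cols])
    x_test = transform(encoder, test_df[cols])
    return x_train, x_test


def _narrative_features(
    train_df: pd.DataFrame,
    test_df: pd.DataFrame,
    params: EmbeddingParams,
) -> tuple[np.ndarray, np.ndarray]:
    train_tokens = [normalize_narrative(t) for t in train_df[NARRATIVE_FIELD]]
    test_tokens = [normalize_narrative(t) for t in test_df[NARRATIVE_FIELD]]
    embedding = train_embedding(train_tokens, params)
    stats = compute_tfidf(train_tokens)
    x_train, _ = vectorize_corpus(train_tokens, embedding, stats)
    x_test, _ = vectorize_corpus(test_tokens, embedding, stats)
    return x_train, x_test


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    run_dir = Path(config.output_dir) / f"{config.task}_{int(time.time())}"
    run_dir.mkdir(parents=True, exist_ok=True)
    audit: list[dict] = []
    current: Optional[pd.DataFrame] = None

    def stage(name, fn, *args, **kwargs):
        nonlocal current
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # snapshot the stage input for debugging
            snap = None
            if isinstance(current, pd.DataFrame):
                snap = run_dir / f"failed_{name}_input.csv"
                write_records_csv(current, snap)
            raise StageError(name, snap, exc) from exc
        entry = {"stage": name, "seconds": round(time.perf_counter() - t0, 3)}
        if isinstance(result, pd.DataFrame):
            entry["rows_in"] = int(len(current)) if current is not None else None
            entry["rows_out"] = int(len(result))
            current = result
        audit.append(entry)
        return result

    # --- data ---------------------------------------------------------------
    if config.input_csv:
        df = stage("load", read_records_csv, config.input_csv)
    else:
        df = stage("generate", generate_dataset, config.generator)

    clean_result = stage("clean", clean_records, df)
    current = cleaned = clean_result.records
    audit[-1].update(
        rows_in=len(df), rows_out=len(cleaned), dropped=clean_result.dropped_counts
    )

    cleaned = stage("time_features", engineer_time_features, cleaned)
    base_task = "dafw" if config.task.startswith("dafw") else (
        "outcome_fixed_field" if config.task == "outcome_fixed_field" else "outcome_narrative"
    )
    selected = stage(
        "select_task_rows",
        select_task_rows,
        cleaned,
        base_task,
        keep_classes=config.keep_classes,
    )

    train_df, test_df = stratified_split(
        selected, CLASS_FIELD, config.train_fraction, seed=config.split_seed
    )
    train_df, test_df = train_df.copy(), test_df.copy()
    audit.append(
        {"stage": "split", "rows_in": len(selected), "train": len(train_df), "test": len(test_df)}
    )

    # --- augmentation (training rows only) -----------------------------------
    if config.task == "outcome_narrative_augmented":
        def _augment(d: pd.DataFrame) -> pd.DataFrame:
            norm = {i: normalize_narrative(t) for i, t in d[NARRATIVE_FIELD].items()}
            d = d.copy()
            d[NARRATIVE_FIELD] = [" ".join(norm[i]) for i in d.index]
            models = fit_class_models(d, config.embedding)
            to_aug = (
                set(config.classes_to_augment)
                if config.classes_to_augment is not None
                else set(d[CLASS_FIELD].unique()) - DEFAULT_UNAUGMENTED_CLASSES
            )
            plan = AugmentationPlan(
                per_class_models=models,
                classes_to_augment=to_aug,
                n_words=config.n_words,
                top_k=config.top_k,
                seed=config.augment_seed,
                max_new_per_class=config.max_new_per_class,
            )
            return augment_training_set(d, plan)

        before = class_counts(train_df)
        saved_current = current
        current = train_df
        train_df = stage("augment", _augment, train_df)
        audit[-1]["class_counts_before"] = before
        audit[-1]["class_counts_after"] = class_counts(train_df)
        current = saved_current

    # --- features -----------------------------------------------------------
    if config.task in ("outcome_fixed_field", "dafw_fixed_field"):
        x_train, x_test = _fixed_field_features(train_df, test_df, config.encoder_m)
    else:
        x_train, x_test = _narrative_features(train_df, test_df, config.embedding)
    audit.append({"stage": "features", "n_features": int(np.shape(x_train)[1])})

    if config.is_classification:
        y_train, y_test = train_df[CLASS_FIELD], test_df[CLASS_FIELD]
        task = "classification"
    else:
        y_train = train_df[DAYS_FIELD].astype(float)
        y_test = test_df[DAYS_FIELD].astype(float)
        task = "regression"

    # --- models -------------------------------------------------------------
    reports: dict[str, object] = {}
    for family in config.model_families:
        t0 = time.perf_counter()
        spec = ModelSpec(
            task=task,
            family=family,
            hyperparams=config.model_hyperparams.get(family, {}),
            seed=config.model_seed,
        )
        fitted = train(spec, x_train, y_train)
        pred = fitted.predict(x_test)
        if task == "classification":
            report = classification_report(y_test, pred)
            report.confusion_frame().to_csv(run_dir / f"confusion_{family}.csv")
        else:
            report = regression_report(y_test, pred)
        reports[family] = report
        (run_dir / f"report_{family}.json").write_text(report.to_json())
        audit.append(
            {"stage": f"train_eval_{family}", "seconds": round(time.perf_counter() - t0, 3)}
        )

    # --- importance ----------------------------------------------------------
    importance_table = None
    if config.run_importance and config.task == "outcome_fixed_field":
        enc_all = fit_target_encoder(train_df, CATEGORICAL_FIELDS, CLASS_FIELD, m=config.encoder_m)
        cols = list(CATEGORICAL_FIELDS) + list(NUMERIC_FEATURES)
        full = pd.concat([train_df, test_df], ignore_index=True)
        features = transform(enc_all, full[cols])
        names = list(CATEGORICAL_FIELDS) + list(NUMERIC_FEATURES)
        spec = ModelSpec(
            task="classification",
            family="ann",
            hyperparams=config.model_hyperparams.get("ann", {}),
            seed=config.model_seed,
        )
        importance_table = loo_importance(
            spec, features, full[CLASS_FIELD], names, split_seed=config.split_seed
        )
        (run_dir / "importance.json").write_text(importance_table.to_json())
        importance_table.to_frame().to_csv(run_dir / "importance.csv", index=False)

    (run_dir / "config.json").write_text(json.dumps(config.resolved(), indent=2, default=str))
    (run_dir / "audit.json").write_text(json.dumps(audit, indent=2))
    return ExperimentResult(run_dir=run_dir, reports=reports, audit=audit, importance=importance_table)
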