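"""Learner configuration: the four model families with their fixed settings.

Logistic regression, decision tree and random forest delegate to
scikit-learn; the artificial neural network is the package's own seeded
numpy MLP (:mod:`mineinjury.mlp`). Settings follow the study design:
random forests use 30 trees with Gini impurity (classification) or squared
error (regression); the ANN has two ReLU hidden layers, learning rate
0.001, dropout 0.3, softmax output for classification and softplus output
for regression so predicted days away from work cannot be negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

from .mlp import MLP

FAMILIES = ("logistic_regression", "decision_tree", "random_forest", "ann")
TASKS = ("classification", "regression")


@dataclass
class ModelSpec:
    """One learner configuration; hyperparams override the family defaults."""

    task: str
    family: str
    hyperparams: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.task == "regression" and self.family == "logistic_regression":
            raise ValueError("logistic regression is a classification family")


@dataclass
class FittedModel:
    """A trained learner with a uniform predict surface."""

    spec: ModelSpec
    model: object
    scaler: Optional[StandardScaler]
    feature_names: Optional[list[str]]

    def _prepare(self, features) -> np.ndarray:
        x = _as_matrix(features)
        if self.feature_names is not None and isinstance(features, pd.DataFrame):
            if list(features.columns) != self.feature_names:
                raise ValueError("feature columns differ from those used in training")
        n_expected = (
            self.scaler.n_features_in_
            if self.scaler is not None
            else getattr(self.model, "n_features_in_", None)
        )
        if n_expected is not None and x.shape[1] != n_expected:
            raise ValueError(
                f"feature count mismatch: model expects {n_expected}, got {x.shape[1]}"
            )
        if self.scaler is not None:
            x = self.scaler.transform(x)
        return x

    def predict(self, features):
        """Class labels (classification) or non-negative reals (ANN regression)."""
        return self.model.predict(self._prepare(features))

    def predict_proba(self, features) -> np.ndarray:
        if self.spec.task != "classification":
            raise ValueError("probabilities are only defined for classification")
        return self.model.predict_proba(self._prepare(features))

    @property
    def classes_(self):
        return self.model.classes_


def _as_matrix(features) -> np.ndarray:
    x = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(
        features, dtype=float
    )
    if x.ndim != 2:
        raise ValueError("features must be a 2-D numeric table")
    return x


def _build(spec: ModelSpec):
    hp = dict(spec.hyperparams)
    if spec.family == "logistic_regression":
        return LogisticRegression(
            max_iter=hp.pop("max_iter", 2000),
            C=hp.pop("C", 1.0),
            random_state=spec.seed,
            **hp,
        )
    if spec.family == "decision_tree":
        if spec.task == "classification":
            return DecisionTreeClassifier(
                criterion=hp.pop("criterion", "gini"), random_state=spec.seed, **hp
            )
        return DecisionTreeRegressor(
            criterion=hp.pop("criterion", "squared_error"), random_state=spec.seed, **hp
        )
    if spec.family == "random_forest":
        n_trees = hp.pop("n_trees", 30)
        if spec.task == "classification":
            return RandomForestClassifier(
                n_estimators=n_trees,
                criterion=hp.pop("criterion", "gini"),
                random_state=spec.seed,
                n_jobs=1,
                **hp,
            )
        return RandomForestRegressor(
            n_estimators=n_trees,
            criterion=hp.pop("criterion", "squared_error"),
            random_state=spec.seed,
            n_jobs=1,
            **hp,
        )
    # ann
    return MLP(
        task=spec.task,
        hidden=tuple(hp.pop("hidden", (128, 64))),
        learning_rate=hp.pop("learning_rate", 0.001),
        dropout=hp.pop("dropout", 0.3),
        epochs=hp.pop("epochs", 50),
        batch_size=hp.pop("batch_size", 64),
        seed=spec.seed,
        **hp,
    )


def train(spec: ModelSpec, features, targets) -> FittedModel:
    """Fit one configured learner; validates inputs before fitting."""
    x = _as_matrix(features)
    if np.isnan(x).any():
        raise ValueError("features contain NaN; clean or impute before training")
    y = np.asarray(targets)
    if len(y) != len(x):
        raise ValueError(f"feature/target length mismatch: {len(x)} vs {len(y)}")
    if spec.task == "regression":
        yv = y.astype(float)
        if np.isnan(yv).any():
            raise ValueError("regression targets contain NaN")
        y = yv

    scaler = None
    if spec.family == "logistic_regression":
        # the MLP standardizes internally; scale here for logistic regression
        scaler = StandardScaler().fit(x)
        x = scaler.transform(x)
    model = _build(spec).fit(x, y)
    names = list(features.columns) if isinstance(features, pd.DataFrame) else None
    return FittedModel(spec=spec, model=model, scaler=scaler, feature_names=names)


def predict(model: FittedModel, features):
    """Functional alias for :meth:`FittedModel.predict`."""
    return model.predict(features)
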