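"""Supervised switch/nonswitch classification of DoS feature vectors.

Three model families are supported — a single decision tree, a random
forest, and a gradient-boosted tree ensemble — trained on the 14-feature
DoS descriptors with stratified 5-fold cross-validation.  Classification
is per angle; a residue is a switch residue when at least one of its
angles is classified as a switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .dos import FEATURE_NAMES

__all__ = [
    "LabeledFeatureSet",
    "CVReport",
    "SwitchModel",
    "MODEL_KINDS",
    "DEFAULT_HYPERPARAMETERS",
    "train",
    "cross_validate",
    "predict",
    "residue_rollup",
    "save_model",
    "load_model",
]

MODEL_KINDS = ("decision_tree", "random_forest", "gradient_boosted")

#: overridable via the ``hyperparameters`` argument of train/cross_validate
DEFAULT_HYPERPARAMETERS: dict[str, dict] = {
    "decision_tree": {},
    "random_forest": {"n_estimators": 100},
    "gradient_boosted": {"n_estimators": 100, "max_depth": 3},
}

_MODEL_SCHEMA_VERSION = 1


@dataclass
class LabeledFeatureSet:
    """Feature rows with binary switch labels, keyed by unique identifiers."""

    identifiers: list[str]
    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if len(self.identifiers) != len(set(self.identifiers)):
            raise ValueError("duplicate identifiers in labeled feature set")
        if self.X.shape[0] != len(self.identifiers) or self.X.shape[0] != self.y.size:
            raise ValueError("identifiers, features, and labels must align")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} feature columns, got {self.X.shape[1]}"
            )
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.identifiers)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, id_column: str = "identifier",
                   label_column: str = "label") -> "LabeledFeatureSet":
        missing = [c for c in (id_column, label_column, *FEATURE_NAMES) if c not in df.columns]
        if missing:
            raise ValueError(f"feature table is missing columns: {missing}")
        return cls(
            identifiers=df[id_column].astype(str).tolist(),
            X=df[list(FEATURE_NAMES)].to_numpy(float),
            y=df[label_column].to_numpy(int),
        )


@dataclass
class CVReport:
    """Stratified k-fold accuracy summary (mean with std, as in benchmark tables)."""

    fold_accuracies: list[float]
    n_folds: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies))

    def __str__(self) -> str:  # e.g. "96.94 (0.04)" in percent
        return f"{100 * self.mean_accuracy:.2f} ({100 * self.std_accuracy:.2f})"


@dataclass
class SwitchModel:
    model_kind: str
    estimator: object
    feature_names: tuple[str, ...]
    metadata: dict = field(default_factory=dict)


def _make_estimator(model_kind: str, seed: int, hyperparameters: Mapping | None):
    hp = dict(DEFAULT_HYPERPARAMETERS.get(model_kind, {}))
    if hyperparameters:
        hp.update(hyperparameters)
    if model_kind == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if model_kind == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if model_kind == "gradient_boosted":
        from xgboost import XGBClassifier

        return XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", **hp
        )
    raise ValueError(f"unknown model kind {model_kind!r}; choose from {MODEL_KINDS}")


def _check_trainable(dataset: LabeledFeatureSet) -> None:
    counts = np.bincount(dataset.y, minlength=2)
    if counts[0] < 2 or counts[1] < 2:
        raise ValueError(
            f"training needs >= 2 examples per class (got 0:{counts[0]}, 1:{counts[1]})"
        )


def train(
    dataset: LabeledFeatureSet,
    model_kind: str = "random_forest",
    seed: int = 0,
    hyperparameters: Mapping | None = None,
) -> SwitchModel:
    """Fit a switch classifier; deterministic for a fixed seed."""
    _check_trainable(dataset)
    est = _make_estimator(model_kind, seed, hyperparameters)
    est.fit(dataset.X, dataset.y)
    meta = {
        "seed": seed,
        "n_training_rows": len(dataset),
        "hyperparameters": dict(hyperparameters or DEFAULT_HYPERPARAMETERS.get(model_kind, {})),
    }
    return SwitchModel(model_kind, est, tuple(dataset.feature_names), meta)


def cross_validate(
    dataset: LabeledFeatureSet,
    model_kind: str = "random_forest",
    n_folds: int = 5,
    seed: int = 0,
    hyperparameters: Mapping | None = None,
) -> CVReport:
    """Stratified k-fold cross-validation with fixed-seed shuffling."""
    if n_folds < 2:
        raise ValueError("cross-validation needs at least 2 folds")
    counts = np.bincount(dataset.y, minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"each class needs >= {n_folds} members for {n_folds}-fold CV "
            f"(got 0:{counts[0]}, 1:{counts[1]})"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs: list[float] = []
    for tr, te in skf.split(dataset.X, dataset.y):
        est = _make_estimator(model_kind, seed, hyperparameters)
        est.fit(dataset.X[tr], dataset.y[tr])
        accs.append(float(np.mean(est.predict(dataset.X[te]) == dataset.y[te])))
    return CVReport(accs, n_folds)


def predict(model: SwitchModel, features) -> np.ndarray:
    """Predict 0/1 switch labels for feature rows (array or DataFrame)."""
    if isinstance(features, pd.DataFrame):
        missing = [c for c in model.feature_names if c not in features.columns]
        if missing:
            raise ValueError(f"feature table is missing columns: {missing}")
        X = features[list(model.feature_names)].to_numpy(float)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != len(model.feature_names):
            raise ValueError(
                f"expected {len(model.feature_names)} features, got {X.shape[1]}"
            )
    return np.asarray(model.estimator.predict(X), dtype=int)


def residue_rollup(
    triplet_labels: Mapping[str, int] | Sequence[tuple[str, int]],
) -> tuple[bool, list[str]]:
    """Roll per-angle calls up to the residue level.

    A residue is a switch residue iff at least one of its angles is a
    switch.  Returns the flag and the list of switch-triplet labels in
    input order.
    """
    items = list(triplet_labels.items()) if isinstance(triplet_labels, Mapping) else list(triplet_labels)
    switches = [t for t, lab in items if int(lab) == 1]
    return (len(switches) > 0, switches)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: SwitchModel, path: str | Path) -> None:
    doc = {
        "schema_version": _MODEL_SCHEMA_VERSION,
        "model_kind": model.model_kind,
        "feature_names": list(model.feature_names),
        "metadata": model.metadata,
        "estimator": model.estimator,
    }
    joblib.dump(doc, path)


def load_model(path: str | Path) -> SwitchModel:
    doc = joblib.load(path)
    if doc.get("schema_version") != _MODEL_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported model schema version {doc.get('schema_version')!r}"
        )
    return SwitchModel(
        doc["model_kind"], doc["estimator"], tuple(doc["feature_names"]), doc["metadata"]
    )
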