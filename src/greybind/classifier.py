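"""Random-forest training, prediction, and evaluation protocols.

The forest follows the classic Breiman defaults (bootstrap resampling of
the training-set size, Gini impurity, unlimited depth); only the tree
count and the number of predictors sampled per split are pinned by config
(560 and 5 by default).  Prediction is the majority vote of the trees;
ties resolve to the alphabetically first class (``binding``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from greybind import features as features_mod
from greybind.dataset import BINDING, NON_BINDING, LabeledDataset
from greybind.encoding import ResidueCodeTable

_ARTIFACT_VERSION = 1


@dataclass(frozen=True)
class RfConfig:
    """Random-forest hyperparameters."""

    n_trees: int = 560
    predictors_per_split: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 1 <= self.predictors_per_split <= features_mod.N_FEATURES:
            raise ValueError(
                f"predictors_per_split must be in [1, {features_mod.N_FEATURES}]"
            )

    def to_dict(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "predictors_per_split": self.predictors_per_split,
            "seed": self.seed,
        }


@dataclass
class TrainedModel:
    """A fitted forest plus the config and feature-column order used."""

    estimator: RandomForestClassifier
    config: RfConfig
    feature_names: tuple[str, ...] = tuple(features_mod.FEATURE_NAMES)


def _check_features(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.ndim != 2 or X.shape[1] != features_mod.N_FEATURES:
        raise ValueError(
            f"feature matrix must have {features_mod.N_FEATURES} columns, got shape {X.shape}"
        )
    return X


def train(X: np.ndarray, y: Sequence[str], config: RfConfig | None = None) -> TrainedModel:
    """Fit a seeded random forest on 23-D feature vectors.

    Raises
    ------
    ValueError
        Wrong feature dimension, a single-class label vector, or fewer
        than 2 examples in some class.
    """
    if config is None:
        config = RfConfig()
    X = _check_features(X)
    y = np.asarray(y, dtype=object)
    if y.shape != (X.shape[0],):
        raise ValueError("labels must align with feature rows")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("training data must contain both classes")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 training examples")
    estimator = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.predictors_per_split,
        criterion="gini",
        max_depth=None,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    estimator.fit(X, y)
    return TrainedModel(estimator=estimator, config=config)


def predict(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Majority-vote labels for 23-D feature vectors.

    Ties break toward the class with the lower index in the model's
    sorted class list (``binding`` before ``non-binding``).
    """
    if not isinstance(model, TrainedModel) or not hasattr(model.estimator, "estimators_"):
        raise RuntimeError("model is not fitted")
    X = _check_features(X)
    return model.estimator.predict(X)


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class ClassCounts:
    n: int
    n_correct: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n:
            raise ValueError(f"invalid counts: {self.n_correct}/{self.n}")

    @property
    def success_rate(self) -> float:
        """Percent correct, 100 * n_correct / n."""
        return 100.0 * self.n_correct / self.n if self.n else 0.0


@dataclass(frozen=True)
class EvaluationReport:
    """Per-class and overall correct counts and success rates (%)."""

    classes: Mapping[str, ClassCounts]
    config: RfConfig | None = None
    protocol: str = ""

    @property
    def overall(self) -> ClassCounts:
        return ClassCounts(
            n=sum(c.n for c in self.classes.values()),
            n_correct=sum(c.n_correct for c in self.classes.values()),
        )

    def to_dict(self) -> dict:
        payload = {
            "protocol": self.protocol,
            "classes": {
                label: {
                    "n": counts.n,
                    "n_correct": counts.n_correct,
                    "success_rate": counts.success_rate,
                }
                for label, counts in self.classes.items()
            },
            "overall": {
                "n": self.overall.n,
                "n_correct": self.overall.n_correct,
                "success_rate": self.overall.success_rate,
            },
        }
        if self.config is not None:
            payload["config"] = self.config.to_dict()
        return payload

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


def report_from_predictions(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    config: RfConfig | None = None,
    protocol: str = "",
) -> EvaluationReport:
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/label length mismatch")
    classes: dict[str, ClassCounts] = {}
    for label in sorted(set(y_true)):
        mask = y_true == label
        classes[label] = ClassCounts(
            n=int(mask.sum()), n_correct=int((y_pred[mask] == label).sum())
        )
    return EvaluationReport(classes=classes, config=config, protocol=protocol)


def extract_features(
    dataset: LabeledDataset,
    table: ResidueCodeTable | None = None,
    unknown_policy: str = "skip",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """PseAAC matrix, label vector and ids for every record in a dataset."""
    X = np.vstack(
        [features_mod.pseaac(r.sequence, table=table, unknown_policy=unknown_policy) for r in dataset]
    )
    y = np.asarray(dataset.labels(), dtype=object)
    return X, y, [r.id for r in dataset]


def _fold_seeds(master_seed: int, n: int) -> list[int]:
    """One independent 31-bit seed per jackknife fold from a master seed."""
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


def jackknife_features(
    X: np.ndarray, y: Sequence[str], config: RfConfig | None = None
) -> EvaluationReport:
    """Leave-one-out evaluation on a precomputed feature matrix."""
    if config is None:
        config = RfConfig()
    X = _check_features(X)
    y = np.asarray(y, dtype=object)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 3:
        raise ValueError("jackknife needs at least 3 examples in each class")
    n = X.shape[0]
    seeds = _fold_seeds(config.seed, n)
    predictions = np.empty(n, dtype=object)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        fold_config = RfConfig(config.n_trees, config.predictors_per_split, seeds[i])
        model = train(X[mask], y[mask], fold_config)
        predictions[i] = predict(model, X[i])[0]
        mask[i] = True
    return report_from_predictions(y, predictions, config=config, protocol="jackknife")


def jackknife(
    dataset: LabeledDataset,
    config: RfConfig | None = None,
    table: ResidueCodeTable | None = None,
) -> EvaluationReport:
    """Leave-one-out jackknife over a labeled sequence dataset.

    Features depend only on each sequence itself, so they are extracted
    once; each of the N rounds retrains the forest on the remaining N-1
    samples with a fold seed derived deterministically from the master
    seed.
    """
    X, y, _ = extract_features(dataset, table=table)
    return jackknife_features(X, y, config=config)


def evaluate_independent(model: TrainedModel, test: LabeledDataset | tuple) -> EvaluationReport:
    """Single-pass evaluation of a fitted model on a labeled test set."""
    if isinstance(test, LabeledDataset):
        if len(test) == 0:
            raise ValueError("test set is empty")
        X, y, _ = extract_features(test)
    else:
        X, y = test
        X = _check_features(X)
        y = np.asarray(y, dtype=object)
        if y.size == 0:
            raise ValueError("test set is empty")
    y_pred = predict(model, X)
    return report_from_predictions(y, y_pred, config=model.config, protocol="independent")


# ---------------------------------------------------------------------------
# persistence


def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump(
        {
            "artifact_version": _ARTIFACT_VERSION,
            "estimator": model.estimator,
            "config": model.config.to_dict(),
            "feature_names": list(model.feature_names),
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    if payload.get("artifact_version") != _ARTIFACT_VERSION:
        raise ValueError(f"unsupported model artifact version in {path}")
    return TrainedModel(
        estimator=payload["estimator"],
        config=RfConfig(**payload["config"]),
        feature_names=tuple(payload["feature_names"]),
    )
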