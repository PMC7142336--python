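"""SVM-RBF and random-forest classifiers with the exponential grid search.

The primary classifier is a soft-margin SVM with the RBF kernel; its penalty
C and kernel width gamma are tuned over the grid ``2**a`` for integer
exponents a in [-10, 10] (both axes) by stratified k-fold cross-validation
accuracy on the training data only.  Ties resolve toward smaller C, then
smaller gamma.  A random forest is provided for comparison runs.

Features are standardized with training-set statistics before the SVM by
default: ACT/CCT magnitudes (bounded by ~0.25) differ from AAC magnitudes
(bounded by 1) and the RBF kernel is scale-sensitive.  A flag disables it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data import LabeledDataset

MODEL_SCHEMA_VERSION = 1
DEFAULT_RF_TREES = 500


@dataclass
class SvmConfig:
    """Soft-margin penalty C, RBF width gamma, and grid-search bounds."""

    C: float = 1.0
    gamma: float = 1.0
    grid_lo_exp: int = -10
    grid_hi_exp: int = 10

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if self.grid_lo_exp > self.grid_hi_exp:
            raise ValueError("grid_lo_exp must not exceed grid_hi_exp")


@dataclass
class GridSearchResult:
    C: float
    gamma: float
    cv_accuracy: float
    table: pd.DataFrame  # one row per (C, gamma) candidate


class _Scaler:
    """Per-feature center/scale learned on training data; constant features
    get scale 1 so no division by zero occurs."""

    def __init__(self, mean: np.ndarray, scale: np.ndarray):
        self.mean = mean
        self.scale = scale

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Scaler":
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0.0] = 1.0
        return cls(mean, scale)

    @classmethod
    def identity(cls, d: int) -> "_Scaler":
        return cls(np.zeros(d), np.ones(d))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.scale


@dataclass
class TrainedClassifier:
    """A fitted model plus the scaler and feature-name contract it was
    trained under.  Prediction requires the same feature names; any other
    set is an error (column order may differ — alignment is by name)."""

    kind: str
    model: object
    scaler: _Scaler
    feature_names: list[str]
    hyperparams: dict = field(default_factory=dict)

    def _align(self, features: pd.DataFrame) -> np.ndarray:
        have = set(features.columns)
        want = set(self.feature_names)
        if have != want:
            missing = sorted(want - have)[:5]
            extra = sorted(have - want)[:5]
            raise ValueError(
                f"feature names do not match training: missing={missing}, "
                f"extra={extra}"
            )
        return features.loc[:, self.feature_names].to_numpy()

    def predict_scores(
        self, features: pd.DataFrame
    ) -> tuple[np.ndarray, np.ndarray]:
        """Continuous score and binary label per sample.

        SVM scores are signed decision values (positive => DNA-binding);
        RF scores are positive-class vote fractions.  Labels are score > 0
        for the SVM and score >= 0.5 for the forest.
        """
        X = self.scaler.transform(self._align(features))
        if self.kind == "svm":
            scores = self.model.decision_function(X)
            labels = (scores > 0).astype(int)
        else:
            scores = self.model.predict_proba(X)[:, 1]
            labels = (scores >= 0.5).astype(int)
        return scores, labels

    def save(self, path: Union[str, Path]) -> None:
        joblib.dump(
            {
                "schema_version": MODEL_SCHEMA_VERSION,
                "kind": self.kind,
                "model": self.model,
                "scaler_mean": self.scaler.mean,
                "scaler_scale": self.scaler.scale,
                "feature_names": self.feature_names,
                "hyperparams": self.hyperparams,
            },
            path,
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "TrainedClassifier":
        payload = joblib.load(path)
        if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(
                f"model schema version {payload.get('schema_version')} is not "
                f"supported (expected {MODEL_SCHEMA_VERSION})"
            )
        return cls(
            kind=payload["kind"],
            model=payload["model"],
            scaler=_Scaler(payload["scaler_mean"], payload["scaler_scale"]),
            feature_names=payload["feature_names"],
            hyperparams=payload["hyperparams"],
        )


def train(
    data: LabeledDataset,
    kind: str = "svm",
    *,
    C: float = 1.0,
    gamma: float | str = "scale",
    n_trees: int = DEFAULT_RF_TREES,
    seed: int = 0,
    standardize: bool = True,
) -> TrainedClassifier:
    """Standardize with training statistics (optional) and fit the model.

    ``gamma`` may be a positive real or ``"scale"`` (sklearn's 1/(D * var)
    heuristic), the sensible default when no grid search has been run.
    """
    data.require_both_classes()
    if isinstance(gamma, str) and gamma != "scale":
        raise ValueError(f"gamma must be positive or 'scale', got {gamma!r}")
    if not isinstance(gamma, str) and gamma <= 0:
        raise ValueError("gamma must be positive")
    if C <= 0:
        raise ValueError("C must be positive")
    Xraw = data.X.to_numpy()
    scaler = _Scaler.fit(Xraw) if standardize else _Scaler.identity(Xraw.shape[1])
    X = scaler.transform(Xraw)
    if kind == "svm":
        model = SVC(kernel="rbf", C=C, gamma=gamma)
        hyper = {"C": C, "gamma": gamma, "standardize": standardize}
    elif kind == "random_forest":
        model = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed, n_jobs=1
        )
        hyper = {"n_trees": n_trees, "seed": seed, "standardize": standardize}
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    model.fit(X, data.y)
    return TrainedClassifier(
        kind=kind,
        model=model,
        scaler=scaler,
        feature_names=data.feature_names,
        hyperparams=hyper,
    )


def stratified_folds(
    y: np.ndarray, folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Shuffled stratified fold indices; errors if a training side would
    lose a class entirely."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))
    for tr, _ in splits:
        if len(np.unique(y[tr])) < 2:
            raise ValueError("degenerate fold: a training split lost a class")
    return splits


def grid_search_svm(
    train_data: LabeledDataset,
    config: SvmConfig | None = None,
    folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
    exp_step: int = 1,
) -> GridSearchResult:
    """Pick (C, gamma) = (2**a, 2**b) maximizing stratified CV accuracy.

    Every integer-exponent pair within the config bounds is evaluated on the
    *training data only*; ties break toward smaller a, then smaller b.  The
    full accuracy table is returned alongside the winner.  ``exp_step``
    coarsens the grid (step 2 quarters the candidate count) without changing
    the bounds.
    """
    cfg = config or SvmConfig()
    train_data.require_both_classes()
    X = train_data.X.to_numpy()
    y = train_data.y
    splits = stratified_folds(y, folds, seed)
    # standardize once per fold, reused across the whole grid
    fold_data = []
    for tr, va in splits:
        scaler = _Scaler.fit(X[tr]) if standardize else _Scaler.identity(X.shape[1])
        fold_data.append(
            (scaler.transform(X[tr]), y[tr], scaler.transform(X[va]), y[va])
        )

    exponents = range(cfg.grid_lo_exp, cfg.grid_hi_exp + 1, exp_step)
    best: tuple[float, int, int] | None = None
    rows = []
    for a in exponents:
        for b in exponents:
            C, gamma = 2.0**a, 2.0**b
            correct = 0
            total = 0
            for Xtr, ytr, Xva, yva in fold_data:
                clf = SVC(kernel="rbf", C=C, gamma=gamma)
                clf.fit(Xtr, ytr)
                correct += int((clf.predict(Xva) == yva).sum())
                total += len(yva)
            acc = correct / total
            rows.append({"a": a, "b": b, "C": C, "gamma": gamma, "cv_accuracy": acc})
            if best is None or acc > best[0]:
                best = (acc, a, b)
    assert best is not None
    acc, a, b = best
    return GridSearchResult(
        C=2.0**a, gamma=2.0**b, cv_accuracy=acc, table=pd.DataFrame(rows)
    )
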