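"""Tree-ensemble feature importance ranking and top-K selection.

Features are ranked by the importance scores of a gradient-boosted tree
ensemble (XGBoost, the default) or a random forest, then the K best are
retained.  RF importances are mean-impurity-decrease values normalized to
sum 1; XGBoost importances default to total gain, with split-count
("weight") and per-split average gain available by flag.  Ties are broken
by ascending original feature index so a ranking is always a deterministic
total order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from xgboost import XGBClassifier

from .data import LabeledDataset

#: Ensemble hyperparameters are unstated by the underlying protocol; they are
#: fixed here and echoed into every ranking's metadata.
DEFAULT_N_ESTIMATORS = 500
DEFAULT_MAX_DEPTH = 6
DEFAULT_LEARNING_RATE = 0.1


@dataclass
class ImportanceRanking:
    """Per-feature scores plus the induced total order over feature indices."""

    method: str
    scores: np.ndarray
    order: np.ndarray  # permutation of 0..D-1, descending score
    feature_names: list[str]
    trained_on: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.order = np.asarray(self.order, dtype=int)
        d = len(self.scores)
        if sorted(self.order.tolist()) != list(range(d)):
            raise ValueError("order must be a permutation of 0..D-1")
        ranked = self.scores[self.order]
        if np.any(np.diff(ranked) > 1e-12):
            raise ValueError("scores along order must be non-increasing")

    def top_names(self, k: int) -> list[str]:
        return [self.feature_names[i] for i in self.order[:k]]

    def write(self, path: Union[str, Path]) -> None:
        """Two-column text (feature name, score) in rank order."""
        with open(path, "w") as fh:
            for i in self.order:
                fh.write(f"{self.feature_names[i]}\t{self.scores[i]:.10g}\n")


def _order_from_scores(scores: np.ndarray) -> np.ndarray:
    # stable sort on descending score; ties fall back to ascending index
    return np.lexsort((np.arange(len(scores)), -scores))


def rank_features(
    data: LabeledDataset,
    method: str = "xgboost",
    seed: int = 0,
    n_estimators: int = DEFAULT_N_ESTIMATORS,
    importance_type: str = "total_gain",
) -> ImportanceRanking:
    """Fit the chosen ensemble and rank all features by importance.

    XGBoost importance defaults to total gain — the summed loss reduction
    over every split a feature participates in, the quantity split-based
    importance analyses rank by.  ``"weight"`` (split count) and ``"gain"``
    (per-split average, which over-rewards rare lucky splits on noise) are
    available by flag.  Deterministic given ``seed`` (single-threaded
    fits).  Requires at least two samples of each class and finite feature
    values.
    """
    data.require_both_classes()
    neg, pos = data.class_counts()
    if min(neg, pos) < 2:
        raise ValueError("need at least 2 samples of each class to rank features")
    X = data.X.to_numpy()
    y = data.y

    if method == "xgboost":
        model = XGBClassifier(
            n_estimators=n_estimators,
            max_depth=DEFAULT_MAX_DEPTH,
            learning_rate=DEFAULT_LEARNING_RATE,
            tree_method="hist",
            random_state=seed,
            n_jobs=1,
            importance_type=importance_type,
        )
        model.fit(X, y)
        scores = np.asarray(model.feature_importances_, dtype=float)
        params = {
            "n_estimators": n_estimators,
            "max_depth": DEFAULT_MAX_DEPTH,
            "learning_rate": DEFAULT_LEARNING_RATE,
            "importance_type": importance_type,
            "seed": seed,
        }
    elif method == "random_forest":
        model = RandomForestClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1
        )
        model.fit(X, y)
        scores = np.asarray(model.feature_importances_, dtype=float)
        params = {"n_estimators": n_estimators, "seed": seed}
    else:
        raise ValueError(f"unknown ranking method {method!r}")

    return ImportanceRanking(
        method=method,
        scores=scores,
        order=_order_from_scores(scores),
        feature_names=data.feature_names,
        trained_on=data.provenance.get("source", "") or f"n={data.n_samples}",
        params=params,
    )


def select_top_k(
    ranking: ImportanceRanking, features: pd.DataFrame, k: int
) -> pd.DataFrame:
    """Retain the K best-ranked columns, samples and values untouched."""
    d = len(ranking.feature_names)
    if not 1 <= k <= d:
        raise ValueError(f"K must lie in 1..{d}, got {k}")
    names = ranking.top_names(k)
    missing = [n for n in names if n not in features.columns]
    if missing:
        raise KeyError(f"feature table lacks ranked columns: {missing[:5]}")
    return features.loc[:, names]


def k_sweep(
    data: LabeledDataset,
    ranking: ImportanceRanking,
    grid: Sequence[int],
    evaluator: Callable[[LabeledDataset], dict],
) -> pd.DataFrame:
    """Evaluate the top-K subset for every K in ``grid``.

    ``evaluator`` maps a reduced dataset to a flat dict of metrics (e.g. a
    cross-validation protocol); the result has one row per K.  The default
    experiment grid is K = 10, 20, ..., 650.
    """
    rows = []
    for k in grid:
        reduced = LabeledDataset(
            X=select_top_k(ranking, data.X, int(k)),
            y=data.y,
            provenance=dict(data.provenance),
        )
        metrics = evaluator(reduced)
        rows.append({"K": int(k), **metrics})
    return pd.DataFrame(rows)


def default_k_grid(d: int | None = None) -> list[int]:
    """K = 10, 20, ..., 650, truncated to the table dimension if given."""
    grid = list(range(10, 651, 10))
    if d is not None:
        grid = [k for k in grid if k <= d]
    return grid
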