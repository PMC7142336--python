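"""Evaluation protocols and metrics for the binary DNA-binding predictor.

Three protocols: stratified 10-fold cross-validation, jackknife (leave-one-
out) cross-validation, and an independent train/test split.  Cross-validated
metrics are computed from *pooled* held-out predictions — every sample is
scored exactly once by a model that never saw it, and one confusion table is
built from the pool (pooling is what makes a jackknife MCC/AUC meaningful;
per-fold averaging would leave single-sample folds undefined).

Metrics: sensitivity SN = TP/(TP+FN), specificity SP = TN/(TN+FP), accuracy
ACC = (TP+TN)/N, Matthews correlation coefficient
MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN)) with the 0/0
case defined as 0, and AUC.  AUC is computed as the Mann-Whitney pair
statistic (ties count 1/2), which a test cross-checks against the
trapezoidal area under the ROC curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve as _sk_roc_curve

from .classify import SvmConfig, grid_search_svm, stratified_folds, train
from .data import LabeledDataset
from .selection import rank_features

PROTOCOLS = ("tenfold", "jackknife", "independent")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(
        cls, y_true: np.ndarray, y_pred: np.ndarray
    ) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        if y_true.shape != y_pred.shape:
            raise ValueError("y_true and y_pred must have the same length")
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """SN, SP, ACC and MCC from a confusion table.

    Degenerate ratios (empty class, zero MCC denominator) are defined as 0,
    except ACC which always has the full sample count as denominator.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics on zero samples")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / counts.total
    denom = math.sqrt(
        float(tp + fn) * float(tp + fp) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return {"sn": sn, "sp": sp, "acc": acc, "mcc": mcc}


def compute_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 * P(tie)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes to be present")
    ranks = rankdata(scores)  # mid-ranks handle ties as 1/2
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(FPR, TPR) pairs of the threshold sweep, from (0,0) to (1,1)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes to be present")
    fpr, tpr, _ = _sk_roc_curve(labels, np.asarray(scores, dtype=float))
    return np.column_stack([fpr, tpr])


def trapezoid_auc(roc: np.ndarray) -> float:
    """Area under an ROC polyline — the geometric counterpart of
    :func:`compute_auc`."""
    return float(np.trapezoid(roc[:, 1], roc[:, 0]))


@dataclass(frozen=True)
class MetricsReport:
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float
    counts: ConfusionCounts
    protocol: str

    def as_dict(self) -> dict:
        return {
            "protocol": self.protocol,
            "sn": self.sn,
            "sp": self.sp,
            "acc": self.acc,
            "mcc": self.mcc,
            "auc": self.auc,
            "tp": self.counts.tp,
            "fp": self.counts.fp,
            "tn": self.counts.tn,
            "fn": self.counts.fn,
        }

    def __str__(self) -> str:
        c = self.counts
        return (
            f"[{self.protocol}] ACC={self.acc:.4f} SN={self.sn:.4f} "
            f"SP={self.sp:.4f} MCC={self.mcc:.4f} AUC={self.auc:.4f} "
            f"(TP={c.tp} FP={c.fp} TN={c.tn} FN={c.fn})"
        )


def report_from_scores(
    y_true: np.ndarray,
    scores: np.ndarray,
    y_pred: np.ndarray,
    protocol: str,
) -> tuple[MetricsReport, np.ndarray]:
    counts = ConfusionCounts.from_predictions(y_true, y_pred)
    m = compute_metrics(counts)
    auc = compute_auc(scores, y_true)
    roc = roc_points(scores, y_true)
    return (
        MetricsReport(counts=counts, auc=auc, protocol=protocol, **m),
        roc,
    )


@dataclass(frozen=True)
class EvalSettings:
    """Pipeline settings shared by all protocols.

    ``select_method``/``select_k`` turn on importance-based selection.
    ``rank_scope`` chooses where the ranking is fitted: ``"full"`` ranks
    once on the entire dataset before the folds (the historical protocol for
    this kind of predictor, which leaks label information into fold test
    sets) and ``"fold"`` re-ranks inside each training fold (leakage-safe;
    recommended).  ``grid_search`` tunes (C, gamma) — on the full data once
    under ``"full"`` scope, inside each training fold under ``"fold"``.
    """

    classifier: str = "svm"
    C: float = 1.0
    gamma: float | str = "scale"
    n_trees: int = 500
    standardize: bool = True
    select_method: str | None = None
    select_k: int | None = None
    rank_scope: str = "full"
    grid_search: bool = False
    grid_lo_exp: int = -10
    grid_hi_exp: int = 10
    grid_step: int = 1
    grid_folds: int = 10

    def __post_init__(self) -> None:
        if self.rank_scope not in ("full", "fold"):
            raise ValueError("rank_scope must be 'full' or 'fold'")
        if (self.select_method is None) != (self.select_k is None):
            raise ValueError("select_method and select_k must be set together")


def _svm_params(ds: LabeledDataset, settings: EvalSettings, seed: int):
    if not settings.grid_search or settings.classifier != "svm":
        return settings.C, settings.gamma
    gs = grid_search_svm(
        ds,
        SvmConfig(
            grid_lo_exp=settings.grid_lo_exp, grid_hi_exp=settings.grid_hi_exp
        ),
        folds=settings.grid_folds,
        seed=seed,
        standardize=settings.standardize,
        exp_step=settings.grid_step,
    )
    return gs.C, gs.gamma


def _fit(ds: LabeledDataset, settings: EvalSettings, C: float, gamma: float, seed: int):
    return train(
        ds,
        kind=settings.classifier,
        C=C,
        gamma=gamma,
        n_trees=settings.n_trees,
        seed=seed,
        standardize=settings.standardize,
    )


def evaluate_cv(
    data: LabeledDataset,
    protocol: str = "tenfold",
    settings: EvalSettings | None = None,
    seed: int = 0,
) -> tuple[MetricsReport, np.ndarray]:
    """Cross-validated evaluation with pooled held-out predictions.

    ``tenfold`` uses shuffled stratified 10-fold splits seeded by ``seed``;
    ``jackknife`` is leave-one-out (n models, each tested on one sample).
    Returns the pooled metrics report and ROC points.
    """
    settings = settings or EvalSettings()
    data.require_both_classes()
    n = data.n_samples

    working = data
    if settings.select_k is not None and settings.rank_scope == "full":
        ranking = rank_features(data, settings.select_method, seed=seed)
        working = data.with_features(ranking.top_names(settings.select_k))

    C = gamma = None
    if settings.rank_scope == "full":
        C, gamma = _svm_params(working, settings, seed)

    if protocol == "tenfold":
        if n < 10:
            raise ValueError(f"10-fold CV requires at least 10 samples, got {n}")
        splits = stratified_folds(data.y, 10, seed)
    elif protocol == "jackknife":
        if n < 2:
            raise ValueError("jackknife requires at least 2 samples")
        splits = [
            (np.delete(np.arange(n), i), np.array([i])) for i in range(n)
        ]
    else:
        raise ValueError(f"unknown CV protocol {protocol!r}")

    scores = np.full(n, np.nan)
    preds = np.full(n, -1)
    for tr_idx, te_idx in splits:
        tr = working.subset(tr_idx)
        te_X = working.X.iloc[te_idx]
        if settings.rank_scope == "fold":
            if settings.select_k is not None:
                fold_rank = rank_features(
                    data.subset(tr_idx), settings.select_method, seed=seed
                )
                names = fold_rank.top_names(settings.select_k)
                tr = data.subset(tr_idx).with_features(names)
                te_X = data.X.iloc[te_idx].loc[:, names]
            C, gamma = _svm_params(tr, settings, seed)
        model = _fit(tr, settings, C, gamma, seed)
        s, p = model.predict_scores(te_X)
        scores[te_idx] = s
        preds[te_idx] = p

    assert not np.isnan(scores).any() and (preds >= 0).all()
    return report_from_scores(data.y, scores, preds, protocol)


def evaluate_independent(
    train_data: LabeledDataset,
    test_data: LabeledDataset,
    settings: EvalSettings | None = None,
    seed: int = 0,
    strict: bool = False,
) -> tuple[MetricsReport, np.ndarray]:
    """Train once on ``train_data``, evaluate once on disjoint ``test_data``.

    Ranking and grid search use the training set only.  Overlapping sample
    ids produce a warning (an error in strict mode).
    """
    import warnings

    settings = settings or EvalSettings()
    train_data.require_both_classes()
    overlap = set(train_data.ids) & set(test_data.ids)
    if overlap:
        msg = f"{len(overlap)} sample ids occur in both train and test"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)

    working_train = train_data
    test_X = test_data.X
    if settings.select_k is not None:
        ranking = rank_features(train_data, settings.select_method, seed=seed)
        names = ranking.top_names(settings.select_k)
        working_train = train_data.with_features(names)
        test_X = test_data.X.loc[:, names]

    C, gamma = _svm_params(working_train, settings, seed)
    model = _fit(working_train, settings, C, gamma, seed)
    scores, preds = model.predict_scores(test_X)
    return report_from_scores(test_data.y, scores, preds, "independent")


def write_report(
    report: MetricsReport, roc: np.ndarray, out_dir: Union[str, Path]
) -> None:
    """Serialize a report as text + single-record TSV, and ROC as TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "metrics.txt").write_text(str(report) + "\n")
    pd.DataFrame([report.as_dict()]).to_csv(
        out / "metrics.tsv", sep="\t", index=False
    )
    pd.DataFrame(roc, columns=["fpr", "tpr"]).to_csv(
        out / "roc.tsv", sep="\t", index=False
    )


def plot_roc(
    curves: dict[str, np.ndarray], path: Union[str, Path], title: str = "ROC"
) -> None:
    """Emit an ROC figure for one or more labelled curves (requires
    matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for label, roc in curves.items():
        ax.plot(roc[:, 0], roc[:, 1], label=f"{label} (AUC={trapezoid_auc(roc):.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(title)
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
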