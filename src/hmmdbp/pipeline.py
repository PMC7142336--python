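"""End-to-end runs and the experiment sweeps behind the benchmark figures.

``run_pipeline`` chains featurize -> rank + top-K select -> grid-search SVM
-> train -> evaluate and writes every artifact (feature table, ranking,
model, metrics, ROC, config echo) into one output directory, so a run is
reproducible from its directory alone.  The sweep runners re-execute the
pipeline across a grid: maximum lag G (feature-dimension trade-off),
top-K (selection depth), and classifier x feature-family comparisons.

All randomness flows from a single top-level seed; derived stages (fold
splitting, ensembles, the synthetic generator) reuse it directly, which the
config echo records.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence, Union

import pandas as pd
import yaml

from . import __version__
from .data import LabeledDataset
from .evaluate import (
    EvalSettings,
    MetricsReport,
    evaluate_cv,
    evaluate_independent,
    write_report,
)
from .features import FeatureSpec, featurize_profiles, featurize_dir
from .profile_io import HmmProfile, read_profile_dir
from .selection import default_k_grid, k_sweep, rank_features

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; echoed verbatim into the output."""

    profile_dir: str | None = None
    label_file: str | None = None
    test_profile_dir: str | None = None
    test_label_file: str | None = None
    max_lag: int = 5
    include_aac: bool = True
    include_act: bool = True
    include_cct: bool = True
    select_method: str | None = "xgboost"
    select_k: int | None = 270
    rank_scope: str = "full"
    classifier: str = "svm"
    grid_search: bool = True
    grid_lo_exp: int = -10
    grid_hi_exp: int = 10
    grid_step: int = 1
    grid_folds: int = 10
    standardize: bool = True
    protocol: str = "tenfold"
    seed: int = 0
    out_dir: str = "hmmdbp_run"

    def feature_spec(self) -> FeatureSpec:
        return FeatureSpec(
            max_lag=self.max_lag,
            include_aac=self.include_aac,
            include_act=self.include_act,
            include_cct=self.include_cct,
        )

    def eval_settings(self) -> EvalSettings:
        return EvalSettings(
            classifier=self.classifier,
            select_method=self.select_method,
            select_k=self.select_k,
            rank_scope=self.rank_scope,
            grid_search=self.grid_search,
            grid_lo_exp=self.grid_lo_exp,
            grid_hi_exp=self.grid_hi_exp,
            grid_step=self.grid_step,
            grid_folds=self.grid_folds,
            standardize=self.standardize,
        )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(payload) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def echo(self, out_dir: Path) -> None:
        payload = asdict(self)
        payload["artifact_version"] = __version__
        (out_dir / "config.yaml").write_text(yaml.safe_dump(payload, sort_keys=True))


class StageError(RuntimeError):
    """Wraps a failure with the pipeline stage where it occurred."""

    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"stage '{stage}' failed: {exc}")
        self.stage = stage


def _load_dataset(config: RunConfig) -> LabeledDataset:
    if config.profile_dir is None or config.label_file is None:
        raise ValueError("config must point at a profile_dir and label_file")
    return featurize_dir(config.profile_dir, config.label_file, config.feature_spec())


def run_pipeline(
    config: RunConfig, data: LabeledDataset | None = None
) -> MetricsReport:
    """Execute one full run and write its artifacts to ``config.out_dir``.

    ``data`` may be supplied directly (e.g. an in-memory synthetic dataset)
    to skip the featurize-from-disk stage.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    if data is None:
        try:
            data = _load_dataset(config)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise StageError("featurize", exc) from exc
    logger.info(
        "featurize: %d samples x %d features (%.1fs)",
        data.n_samples, data.n_features, time.perf_counter() - t0,
    )
    data.write_table(out / "features.tsv")

    if config.select_k is not None:
        try:
            ranking = rank_features(data, config.select_method, seed=config.seed)
            ranking.write(out / "ranking.tsv")
        except Exception as exc:
            raise StageError("rank", exc) from exc
        if config.select_k > data.n_features:
            raise StageError(
                "select",
                ValueError(
                    f"K={config.select_k} exceeds feature dimension "
                    f"{data.n_features}"
                ),
            )

    settings = config.eval_settings()
    try:
        if config.protocol == "independent":
            if config.test_profile_dir is None or config.test_label_file is None:
                raise ValueError("independent protocol needs test_profile_dir/"
                                 "test_label_file")
            test = featurize_dir(
                config.test_profile_dir,
                config.test_label_file,
                config.feature_spec(),
            )
            report, roc = evaluate_independent(data, test, settings, config.seed)
        else:
            report, roc = evaluate_cv(data, config.protocol, settings, config.seed)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("evaluate", exc) from exc

    write_report(report, roc, out)
    config.echo(out)
    logger.info("pipeline done in %.1fs: %s", time.perf_counter() - t0, report)
    return report


def run_k_sweep(
    config: RunConfig,
    data: LabeledDataset | None = None,
    grid: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Accuracy-vs-K table: rank once, evaluate the top-K subset per K."""
    data = data if data is not None else _load_dataset(config)
    grid = list(grid) if grid is not None else default_k_grid(data.n_features)
    ranking = rank_features(data, config.select_method or "xgboost", seed=config.seed)
    settings = replace(config.eval_settings(), select_method=None, select_k=None)

    def evaluator(reduced: LabeledDataset) -> dict:
        report, _ = evaluate_cv(reduced, config.protocol, settings, config.seed)
        return {
            "acc": report.acc, "sn": report.sn, "sp": report.sp,
            "mcc": report.mcc, "auc": report.auc,
        }

    table = k_sweep(data, ranking, grid, evaluator)
    table.insert(1, "method", ranking.method)
    _maybe_write(config, table, "k_sweep.tsv")
    return table


def run_g_sweep(
    config: RunConfig,
    profiles: Sequence[HmmProfile] | None = None,
    labels: dict[str, int] | None = None,
    g_values: Sequence[int] = tuple(range(1, 11)),
    classifiers: Sequence[str] = ("svm", "random_forest"),
) -> pd.DataFrame:
    """Re-featurize per maximum lag G and evaluate each classifier.

    One row per (G, classifier) with the feature dimension 20 + 400*G and
    the configured protocol's accuracy — the table behind the lag-choice
    figure.  No selection is applied: the sweep probes the raw descriptor.
    """
    if profiles is None:
        if config.profile_dir is None or config.label_file is None:
            raise ValueError("config must point at a profile_dir and label_file")
        profiles, labels = read_profile_dir(config.profile_dir, config.label_file)
    assert labels is not None
    min_len = min(p.length for p in profiles)
    if max(g_values) >= min_len:
        raise ValueError(
            f"max lag {max(g_values)} must be below the minimum sequence "
            f"length {min_len}"
        )
    settings = replace(
        config.eval_settings(), select_method=None, select_k=None
    )
    rows = []
    for g in g_values:
        fspec = FeatureSpec(max_lag=int(g))
        ds = featurize_profiles(profiles, labels, fspec)
        for clf in classifiers:
            report, _ = evaluate_cv(
                ds, config.protocol, replace(settings, classifier=clf), config.seed
            )
            rows.append(
                {
                    "g": int(g),
                    "classifier": clf,
                    "protocol": config.protocol,
                    "n_features": fspec.n_features,
                    "acc": report.acc,
                }
            )
            logger.info("g-sweep g=%d %s: ACC=%.4f", g, clf, report.acc)
    table = pd.DataFrame(rows)
    _maybe_write(config, table, "g_sweep.tsv")
    return table


_FAMILY_SETTINGS = {
    "AAC": dict(include_aac=True, include_act=False, include_cct=False),
    "ACT": dict(include_aac=False, include_act=True, include_cct=False),
    "CCT": dict(include_aac=False, include_act=False, include_cct=True),
    "AAC+ACT+CCT": dict(include_aac=True, include_act=True, include_cct=True),
}


def run_feature_comparison(
    config: RunConfig,
    profiles: Sequence[HmmProfile] | None = None,
    labels: dict[str, int] | None = None,
    classifiers: Sequence[str] = ("svm", "random_forest"),
) -> pd.DataFrame:
    """Classifier x feature-family comparison: 2 x 4 = 8 rows per protocol."""
    if profiles is None:
        if config.profile_dir is None or config.label_file is None:
            raise ValueError("config must point at a profile_dir and label_file")
        profiles, labels = read_profile_dir(config.profile_dir, config.label_file)
    assert labels is not None
    settings = replace(config.eval_settings(), select_method=None, select_k=None)
    rows = []
    for family, flags in _FAMILY_SETTINGS.items():
        fspec = FeatureSpec(max_lag=config.max_lag, **flags)
        ds = featurize_profiles(profiles, labels, fspec)
        for clf in classifiers:
            report, _ = evaluate_cv(
                ds, config.protocol, replace(settings, classifier=clf), config.seed
            )
            rows.append(
                {
                    "classifier": clf,
                    "features": family,
                    "n_features": fspec.n_features,
                    "sn": report.sn,
                    "sp": report.sp,
                    "acc": report.acc,
                    "mcc": report.mcc,
                    "auc": report.auc,
                }
            )
    table = pd.DataFrame(rows)
    _maybe_write(config, table, "feature_comparison.tsv")
    return table


def _maybe_write(config: RunConfig, table: pd.DataFrame, name: str) -> None:
    out = Path(config.out_dir)
    if out != Path(""):
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / name, sep="\t", index=False)
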