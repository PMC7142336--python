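"""Labeled feature datasets and their on-disk tab-separated representation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Union

import numpy as np
import pandas as pd

LABEL_COLUMN = "label"
ID_COLUMN = "id"


@dataclass
class LabeledDataset:
    """N feature vectors with binary labels — the unit of training/evaluation.

    ``X`` is an N x D frame indexed by protein id with feature-name columns;
    ``y`` holds 0/1 labels aligned to ``X``'s rows.  ``provenance`` records
    how the table was produced (a synthetic spec, source paths, ...).
    """

    X: pd.DataFrame
    y: np.ndarray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        if len(self.X) != len(self.y):
            raise ValueError("X and y have different lengths")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("labels must be binary 0/1")
        if not np.isfinite(self.X.to_numpy()).all():
            raise ValueError("feature table contains missing or non-finite values")

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.X.index]

    @property
    def n_samples(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def class_counts(self) -> tuple[int, int]:
        """(negatives, positives)."""
        return int((self.y == 0).sum()), int((self.y == 1).sum())

    def require_both_classes(self) -> None:
        neg, pos = self.class_counts()
        if neg == 0 or pos == 0:
            raise ValueError(
                f"both classes required, got {pos} positives / {neg} negatives"
            )

    def subset(self, indices: np.ndarray) -> "LabeledDataset":
        """Row subset preserving order of ``indices``."""
        return LabeledDataset(
            X=self.X.iloc[indices], y=self.y[indices], provenance=dict(self.provenance)
        )

    def with_features(self, names: list[str]) -> "LabeledDataset":
        """Column subset in the given order; values are untouched."""
        return LabeledDataset(
            X=self.X.loc[:, names], y=self.y, provenance=dict(self.provenance)
        )

    def write_table(self, path: Union[str, Path]) -> None:
        """Write as TSV: first column id, feature columns, last column label."""
        out = self.X.copy()
        out.insert(len(out.columns), LABEL_COLUMN, self.y)
        out.to_csv(path, sep="\t", index=True, index_label=ID_COLUMN)

    @classmethod
    def read_table(cls, path: Union[str, Path]) -> "LabeledDataset":
        df = pd.read_csv(path, sep="\t", index_col=ID_COLUMN)
        if LABEL_COLUMN not in df.columns:
            raise ValueError(f"feature table lacks a '{LABEL_COLUMN}' column")
        y = df.pop(LABEL_COLUMN).to_numpy()
        return cls(X=df, y=y, provenance={"source": str(path)})
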