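"""Subjects x features table with a binary group label.

The carrier between feature engineering and the two selection
frameworks. Missing values (features undefined for a subject, e.g. no
valid large peak on any night) are kept as NaN here; columns missing in
more than a configurable fraction of subjects are dropped and the rest
median-imputed within group before model training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["FeatureTable"]


@dataclass
class FeatureTable:
    X: pd.DataFrame          # index: subject ids, columns: feature names
    y: pd.Series             # 0 = control, 1 = case, aligned with X

    def __post_init__(self) -> None:
        self.y = pd.Series(self.y, index=self.X.index).astype(int)
        if not set(self.y.unique()) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        counts = self.y.value_counts()
        if len(counts) == 2 and counts.min() / counts.max() < 0.5:
            log.warning("labels are unbalanced: %s", counts.to_dict())

    @property
    def n_subjects(self) -> int:
        return len(self.X)

    def feature_names(self) -> list[str]:
        return list(self.X.columns)

    def drop_sparse(self, missing_max: float = 0.2) -> "FeatureTable":
        """Drop columns missing in more than ``missing_max`` of subjects."""
        keep = self.X.columns[self.X.isna().mean() <= missing_max]
        dropped = sorted(set(self.X.columns) - set(keep))
        if dropped:
            log.info("dropping %d sparse features: %s", len(dropped), dropped)
        return FeatureTable(self.X[keep].copy(), self.y)

    def impute_within_group(self) -> "FeatureTable":
        """Median-impute each column within its label group (falls back
        to the overall median when a whole group is missing)."""
        X = self.X.copy()
        for label in (0, 1):
            rows = self.y == label
            med = X.loc[rows].median()
            X.loc[rows] = X.loc[rows].fillna(med)
        X = X.fillna(X.median())
        return FeatureTable(X, self.y)

    def to_csv(self, features_path, labels_path) -> None:
        self.X.rename_axis("subject_id").to_csv(features_path)
        self.y.rename("label").rename_axis("subject_id").to_csv(labels_path)

    @classmethod
    def from_csv(cls, features_path, labels_path) -> "FeatureTable":
        X = pd.read_csv(features_path, index_col="subject_id")
        y = pd.read_csv(labels_path, index_col="subject_id")["label"]
        return cls(X, y.loc[X.index])
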