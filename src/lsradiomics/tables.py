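"""Sample x feature tables with binary class labels.

Labels follow the clinical coding used throughout the pipeline: 1 = good
prognosis, 2 = poor prognosis.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError

VALID_LABELS = (1, 2)


@dataclass
class FeatureTable:
    """A samples x features matrix plus per-sample binary labels."""

    features: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.features):
            raise ConfigurationError("labels length must match number of samples")
        if self.features.isna().any().any():
            raise ConfigurationError("feature table contains missing values")
        present = np.unique(self.labels)
        if not np.all(np.isin(present, VALID_LABELS)):
            raise ConfigurationError(f"labels must be in {VALID_LABELS}, got {present}")
        for lab in present:
            if (self.labels == lab).sum() < 2:
                raise ConfigurationError(f"need >= 2 samples in class {lab}")

    @property
    def n_samples(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    def matrix(self) -> np.ndarray:
        return self.features.to_numpy(dtype=np.float64)

    def select(self, names: list[str]) -> "FeatureTable":
        return FeatureTable(self.features[names].copy(), self.labels.copy())

    def to_csv(self, path: str | Path) -> None:
        out = self.features.copy()
        out["label"] = self.labels
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ConfigurationError(f"{path}: missing required 'label' column")
        labels = df.pop("label").to_numpy(dtype=int)
        return cls(df, labels)
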