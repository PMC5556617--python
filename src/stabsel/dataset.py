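"""The labeled feature matrix consumed by filters and classifiers."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import FormatError, ShapeError, SingleClassError

__all__ = ["LabeledDataset"]


@dataclass
class LabeledDataset:
    """An n x p metric feature matrix with a binary class label.

    ``X`` keeps named columns (a DataFrame); ``y`` holds the original
    labels.  ``classes`` orders the two labels; internally class
    ``classes[1]`` is the positive class.  ``truth`` optionally records
    generator ground truth (informative feature indices, blocks) for
    synthetic data.
    """

    X: pd.DataFrame
    y: np.ndarray
    provenance: str = ""
    truth: Optional[dict] = None
    classes: np.ndarray = field(init=False)

    def __post_init__(self):
        if not isinstance(self.X, pd.DataFrame):
            self.X = pd.DataFrame(np.asarray(self.X, dtype=np.float64))
            self.X.columns = [f"X{j + 1}" for j in range(self.X.shape[1])]
        self.y = np.asarray(self.y)
        if self.X.shape[0] != self.y.shape[0]:
            raise ShapeError(
                f"{self.X.shape[0]} rows but {self.y.shape[0]} labels"
            )
        if self.X.columns.duplicated().any():
            dup = self.X.columns[self.X.columns.duplicated()].tolist()
            raise FormatError(f"duplicate feature names: {dup}")
        values = self.X.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("all feature columns must be numeric")
        if np.isnan(values.astype(np.float64)).any():
            rows, cols = np.nonzero(np.isnan(values.astype(np.float64)))
            raise FormatError(
                f"missing value at row {rows[0]}, column "
                f"{self.X.columns[cols[0]]!r}"
            )
        self.classes = np.unique(self.y)
        if self.classes.shape[0] < 2:
            raise SingleClassError("label column contains a single class")
        if self.classes.shape[0] > 2:
            raise ShapeError(
                f"expected 2 classes, found {self.classes.shape[0]}"
            )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def feature_names(self) -> list:
        return list(self.X.columns)

    def binary_labels(self) -> np.ndarray:
        """Labels as 0/1, with ``classes[1]`` mapped to 1."""
        return (self.y == self.classes[1]).astype(np.int64)

    def matrix(self) -> np.ndarray:
        return self.X.to_numpy(dtype=np.float64)
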