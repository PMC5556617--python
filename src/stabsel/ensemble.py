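"""Selection ensembles and feature correlation matrices.

A *selection ensemble* is the collection of feature sets ``V_1, ..., V_m``
obtained by running a feature-selection method on ``m`` resampled versions
of a data set with ``p`` candidate features.  All stability measures operate
on this object.  Feature indices are 0-based internally; I/O layers map
named or 1-based features onto indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ShapeError, UndefinedCorrelationError

__all__ = ["SelectionEnsemble", "FeatureCorrelationMatrix"]


@dataclass(frozen=True)
class SelectionEnsemble:
    """Feature sets ``V_1..V_m`` selected over ``m`` resampling iterations.

    Parameters
    ----------
    p : int
        Total number of candidate features.
    sets : tuple of frozenset of int
        The ``m`` selected feature index sets, each a subset of ``{0..p-1}``.
        Empty sets are representable; individual stability measures reject
        them where their definitions require nonempty sets.
    """

    p: int
    sets: tuple = field(default=())

    def __post_init__(self):
        sets = tuple(frozenset(int(j) for j in s) for s in self.sets)
        object.__setattr__(self, "sets", sets)
        if self.p < 1:
            raise ShapeError(f"p must be positive, got {self.p}")
        if len(sets) < 2:
            raise ShapeError(f"need at least 2 selected sets, got {len(sets)}")
        for i, s in enumerate(sets):
            for j in s:
                if not 0 <= j < self.p:
                    raise ShapeError(
                        f"set {i} contains feature index {j} outside [0, {self.p})"
                    )

    @classmethod
    def from_sets(cls, sets: Iterable[Iterable[int]], p: int) -> "SelectionEnsemble":
        return cls(p=p, sets=tuple(sets))

    @classmethod
    def from_indicator_matrix(cls, Z: np.ndarray) -> "SelectionEnsemble":
        """Build from an ``m x p`` binary indicator matrix."""
        Z = np.asarray(Z)
        if Z.ndim != 2:
            raise ShapeError("indicator matrix must be 2-dimensional")
        sets = tuple(frozenset(np.flatnonzero(row).tolist()) for row in Z)
        return cls(p=Z.shape[1], sets=sets)

    @property
    def m(self) -> int:
        """Number of selected sets."""
        return len(self.sets)

    @property
    def sizes(self) -> np.ndarray:
        """Cardinalities ``|V_1|, ..., |V_m|``."""
        return np.array([len(s) for s in self.sets], dtype=np.int64)

    @property
    def counts(self) -> np.ndarray:
        """Selection frequencies ``h_j``: number of sets containing feature j."""
        h = np.zeros(self.p, dtype=np.int64)
        for s in self.sets:
            for j in s:
                h[j] += 1
        return h

    @property
    def q(self) -> int:
        """Total number of selections, ``q = sum_j h_j = sum_i |V_i|``."""
        return int(self.sizes.sum())

    @property
    def union(self) -> frozenset:
        """Union ``V`` of all selected sets."""
        return frozenset().union(*self.sets)

    def indicator_matrix(self) -> np.ndarray:
        """Binary ``m x p`` matrix with ``Z[i, j] = 1`` iff feature j is in V_i."""
        Z = np.zeros((self.m, self.p), dtype=np.float64)
        for i, s in enumerate(self.sets):
            if s:
                Z[i, sorted(s)] = 1.0
        return Z


class FeatureCorrelationMatrix:
    """Pairwise Pearson correlations between the ``p`` features of a data set.

    Correlations involving a constant (zero-variance) feature are undefined
    and stored as NaN; consumers must reject them explicitly rather than
    treat them as zero.
    """

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=np.float64)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ShapeError("correlation matrix must be square")
        finite = np.isfinite(values)
        if not np.allclose(values[finite], values.T[finite], atol=1e-10):
            raise ShapeError("correlation matrix must be symmetric")
        with np.errstate(invalid="ignore"):
            bad = finite & ((values < -1 - 1e-9) | (values > 1 + 1e-9))
        if bad.any():
            raise ShapeError("correlation entries must lie in [-1, 1]")
        self._values = values

    @classmethod
    def from_data(cls, X) -> "FeatureCorrelationMatrix":
        """Compute from an ``n x p`` feature matrix (rows = observations).

        Constant columns produce NaN rows/columns (undefined correlation),
        except for the diagonal which is set to 1 by convention.
        """
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ShapeError("need a 2-d matrix with at least 2 observations")
        with np.errstate(invalid="ignore", divide="ignore"):
            C = np.corrcoef(X, rowvar=False)
        C = np.atleast_2d(C)
        np.fill_diagonal(C, 1.0)
        return cls(C)

    @classmethod
    def identity(cls, p: int) -> "FeatureCorrelationMatrix":
        """All off-diagonal correlations zero (independent features)."""
        return cls(np.eye(p))

    @property
    def values(self) -> np.ndarray:
        return self._values

    @property
    def p(self) -> int:
        return self._values.shape[0]

    def __getitem__(self, key):
        return self._values[key]

    def require_defined(self, indices: Sequence[int]) -> None:
        """Raise if any correlation among ``indices`` is undefined (NaN)."""
        idx = np.fromiter(indices, dtype=np.int64)
        sub = self._values[np.ix_(idx, idx)]
        if np.isnan(sub).any():
            bad = sorted(set(idx[np.isnan(sub).any(axis=1)].tolist()))
            raise UndefinedCorrelationError(
                f"undefined correlations for constant features {bad}"
            )
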