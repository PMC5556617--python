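"""Univariate filter methods: variance, AUC and greedy MRMR.

Each filter assigns every feature a score; the highest-scoring features
are kept.  Ties are always broken by the lowest feature index, which
makes top-k selection deterministic — this matters because the selected
sets feed the stability measures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import rankdata

from .errors import (
    ShapeError,
    SingleClassError,
    UndefinedCorrelationError,
)

__all__ = [
    "FilterScores",
    "variance_filter",
    "auc_filter",
    "auc_scores",
    "mrmr_select",
    "mrmr_from_scores",
    "select_top_k",
    "select_above",
]


@dataclass(frozen=True)
class FilterScores:
    """Per-feature scores of a filter method.

    For MRMR, ``order`` is the greedy selection order and ``quotients``
    the relevance/redundancy quotient realized at each step; ``scores``
    then ranks features by selection step (earlier pick = higher score)
    so that generic top-k selection recovers the greedy prefix.
    """

    method: str
    scores: np.ndarray
    order: Optional[np.ndarray] = None
    quotients: Optional[np.ndarray] = None

    @property
    def p(self) -> int:
        return self.scores.shape[0]


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ShapeError("feature matrix must be 2-dimensional")
    return X


def _as_binary_labels(y) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.shape[0] < 2:
        raise SingleClassError("labels contain a single class")
    if classes.shape[0] > 2:
        raise ShapeError(f"expected binary labels, found {classes.shape[0]} classes")
    return (y == classes[1]).astype(np.int64)


def variance_filter(X) -> FilterScores:
    """Score each feature by its sample variance (n−1 denominator)."""
    X = _as_matrix(X)
    if X.shape[0] < 2:
        raise ShapeError("variance filter needs at least 2 observations")
    return FilterScores("variance", np.var(X, axis=0, ddof=1))


def auc_scores(X, y) -> np.ndarray:
    """Raw per-feature AUC of the single-feature threshold rule.

    Computed rank-based with midrank tie handling, i.e. the normalized
    Mann-Whitney U statistic of the positive against the negative class.
    """
    X = _as_matrix(X)
    y = _as_binary_labels(y)
    n1 = int(y.sum())
    n0 = y.shape[0] - n1
    ranks = rankdata(X, axis=0, method="average")
    r1 = ranks[y == 1].sum(axis=0)
    return (r1 - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def auc_filter(X, y) -> FilterScores:
    """Score each feature by |0.5 − AUC| of its single-feature rule.

    An AUC of 1 (all positive-class values above all negative ones) and
    an AUC of 0 (perfect anti-separation) both allow a perfectly accurate
    threshold rule, so both map to the maximal score 0.5; an AUC of 0.5
    is uninformative and scores 0.
    """
    return FilterScores("auc", np.abs(0.5 - auc_scores(X, y)))


def mrmr_from_scores(
    relevance: np.ndarray, abs_correlation: np.ndarray, k: int
) -> FilterScores:
    """Greedy maximum-relevance-minimum-redundancy selection.

    The first pick maximizes relevance.  Each later pick maximizes
    relevance / redundancy over the remaining candidates, where the
    redundancy of a candidate is the sum of ``abs_correlation`` between
    it and the already chosen features.  A candidate with redundancy
    exactly 0 has quotient +inf; such candidates are ranked among each
    other by relevance.  All ties break toward the lowest feature index.
    """
    relevance = np.asarray(relevance, dtype=np.float64)
    p = relevance.shape[0]
    if not 1 <= k <= p:
        raise ShapeError(f"k must be in [1, {p}], got {k}")
    A = np.asarray(abs_correlation, dtype=np.float64)
    if A.shape != (p, p):
        raise ShapeError("abs_correlation must be p x p")

    chosen: list[int] = []
    quotients: list[float] = []
    redundancy = np.zeros(p)
    remaining = np.ones(p, dtype=bool)
    for step in range(k):
        if step == 0:
            crit = relevance
        else:
            if np.isnan(redundancy[remaining]).any():
                bad = np.flatnonzero(remaining & np.isnan(redundancy))
                raise UndefinedCorrelationError(
                    f"constant candidate features {bad.tolist()} have undefined "
                    "correlation with the chosen set"
                )
            with np.errstate(divide="ignore"):
                crit = np.where(redundancy > 0, relevance / redundancy, np.inf)
        # rank by criterion, break inf-ties by relevance, then by index
        masked = np.where(remaining, crit, -np.inf)
        best = np.max(masked)
        cand = np.flatnonzero(masked == best)
        if len(cand) > 1 and np.isinf(best):
            cand = cand[relevance[cand] == relevance[cand].max()]
        pick = int(cand[0])
        chosen.append(pick)
        quotients.append(float(masked[pick]))
        remaining[pick] = False
        redundancy = redundancy + A[pick]
    order = np.array(chosen, dtype=np.int64)
    # step-rank scores: earlier picks score higher, unchosen features 0
    scores = np.zeros(p)
    scores[order] = np.arange(k, 0, -1, dtype=np.float64)
    return FilterScores(
        "mrmr", scores, order=order, quotients=np.array(quotients)
    )


def mrmr_select(X, y, k: int) -> FilterScores:
    """MRMR with AUC-filter relevance and absolute-Pearson redundancy."""
    X = _as_matrix(X)
    relevance = auc_filter(X, y).scores
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.atleast_2d(C)
    np.fill_diagonal(C, 1.0)
    return mrmr_from_scores(relevance, np.abs(C), k)


def select_top_k(scores: FilterScores, k: int) -> np.ndarray:
    """Indices of the k highest-scoring features, ties to the lowest index.

    The result is sorted ascending; nested: the top-k1 set is contained
    in the top-k2 set whenever k1 <= k2.
    """
    p = scores.p
    if not 1 <= k <= p:
        raise ShapeError(f"k must be in [1, {p}], got {k}")
    order = np.lexsort((np.arange(p), -scores.scores))
    return np.sort(order[:k])


def select_above(scores: FilterScores, threshold: float) -> np.ndarray:
    """Indices of all features with score strictly above ``threshold``."""
    return np.flatnonzero(scores.scores > threshold)
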