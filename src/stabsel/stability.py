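"""Stability measures for feature selection.

Given the feature sets ``V_1..V_m`` selected on ``m`` resampled versions of
a data set with ``p`` features, each measure returns a single number
quantifying how reproducible the selection is; higher values mean more
stable selection.

Two families are implemented.  *Pairwise* measures average a similarity
score over all ``m(m-1)/2`` unordered pairs of sets: Jaccard (SJ),
Dice (SD), Ochiai (SO), a correlation-adjusted Jaccard in which different
but highly correlated features still count as agreement (SZ), the
chance-corrected index of Lustgarten et al. (SL) and the Pearson
correlation of the binary indicator vectors (SC, the phi coefficient).
*Frequency* measures work with the selection counts ``h_j``: the
entropy-based consistency index (SN), the frequency measure of Davis et
al. with sparsity penalty ``alpha`` (SD-alpha) and the relative weighted
consistency (SS).

SL, SS and SC are corrected for chance: their expected value under purely
random selection of ``k``-subsets does not grow with ``k``.  The corrected
measures are undefined for degenerate ensembles (e.g. all features
selected); such cases raise typed errors which :func:`all_stabilities`
converts into explicit *undefined* results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .ensemble import FeatureCorrelationMatrix, SelectionEnsemble
from .errors import (
    DegenerateSelectionError,
    EmptySetError,
    ShapeError,
    StabselError,
)

__all__ = [
    "StabilityScore",
    "PAIRWISE_MEASURES",
    "MEASURES",
    "jaccard_stability",
    "dice_stability",
    "ochiai_stability",
    "zucknick_stability",
    "lustgarten_stability",
    "novovicova_stability",
    "davis_stability",
    "somol_stability",
    "correlation_stability",
    "all_stabilities",
    "pairwise_scores",
    "measure_range",
]

PAIRWISE_MEASURES = ("SJ", "SD", "SO", "SZ", "SL", "SC")
#: Canonical measure identifiers.  ``SD-alpha`` instances are keyed
#: ``"SD-0"``, ``"SD-1"`` etc. by :func:`all_stabilities`.
MEASURES = ("SJ", "SD", "SO", "SZ", "SL", "SN", "SD-alpha", "SS", "SC")


@dataclass(frozen=True)
class StabilityScore:
    """A stability value together with its theoretical range.

    ``value`` is ``None`` when the measure is undefined for the ensemble
    (degenerate selection); ``reason`` then explains why.
    """

    measure: str
    value: Optional[float]
    range: tuple
    alpha: Optional[float] = None
    reason: Optional[str] = None

    @property
    def defined(self) -> bool:
        return self.value is not None

    def __float__(self) -> float:
        if self.value is None:
            raise ValueError(f"{self.measure} is undefined: {self.reason}")
        return float(self.value)


def measure_range(measure: str, m: int, p: int, alpha: float = 0.0) -> tuple:
    """Theoretical [lo, hi] range of a measure for given ensemble shape."""
    if measure in ("SL", "SC"):
        return (-1.0, 1.0)
    if measure in ("SD-alpha", "SD-a") or measure.startswith("SD-"):
        if measure not in ("SD", "SD-alpha", "SD-a"):
            alpha = float(measure[3:])
        hi = max(1.0 - alpha / p, 1.0 / (m * (m - 1) / 2.0))
        return (0.0, hi)
    return (0.0, 1.0)


# ---------------------------------------------------------------------------
# pairwise scores


def _require_nonempty(ens: SelectionEnsemble) -> None:
    if any(len(s) == 0 for s in ens.sets):
        raise EmptySetError("pairwise stability measures require nonempty sets")


def _pairs(m: int):
    for i in range(m - 1):
        for j in range(i + 1, m):
            yield i, j


def _pair_jaccard(a: frozenset, b: frozenset) -> float:
    return len(a & b) / len(a | b)


def _pair_dice(a: frozenset, b: frozenset) -> float:
    return 2.0 * len(a & b) / (len(a) + len(b))


def _pair_ochiai(a: frozenset, b: frozenset) -> float:
    return len(a & b) / math.sqrt(len(a) * len(b))


def _pair_lustgarten(a: frozenset, b: frozenset, p: int) -> float:
    den = min(len(a), len(b)) - max(0, len(a) + len(b) - p)
    if den == 0:
        raise DegenerateSelectionError(
            "Lustgarten pair denominator is 0 (e.g. all features selected)"
        )
    return (len(a & b) - len(a) * len(b) / p) / den


def _pair_phi(a: frozenset, b: frozenset, p: int) -> float:
    na, nb = len(a), len(b)
    if na in (0, p) or nb in (0, p):
        raise DegenerateSelectionError(
            "phi coefficient undefined for constant indicator vectors "
            "(empty or full selection)"
        )
    n11 = len(a & b)
    num = p * n11 - na * nb
    den = math.sqrt(na * (p - na) * nb * (p - nb))
    return num / den


def _pair_zucknick(
    a: frozenset, b: frozenset, cor: FeatureCorrelationMatrix, strict: bool = True
) -> float:
    union = sorted(a | b)
    inter = len(a & b)
    u = len(union)
    if u < 2:
        return inter / u
    idx = np.array(union, dtype=np.int64)
    sub = cor.values[np.ix_(idx, idx)]
    iu = np.triu_indices(u, k=1)
    r = float(np.median(sub[iu]))

    def adjust(src: frozenset, other: frozenset) -> float:
        extra = sorted(other - src)
        if not extra or not src:
            return 0.0
        rows = np.array(sorted(src), dtype=np.int64)
        cols = np.array(extra, dtype=np.int64)
        C = cor.values[np.ix_(rows, cols)]
        mask = C > r if strict else C >= r
        return float(C[mask].sum()) / len(other)

    c_ab = adjust(a, b)
    d_ab = adjust(b, a)
    return (inter + c_ab + d_ab) / u


def pairwise_scores(
    ens: SelectionEnsemble,
    measure: str,
    cor: Optional[FeatureCorrelationMatrix] = None,
) -> np.ndarray:
    """The m(m-1)/2 pairwise similarity scores of a pairwise measure.

    Pairs are ordered ``(1,2), (1,3), ..., (m-1,m)``.  The corresponding
    stability value is the arithmetic mean of this array.
    """
    _require_nonempty(ens)
    sets, p = ens.sets, ens.p
    if measure == "SJ":
        f = lambda a, b: _pair_jaccard(a, b)
    elif measure == "SD":
        f = lambda a, b: _pair_dice(a, b)
    elif measure == "SO":
        f = lambda a, b: _pair_ochiai(a, b)
    elif measure == "SL":
        f = lambda a, b: _pair_lustgarten(a, b, p)
    elif measure == "SC":
        f = lambda a, b: _pair_phi(a, b, p)
    elif measure == "SZ":
        if cor is None:
            raise ShapeError("SZ requires a feature correlation matrix")
        if cor.p != p:
            raise ShapeError(
                f"correlation matrix is {cor.p}x{cor.p} but ensemble has p={p}"
            )
        cor.require_defined(sorted(ens.union))
        f = lambda a, b: _pair_zucknick(a, b, cor)
    else:
        raise ShapeError(f"{measure!r} is not a pairwise measure")
    return np.array([f(sets[i], sets[j]) for i, j in _pairs(ens.m)])


def _mean_pairwise(
    ens: SelectionEnsemble, measure: str, cor=None, alpha=None
) -> StabilityScore:
    value = float(np.mean(pairwise_scores(ens, measure, cor)))
    return StabilityScore(measure, value, measure_range(measure, ens.m, ens.p))


# ---------------------------------------------------------------------------
# public measures


def jaccard_stability(ens: SelectionEnsemble) -> StabilityScore:
    """Mean pairwise Jaccard index |Vi ∩ Vj| / |Vi ∪ Vj|."""
    return _mean_pairwise(ens, "SJ")


def dice_stability(ens: SelectionEnsemble) -> StabilityScore:
    """Mean pairwise Dice coefficient 2|Vi ∩ Vj| / (|Vi| + |Vj|)."""
    return _mean_pairwise(ens, "SD")


def ochiai_stability(ens: SelectionEnsemble) -> StabilityScore:
    """Mean pairwise Ochiai index |Vi ∩ Vj| / sqrt(|Vi| |Vj|)."""
    return _mean_pairwise(ens, "SO")


def zucknick_stability(
    ens: SelectionEnsemble, cor: FeatureCorrelationMatrix
) -> StabilityScore:
    """Correlation-adjusted Jaccard index.

    Features in the symmetric difference of a pair still contribute if
    their Pearson correlation with features of the other set exceeds the
    median correlation among all distinct feature pairs of the union.
    With all off-diagonal correlations zero this reduces exactly to the
    Jaccard measure.  The threshold comparison is strict (``Cor > r``),
    so for a two-feature union the single correlation never passes its
    own median.
    """
    return _mean_pairwise(ens, "SZ", cor=cor)


def lustgarten_stability(ens: SelectionEnsemble) -> StabilityScore:
    """Chance-corrected pairwise overlap of Lustgarten et al.

    Pairwise score (|Vi ∩ Vj| − |Vi||Vj|/p) / (min(|Vi|,|Vj|) −
    max(0, |Vi|+|Vj|−p)).  Undefined when the denominator vanishes,
    in particular when all features are selected.
    """
    return _mean_pairwise(ens, "SL")


def correlation_stability(ens: SelectionEnsemble) -> StabilityScore:
    """Mean pairwise Pearson correlation of the binary indicator vectors.

    For binary vectors this is the phi coefficient of the 2x2 contingency
    table of each pair; it is corrected for chance.  Undefined whenever a
    set is empty or selects all ``p`` features (constant indicator).
    """
    return _mean_pairwise(ens, "SC")


def novovicova_stability(ens: SelectionEnsemble) -> StabilityScore:
    """Entropy-based frequency measure: (1 / (q log2 m)) Σ_j h_j log2 h_j."""
    q = ens.q
    if q == 0:
        raise EmptySetError("all selected sets are empty (q = 0)")
    h = ens.counts
    h = h[h > 0].astype(np.float64)
    value = float(np.sum(h * np.log2(h)) / (q * math.log2(ens.m)))
    return StabilityScore("SN", value, measure_range("SN", ens.m, ens.p))


def davis_stability(ens: SelectionEnsemble, alpha: float = 0.0) -> StabilityScore:
    """Frequency measure of Davis et al. with sparsity penalty ``alpha``.

    max(0, mean_{j in V} h_j/m − alpha * median(|V_1|..|V_m|) / p); the
    median is the standard sample median (mean of the two central order
    statistics for even m).
    """
    if alpha < 0:
        raise ShapeError(f"alpha must be >= 0, got {alpha}")
    union = ens.union
    if not union:
        raise EmptySetError("the union of the selected sets is empty")
    h = ens.counts
    freq = float(h[h > 0].sum()) / (len(union) * ens.m)
    penalty = alpha * float(np.median(ens.sizes)) / ens.p
    value = max(0.0, freq - penalty)
    key = f"SD-{alpha:g}"
    return StabilityScore(
        key, value, measure_range("SD-alpha", ens.m, ens.p, alpha), alpha=alpha
    )


def somol_stability(ens: SelectionEnsemble) -> StabilityScore:
    """Relative weighted consistency of Somol and Novovicova.

    The weighted consistency D = Σ_j (h_j/q)(h_j−1)/(m−1) is rescaled by
    its extremes c_min, c_max attainable at the observed total number of
    selections q, giving a chance-corrected value in [0, 1].  Undefined
    when c_max = c_min (e.g. all features selected in every set).
    """
    q, m, p = ens.q, ens.m, ens.p
    if q == 0:
        raise EmptySetError("all selected sets are empty (q = 0)")
    h = ens.counts.astype(np.float64)
    D = float(np.sum((h / q) * ((h - 1) / (m - 1))))
    c_min = (q * q - p * (q - q % p) - (q % p) ** 2) / (p * q * (m - 1))
    c_max = ((q % m) ** 2 + q * (m - 1) - (q % m) * m) / (q * (m - 1))
    if math.isclose(c_min, c_max, abs_tol=1e-15):
        raise DegenerateSelectionError(
            "relative weighted consistency undefined: c_max = c_min"
        )
    value = (D - c_min) / (c_max - c_min)
    return StabilityScore("SS", value, measure_range("SS", m, p))


# ---------------------------------------------------------------------------
# dispatcher


def all_stabilities(
    ens: SelectionEnsemble,
    cor: Optional[FeatureCorrelationMatrix] = None,
    alphas: Sequence[float] = (0, 1, 2, 10),
    measures: Optional[Iterable[str]] = None,
) -> Mapping[str, StabilityScore]:
    """Evaluate all (or the requested) stability measures on one ensemble.

    Measures whose preconditions fail for this ensemble are reported as
    undefined scores carrying the reason, never silently dropped.  ``SZ``
    needs the feature correlation matrix ``cor``; ``SD-alpha`` is
    evaluated once per entry of ``alphas``.
    """
    if measures is None:
        measures = MEASURES
    out: dict[str, StabilityScore] = {}

    def run(key: str, fn, *args, alpha=None):
        try:
            out[key] = fn(*args)
        except StabselError as exc:
            rng = measure_range(key, ens.m, ens.p, alpha or 0.0)
            out[key] = StabilityScore(key, None, rng, alpha=alpha, reason=str(exc))

    for meas in measures:
        if meas == "SJ":
            run("SJ", jaccard_stability, ens)
        elif meas == "SD":
            run("SD", dice_stability, ens)
        elif meas == "SO":
            run("SO", ochiai_stability, ens)
        elif meas == "SZ":
            if cor is None:
                out["SZ"] = StabilityScore(
                    "SZ", None, measure_range("SZ", ens.m, ens.p),
                    reason="no feature correlation matrix provided",
                )
            else:
                run("SZ", zucknick_stability, ens, cor)
        elif meas == "SL":
            run("SL", lustgarten_stability, ens)
        elif meas == "SN":
            run("SN", novovicova_stability, ens)
        elif meas == "SS":
            run("SS", somol_stability, ens)
        elif meas == "SC":
            run("SC", correlation_stability, ens)
        elif meas in ("SD-alpha", "SD-a"):
            for a in alphas:
                run(f"SD-{a:g}", lambda e, a=a: davis_stability(e, a), ens, alpha=a)
        elif meas.startswith("SD-"):
            a = float(meas[3:])
            run(f"SD-{a:g}", lambda e, a=a: davis_stability(e, a), ens, alpha=a)
        else:
            raise ShapeError(f"unknown stability measure {meas!r}")
    return out
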