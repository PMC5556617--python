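"""Pareto dominance, fronts, and the accuracy-band configuration analysis.

All criteria are minimized; stability enters as ``1 - stability``.  A
point dominates another if it is no worse in every criterion and
strictly better in at least one; the Pareto front keeps exactly the
non-dominated points.  Duplicated criteria vectors on the front are all
retained, because each carries its own configuration provenance.

The *accuracy band* analysis first restricts to configurations whose
cross-validated error does not exceed ``c* + delta``, with ``c*`` the
best error among all candidates (default band width 0.05), and then
extracts the Pareto front over (1 - stability, model size).  This finds
sparse, stable configurations that give up almost no accuracy relative
to picking purely by error.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .errors import ShapeError, UndefinedStabilityError
from .evaluation import EvaluationResult

logger = logging.getLogger(__name__)

__all__ = [
    "ParetoPoint",
    "AccuracyBand",
    "dominates",
    "pareto_front",
    "accuracy_band",
    "desirable_configurations",
]


@dataclass(frozen=True)
class ParetoPoint:
    """A criteria vector (minimization orientation) with provenance."""

    criteria: tuple
    result: Optional[EvaluationResult] = None

    def __post_init__(self):
        crit = tuple(float(c) for c in self.criteria)
        object.__setattr__(self, "criteria", crit)
        if len(crit) < 1:
            raise ShapeError("criteria vector must have at least one entry")
        if not all(math.isfinite(c) for c in crit):
            raise ShapeError(f"criteria must be finite, got {crit}")


@dataclass(frozen=True)
class AccuracyBand:
    """Configurations within ``delta`` of the best error ``c*``."""

    c_star: float
    delta: float
    retained: tuple


def dominates(y: Sequence[float], z: Sequence[float]) -> bool:
    """True iff y is <= z in every criterion and < in at least one."""
    y = tuple(y)
    z = tuple(z)
    if len(y) != len(z):
        raise ShapeError(f"criteria lengths differ: {len(y)} vs {len(z)}")
    return all(a <= b for a, b in zip(y, z)) and any(a < b for a, b in zip(y, z))


def pareto_front(points: Sequence[ParetoPoint]) -> List[ParetoPoint]:
    """The non-dominated subset, in input order.

    Duplicates of a non-dominated vector are all kept.  Simple O(n^2)
    pairwise scan, vectorized over numpy; adequate for the tens of
    thousands of configurations arising here.
    """
    if len(points) == 0:
        raise ShapeError("cannot compute the Pareto front of no points")
    t = len(points[0].criteria)
    if any(len(pt.criteria) != t for pt in points):
        raise ShapeError("inconsistent criteria dimensions")
    C = np.array([pt.criteria for pt in points], dtype=np.float64)
    keep = []
    for i in range(C.shape[0]):
        le = (C <= C[i]).all(axis=1)
        lt = (C < C[i]).any(axis=1)
        if not (le & lt).any():
            keep.append(points[i])
    return keep


def accuracy_band(
    results: Sequence[EvaluationResult], delta: float = 0.05
) -> AccuracyBand:
    """Retain results whose CV error is within ``delta`` of the best."""
    errors = [r.error for r in results if math.isfinite(r.error)]
    if not errors:
        raise ShapeError("no results with a finite error")
    c_star = min(errors)
    retained = tuple(
        r
        for r in results
        if math.isfinite(r.error) and r.error <= c_star + delta
    )
    return AccuracyBand(c_star=c_star, delta=delta, retained=retained)


def _points_for(
    results: Sequence[EvaluationResult],
    measure: str,
    with_error: bool,
    strict: bool,
) -> List[ParetoPoint]:
    points = []
    undefined = []
    for r in results:
        s = r.stability_value(measure)
        if s is None or not math.isfinite(r.error):
            undefined.append(r.configuration.label())
            continue
        crit = (1.0 - s, r.size)
        if with_error:
            crit = (r.error,) + crit
        points.append(ParetoPoint(criteria=crit, result=r))
    if undefined:
        if strict:
            raise UndefinedStabilityError(
                f"{measure} undefined for configurations: {undefined}"
            )
        logger.warning(
            "%s undefined for %d configuration(s); excluded from the front",
            measure,
            len(undefined),
        )
    if not points:
        raise UndefinedStabilityError(
            f"{measure} is undefined for every candidate configuration"
        )
    return points


def desirable_configurations(
    results: Sequence[EvaluationResult],
    measure: str = "SC",
    delta: float = 0.05,
    mode: str = "band2d",
    strict: bool = False,
) -> List[ParetoPoint]:
    """Pareto-optimal configurations for one stability measure.

    mode "band2d": restrict to the accuracy band (error <= c* + delta),
    then extract the front over (1 - stability, size).  mode "3d":
    extract the front over (error, 1 - stability, size) with no band.
    Configurations for which the measure is undefined are excluded with
    a warning (or raise, if ``strict``).
    """
    if mode == "band2d":
        band = accuracy_band(results, delta=delta)
        points = _points_for(band.retained, measure, with_error=False, strict=strict)
    elif mode == "3d":
        points = _points_for(results, measure, with_error=True, strict=strict)
    else:
        raise ShapeError(f"unknown mode {mode!r}; use 'band2d' or '3d'")
    return pareto_front(points)
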