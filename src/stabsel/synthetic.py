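"""Synthetic microarray-like data and random selection ensembles.

The generator emulates the structure of two-class gene-expression
matrices: many metric features, a handful of informative ones whose
class means differ, optional blocks of mutually correlated features
(co-regulated genes), and the rest pure Gaussian noise.  It provides
ground truth (which features are informative, which belong to blocks)
so that feature-recovery behaviour can be tested without external data.

Correlated blocks are built from a single shared latent factor per
block, ``x = sqrt(rho) * f + sqrt(1 - rho) * eps``, which gives every
within-block pair correlation exactly ``rho`` in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

from .dataset import LabeledDataset
from .ensemble import SelectionEnsemble
from .errors import ConfigError, ShapeError

__all__ = ["GeneratorSpec", "make_dataset", "random_selection_ensemble"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic two-class expression-like data set.

    Defaults describe the desk-scale study condition used throughout the
    test suite: 150 observations, 300 features of which 5 carry a class
    mean shift of 2 noise standard deviations, plus one block of 10
    features with pairwise correlation 0.9.

    Parameters
    ----------
    n, p : int
        Observations and features.
    n_informative : int
        Number of features with a class-dependent mean shift.
    effect : float
        Mean shift between classes on informative features, in units of
        the noise standard deviation (classes sit at ±effect/2).
    blocks : sequence of (size, rho)
        Correlated feature blocks; rho in [0, 1).
    balance : float
        Fraction of observations in class 1, in (0, 1).  Class counts
        are deterministic (round(n * balance)) so both classes are
        always present.
    blocks_overlap_informative : bool
        If True, blocks start at feature 0 and may cover informative
        features, producing the "different but highly correlated"
        selections that distinguish the correlation-adjusted stability
        measure from the plain Jaccard index.  If False (default),
        blocks are placed after the informative features.
    seed : int
        Seed for the generator stream.
    """

    n: int = 150
    p: int = 300
    n_informative: int = 5
    effect: float = 2.0
    blocks: Tuple[Tuple[int, float], ...] = ((10, 0.9),)
    balance: float = 0.5
    blocks_overlap_informative: bool = False
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "blocks", tuple(tuple(b) for b in self.blocks))
        if self.n < 4 or self.p < 1:
            raise ConfigError("need n >= 4 observations and p >= 1 features")
        if not 0 <= self.n_informative <= self.p:
            raise ConfigError("n_informative must lie in [0, p]")
        if not 0 < self.balance < 1:
            raise ConfigError("class balance must be in (0, 1)")
        if self.effect < 0:
            raise ConfigError("effect size must be >= 0")
        used = self.n_informative if not self.blocks_overlap_informative else 0
        for size, rho in self.blocks:
            if size < 2:
                raise ConfigError("block size must be >= 2")
            if not 0 <= rho < 1:
                raise ConfigError("block correlation rho must be in [0, 1)")
            used += size
        if used > self.p:
            raise ConfigError("blocks and informative features exceed p")


def make_dataset(spec: GeneratorSpec) -> LabeledDataset:
    """Draw one data set from the generator specification.

    Returns a :class:`LabeledDataset` whose ``truth`` dict records the
    informative feature indices and the block layout.
    """
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n, spec.p

    n1 = int(round(spec.balance * n))
    n1 = min(max(n1, 1), n - 1)
    y = np.zeros(n, dtype=np.int64)
    y[rng.permutation(n)[:n1]] = 1

    X = rng.standard_normal((n, p))

    start = 0 if spec.blocks_overlap_informative else spec.n_informative
    block_ranges = []
    for size, rho in spec.blocks:
        cols = np.arange(start, start + size)
        f = rng.standard_normal(n)
        X[:, cols] = np.sqrt(rho) * f[:, None] + np.sqrt(1.0 - rho) * X[:, cols]
        block_ranges.append({"features": cols.tolist(), "rho": rho})
        start += size

    informative = np.arange(spec.n_informative)
    shift = np.where(y == 1, spec.effect / 2.0, -spec.effect / 2.0)
    X[:, informative] += shift[:, None]

    frame = pd.DataFrame(X, columns=[f"X{j + 1}" for j in range(p)])
    truth = {
        "informative": informative.tolist(),
        "blocks": block_ranges,
        "spec": spec,
    }
    return LabeledDataset(
        X=frame, y=y, provenance=f"synthetic(seed={spec.seed})", truth=truth
    )


def random_selection_ensemble(
    m: int, p: int, k: int, seed: int | np.random.Generator = 0
) -> SelectionEnsemble:
    """m independent uniform draws of k-subsets of {0..p-1}.

    This is the random-selection null under which chance-corrected
    stability measures have constant expectation regardless of k.
    """
    if not 1 <= k <= p:
        raise ShapeError(f"k must be in [1, {p}], got {k}")
    if m < 2:
        raise ShapeError("need m >= 2 sets")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sets = tuple(
        frozenset(rng.choice(p, size=k, replace=False).tolist()) for _ in range(m)
    )
    return SelectionEnsemble(p=p, sets=sets)
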