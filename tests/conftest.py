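import numpy as np
import pytest

from stabsel import FeatureCorrelationMatrix, SelectionEnsemble


def random_ensemble(rng, p_max=12, m_max=6, allow_full=False):
    """A random ensemble of nonempty sets for oracle comparisons."""
    p = int(rng.integers(2, p_max + 1))
    m = int(rng.integers(2, m_max + 1))
    hi = p if allow_full else p - 1
    sets = []
    for _ in range(m):
        k = int(rng.integers(1, max(hi, 1) + 1))
        sets.append(frozenset(rng.choice(p, size=k, replace=False).tolist()))
    return SelectionEnsemble(p=p, sets=tuple(sets))


def random_correlation(rng, p):
    """A valid random correlation matrix (from random data)."""
    X = rng.standard_normal((max(2 * p, 8), p)) @ rng.standard_normal((p, p))
    return FeatureCorrelationMatrix.from_data(X)


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
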