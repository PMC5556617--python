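"""Unit tests for the individual stability measures on hand-evaluated cases."""

import math

import numpy as np
import pytest

from stabsel import (
    DegenerateSelectionError,
    EmptySetError,
    FeatureCorrelationMatrix,
    SelectionEnsemble,
    UndefinedCorrelationError,
    all_stabilities,
    correlation_stability,
    davis_stability,
    dice_stability,
    jaccard_stability,
    lustgarten_stability,
    novovicova_stability,
    ochiai_stability,
    somol_stability,
    zucknick_stability,
)


def ens(sets, p):
    return SelectionEnsemble(p=p, sets=tuple(frozenset(s) for s in sets))


IDENTICAL = ens([{0, 1, 2}] * 3, p=10)
DISJOINT = ens([{0, 1}, {2, 3}], p=10)


@pytest.mark.parametrize(
    "measure, ensemble, expected",
    [
        (jaccard_stability, IDENTICAL, 1.0),
        (jaccard_stability, DISJOINT, 0.0),
        (jaccard_stability, ens([{0, 1}, {0, 2}], 10), 1 / 3),
        (dice_stability, IDENTICAL, 1.0),
        (dice_stability, DISJOINT, 0.0),
        (dice_stability, ens([{0, 1}, {0, 2}], 10), 0.5),
        (ochiai_stability, IDENTICAL, 1.0),
        (ochiai_stability, DISJOINT, 0.0),
        (ochiai_stability, ens([{0, 1}, {0}], 10), 1 / math.sqrt(2)),
        (lustgarten_stability, ens([{0}, {0}], 4), 0.75),
        (lustgarten_stability, ens([{0}, {1}], 4), -0.25),
        (novovicova_stability, ens([{0, 1, 2}] * 2, 10), 1.0),
        (novovicova_stability, ens([{0}, {1}], 10), 0.0),
        (novovicova_stability, ens([{0, 1}, {0}], 10), 2 / 3),
        (somol_stability, ens([{0}, {0}], 4), 1.0),
        (somol_stability, ens([{0}, {1}], 4), 0.0),
        (somol_stability, ens([{0, 1}, {0}], 4), 1.0),
        (correlation_stability, ens([{0, 2}, {0, 2}], 5), 1.0),
        (correlation_stability, ens([{0}, {1}], 2), -1.0),
        (correlation_stability, ens([{0, 1}, {0, 2}], 4), 0.0),
    ],
)
def test_measure_examples(measure, ensemble, expected):
    assert measure(ensemble).value == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "alpha, ensemble, p, expected",
    [
        # deterministic selection of k=2 features with alpha=1, p=10
        (1.0, [{3, 7}] * 4, 10, 1 - 2 * (1 / 10)),
        (0.0, [{0, 1}, {0, 2}], 10, 2 / 3),
        (10.0, [{3, 7}] * 4, 10, 0.0),  # clamped at 0
    ],
)
def test_davis_examples(alpha, ensemble, p, expected):
    e = ens(ensemble, p)
    assert davis_stability(e, alpha).value == pytest.approx(expected, abs=1e-12)


class TestZucknick:
    def test_worked_example(self):
        # correlated pair outside the intersection raises the score above
        # plain Jaccard: (1 + 0.45 + 0.45) / 3
        C = np.eye(3)
        C[1, 2] = C[2, 1] = 0.9
        C[0, 1] = C[1, 0] = C[0, 2] = C[2, 0] = 0.1
        e = ens([{0, 1}, {0, 2}], 3)
        score = zucknick_stability(e, FeatureCorrelationMatrix(C))
        assert score.value == pytest.approx(1.9 / 3, abs=1e-12)

    def test_zero_correlations_reduce_to_jaccard(self, rng):
        from conftest import random_ensemble

        for _ in range(25):
            e = random_ensemble(rng)
            sz = zucknick_stability(e, FeatureCorrelationMatrix.identity(e.p))
            assert sz.value == pytest.approx(
                jaccard_stability(e).value, abs=1e-12
            )

    def test_identical_sets_attain_one(self):
        C = np.full((4, 4), 0.5)
        np.fill_diagonal(C, 1.0)
        e = ens([{1, 3}] * 3, 4)
        assert zucknick_stability(e, FeatureCorrelationMatrix(C)).value == 1.0

    def test_strict_median_threshold_for_two_feature_union(self):
        # |union| = 2: the single correlation equals the median and the
        # strict inequality excludes it, so SZ falls back to Jaccard
        C = np.eye(2)
        C[0, 1] = C[1, 0] = 0.99
        e = ens([{0}, {1}], 2)
        assert zucknick_stability(e, FeatureCorrelationMatrix(C)).value == 0.0

    def test_constant_feature_in_union_rejected(self):
        C = np.eye(3)
        C[2, :] = C[:, 2] = np.nan
        C[2, 2] = 1.0
        e = ens([{0, 2}, {0, 1}], 3)
        with pytest.raises(UndefinedCorrelationError):
            zucknick_stability(e, FeatureCorrelationMatrix(C))


class TestDegeneracy:
    def test_empty_set_rejected_by_pairwise_measures(self):
        e = ens([{0, 1}, set()], 4)
        for measure in (
            jaccard_stability,
            dice_stability,
            ochiai_stability,
            lustgarten_stability,
            correlation_stability,
        ):
            with pytest.raises(EmptySetError):
                measure(e)

    def test_all_features_selected_undefined_for_corrected_measures(self):
        e = ens([set(range(6))] * 3, 6)
        with pytest.raises(DegenerateSelectionError):
            lustgarten_stability(e)
        with pytest.raises(DegenerateSelectionError):
            somol_stability(e)
        with pytest.raises(DegenerateSelectionError):
            correlation_stability(e)

    def test_all_empty_rejected_by_frequency_measures(self):
        e = ens([set(), set()], 4)
        with pytest.raises(EmptySetError):
            novovicova_stability(e)
        with pytest.raises(EmptySetError):
            davis_stability(e, 1.0)
        with pytest.raises(EmptySetError):
            somol_stability(e)


class TestDispatcher:
    def test_identity_maximum_suite(self):
        e = ens([{0, 1}] * 3, 10)
        out = all_stabilities(
            e, cor=FeatureCorrelationMatrix.identity(10), alphas=[0]
        )
        for key in ("SJ", "SD", "SO", "SZ", "SN", "SC", "SD-0"):
            assert out[key].value == pytest.approx(1.0, abs=1e-9), key

    def test_degeneracy_routed_to_undefined(self):
        e = ens([set(range(5))] * 2, 5)
        out = all_stabilities(e, alphas=[0, 1])
        for key in ("SC", "SL", "SS"):
            assert not out[key].defined
            assert out[key].reason
        for key in ("SJ", "SD", "SO", "SN", "SD-0", "SD-1"):
            assert out[key].defined, key
        assert not out["SZ"].defined  # no correlation matrix passed

    def test_dispatcher_matches_individual_operations(self, rng):
        from conftest import random_ensemble, random_correlation

        for _ in range(20):
            e = random_ensemble(rng)
            cor = random_correlation(rng, e.p)
            out = all_stabilities(e, cor=cor, alphas=[0, 2])
            assert out["SJ"].value == jaccard_stability(e).value
            assert out["SD"].value == dice_stability(e).value
            assert out["SO"].value == ochiai_stability(e).value
            assert out["SZ"].value == zucknick_stability(e, cor).value
            assert out["SN"].value == novovicova_stability(e).value
            assert out["SD-2"].value == davis_stability(e, 2).value

    def test_score_values_lie_in_reported_range(self, rng):
        from conftest import random_ensemble

        for _ in range(200):
            e = random_ensemble(rng)
            for key, score in all_stabilities(e).items():
                if score.defined:
                    lo, hi = score.range
                    assert lo - 1e-9 <= score.value <= hi + 1e-9, key
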