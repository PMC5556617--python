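"""Cross-validated configuration evaluation: splits, extraction cascade,
criteria bookkeeping and the random hyperparameter search."""

import numpy as np
import pytest

import stabsel.evaluation as ev
from stabsel import (
    ConfigError,
    Configuration,
    GeneratorSpec,
    LabeledDataset,
    cv_splits,
    desk_space,
    evaluate_configuration,
    fit_and_extract,
    make_dataset,
    random_search,
    sample_configurations,
    full_space,
)


@pytest.fixture(scope="module")
def data():
    return make_dataset(GeneratorSpec(n=100, p=40, n_informative=3, seed=11))


class TestCvSplits:
    def test_partition_with_balanced_block_sizes(self):
        y = np.array([0] * 55 + [1] * 45)
        splits = cv_splits(100, 10, y, seed=4)
        tests = [set(te.tolist()) for _, te in splits]
        assert all(len(t) == 10 for t in tests)
        assert set().union(*tests) == set(range(100))
        assert sum(len(a & b) for a in tests for b in tests if a is not b) == 0

    def test_stratified(self):
        y = np.array([0] * 80 + [1] * 20)
        for _, test in cv_splits(100, 10, y, seed=0):
            assert (y[test] == 1).sum() == 2

    def test_train_test_complementary(self):
        y = np.arange(20) % 2
        for train, test in cv_splits(20, 5, y, seed=1):
            assert sorted(train.tolist() + test.tolist()) == list(range(20))

    def test_seed_determinism(self):
        y = np.arange(30) % 2
        a = cv_splits(30, 5, y, seed=9)
        b = cv_splits(30, 5, y, seed=9)
        c = cv_splits(30, 5, y, seed=10)
        assert all((x[1] == y_[1]).all() for x, y_ in zip(a, b))
        assert any((x[1] != y_[1]).any() for x, y_ in zip(a, c))


class TestConfiguration:
    def test_parameter_names_validated(self):
        with pytest.raises(ConfigError):
            Configuration("auc", 5, "svm-rbf", {"sigma": 1.0})  # C missing
        with pytest.raises(ConfigError):
            Configuration("auc", 5, "glmboost", {"m_stop": 5, "C": 1.0})
        with pytest.raises(ConfigError):
            Configuration("unknown", 5, "svm-rbf", {"sigma": 1.0, "C": 1.0})


class TestFitAndExtract:
    def test_svm_uses_all_features(self, data):
        config = Configuration("none", 0, "svm-rbf", {"sigma": 0.1, "C": 1.0})
        _, fset = fit_and_extract(data, config)
        assert fset == frozenset(range(data.p))

    def test_cascade_upper_bound(self, data):
        config = Configuration("auc", 1, "lasso-logreg", {"lambda": 1.0})
        _, fset = fit_and_extract(data, config)
        assert len(fset) <= 1

    def test_huge_lasso_penalty_empties_the_model(self, data):
        config = Configuration("auc", 10, "lasso-logreg", {"lambda": 2.0**15})
        _, fset = fit_and_extract(data, config)
        assert len(fset) == 0

    def test_boosting_features_bounded_by_iterations(self, data):
        config = Configuration("variance", 20, "glmboost", {"m_stop": 3})
        _, fset = fit_and_extract(data, config)
        assert 1 <= len(fset) <= 3

    def test_forest_importance_strictly_positive(self, data):
        config = Configuration(
            "auc", 5, "random-forest", {"num.trees": 25, "min.node.size": 2}
        )
        pipe, fset = fit_and_extract(data, config, seed=1)
        imp = pipe.predictor.model.feature_importances_
        assert fset == frozenset(pipe.filtered[np.flatnonzero(imp > 0)].tolist())


class _StubPredictor:
    """Always selects features {0, 1} and predicts the majority class."""

    def __init__(self, y):
        vals, counts = np.unique(y, return_counts=True)
        self.majority = vals[np.argmax(counts)]

    def predict(self, X):
        return np.full(len(X), self.majority)

    def selected_features(self):
        return np.array([0, 1])


class TestEvaluateConfiguration:
    def test_deterministic_stub_criteria(self, monkeypatch):
        monkeypatch.setitem(
            ev._BACKENDS, "svm-rbf", lambda X, y, params, seed: _StubPredictor(y)
        )
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 6))
        y = np.array([0] * 60 + [1] * 40)
        data = LabeledDataset(X=X, y=y)
        config = Configuration("none", 0, "svm-rbf", {"sigma": 1.0, "C": 1.0})
        res = evaluate_configuration(data, config, folds=10, seed=5)
        assert res.size == 2.0
        assert res.error == pytest.approx(0.4)  # minority fraction
        assert res.stability["SJ"].value == 1.0
        assert res.stability["SC"].value == 1.0

    def test_error_is_mean_of_fold_rates_and_size_mean_cardinality(self, data):
        config = Configuration("auc", 5, "glmboost", {"m_stop": 50})
        res = evaluate_configuration(data, config, folds=5, seed=2)
        assert res.size == pytest.approx(np.mean(res.ensemble.sizes), abs=1e-12)
        assert 0.0 <= res.error <= 1.0
        assert res.ensemble.m == 5

    def test_single_separating_feature_recovered(self):
        rng = np.random.default_rng(3)
        n = 100
        y = np.array([0, 1] * (n // 2))
        X = rng.standard_normal((n, 20))
        X[:, 7] = np.where(y == 1, 5.0, -5.0) + 0.1 * rng.standard_normal(n)
        data = LabeledDataset(X=X, y=y)
        config = Configuration("auc", 1, "lasso-logreg", {"lambda": 0.5})
        res = evaluate_configuration(data, config, folds=10, seed=0)
        assert res.error == 0.0
        assert res.size == 1.0
        assert res.stability["SJ"].value == 1.0
        assert res.ensemble.sets[0] == frozenset({7})

    def test_column_permutation_equivariance(self, data):
        config = Configuration("auc", 3, "glmboost", {"m_stop": 40})
        res = evaluate_configuration(data, config, folds=5, seed=8)
        perm = np.random.default_rng(1).permutation(data.p)
        Xp = data.X.iloc[:, perm]
        permuted = LabeledDataset(X=Xp.reset_index(drop=True), y=data.y)
        res_p = evaluate_configuration(permuted, config, folds=5, seed=8)
        assert res_p.error == pytest.approx(res.error, abs=1e-12)
        inverse = np.empty(data.p, dtype=int)
        inverse[perm] = np.arange(data.p)
        mapped = [frozenset(int(inverse[j]) for j in s) for s in res.ensemble.sets]
        assert list(res_p.ensemble.sets) == mapped

    def test_no_test_fold_leakage(self, data):
        config = Configuration("auc", 4, "lasso-logreg", {"lambda": 1.0})
        X = data.matrix()
        y = data.binary_labels()
        train, test = cv_splits(data.n, 5, y, seed=3)[0]
        _, fset = ev._fit_rows(X[train], y[train], config, seed=0)
        X2 = X.copy()
        X2[test] = 999.0  # corrupt held-out rows only
        _, fset2 = ev._fit_rows(X2[train], y[train], config, seed=0)
        assert fset == fset2


class TestRandomSearch:
    def test_sampled_parameters_inside_ranges(self):
        space = full_space(p=300)
        configs = sample_configurations(space, 3, seed=0, per_method=True)
        assert len(configs) == 3 * 12
        for c in configs:
            assert 1 <= c.n_feats <= 300
            for name, value in c.params.items():
                if name in ("m_stop", "num.trees"):
                    assert 1 <= value <= 2**15
                elif name == "min.node.size":
                    assert 1 <= value <= 2**5
                else:
                    assert 2.0**-15 <= value <= 2.0**15

    def test_same_seed_identical_configurations(self):
        space = desk_space(p=50)
        a = sample_configurations(space, 2, seed=7)
        b = sample_configurations(space, 2, seed=7)
        assert a == b

    def test_round_robin_total_count(self):
        space = desk_space(p=50)
        configs = sample_configurations(space, 25, seed=1, per_method=False)
        assert len(configs) == 25
        methods = {(c.filter, c.classifier) for c in configs}
        assert len(methods) == 12  # every augmented method appears

    def test_search_runs_and_is_reproducible(self, data):
        space = desk_space(data.p)
        kwargs = dict(n_configs=6, seed=13, folds=3, measures=["SJ", "SC"])
        r1 = random_search(data, space, **kwargs)
        r2 = random_search(data, space, **kwargs)
        assert [r.error for r in r1] == [r.error for r in r2]
        assert [r.configuration for r in r1] == [r.configuration for r in r2]
        for r in r1:
            assert r.error <= 1.0

    def test_feature_recovery_beats_random_selection(self):
        data = make_dataset(GeneratorSpec(seed=21))
        config = Configuration("auc", 5, "lasso-logreg", {"lambda": 0.1})
        res = evaluate_configuration(data, config, folds=10, seed=4)
        informative = set(data.truth["informative"])
        hits = np.mean(
            [len(s & informative) / max(len(s), 1) for s in res.ensemble.sets]
        )
        assert hits > 0.6  # informative features dominate the fold selections
        from stabsel import jaccard_stability, random_selection_ensemble

        random_sj = jaccard_stability(
            random_selection_ensemble(10, data.p, 5, seed=0)
        ).value
        assert res.stability["SJ"].value > random_sj
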