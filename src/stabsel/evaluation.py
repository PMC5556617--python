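"""Cross-validated evaluation of filter + classifier configurations.

An *augmented method* applies a univariate filter first and then fits a
classifier on the surviving features; classifiers with embedded feature
selection (lasso logistic regression, componentwise boosting, random
forest) prune further, so the features actually used by a fitted model
are the cascade of both stages.  Evaluating a configuration by k-fold
cross-validation yields three criteria:

* **error** — the mean held-out misclassification rate over folds,
* **size** — the mean number of features used by the fold models,
* **stability** — any of the stability measures applied to the ensemble
  of the per-fold feature sets.

Feature-set extraction rules per classifier family:

* lasso logistic regression: features with nonzero coefficients;
* componentwise gradient boosting: features whose single-feature base
  learner was picked in at least one boosting iteration;
* random forest: features with impurity importance strictly > 0;
* RBF-kernel SVM: all features entering the model (no embedded selection).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from joblib import Parallel, delayed
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .dataset import LabeledDataset
from .ensemble import FeatureCorrelationMatrix, SelectionEnsemble
from .errors import BackendError, ConfigError, ShapeError
from .filters import auc_filter, mrmr_select, select_top_k, variance_filter
from .stability import StabilityScore, all_stabilities

logger = logging.getLogger(__name__)

__all__ = [
    "Configuration",
    "EvaluationResult",
    "SearchSpace",
    "cv_splits",
    "fit_and_extract",
    "evaluate_configuration",
    "sample_configurations",
    "random_search",
    "full_space",
    "desk_space",
]

FILTERS = ("variance", "auc", "mrmr", "none")
CLASSIFIERS = ("glmboost", "lasso-logreg", "random-forest", "svm-rbf")

#: hyperparameters applying to each classifier family
_CLASSIFIER_PARAMS = {
    "glmboost": ("m_stop",),
    "lasso-logreg": ("lambda",),
    "random-forest": ("num.trees", "min.node.size"),
    "svm-rbf": ("sigma", "C"),
}


@dataclass(frozen=True)
class Configuration:
    """One augmented method with fixed hyperparameter values."""

    filter: str
    n_feats: int
    classifier: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "params", dict(self.params))
        if self.filter not in FILTERS:
            raise ConfigError(f"unknown filter {self.filter!r}")
        if self.classifier not in CLASSIFIERS:
            raise ConfigError(f"unknown classifier {self.classifier!r}")
        if self.filter != "none" and self.n_feats < 1:
            raise ConfigError("n_feats must be >= 1")
        expected = set(_CLASSIFIER_PARAMS[self.classifier])
        got = set(self.params)
        if got != expected:
            raise ConfigError(
                f"{self.classifier} expects parameters {sorted(expected)}, "
                f"got {sorted(got)}"
            )

    def label(self) -> str:
        par = ", ".join(f"{k}={v:g}" for k, v in sorted(self.params.items()))
        return f"{self.filter}+{self.classifier}(n_feats={self.n_feats}, {par})"


@dataclass
class EvaluationResult:
    """Criteria of one configuration under k-fold cross-validation."""

    configuration: Configuration
    error: float
    size: float
    ensemble: SelectionEnsemble
    stability: Dict[str, StabilityScore]
    folds: int
    seed: int

    def stability_value(self, measure: str) -> Optional[float]:
        score = self.stability.get(measure)
        return None if score is None or not score.defined else score.value


# ---------------------------------------------------------------------------
# cross-validation splits


def cv_splits(
    n: int, folds: int, y, seed: int
) -> List[Tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold partition of ``n`` rows into test blocks.

    Test block sizes differ by at most one overall and per class; the
    split is a deterministic function of the seed.
    """
    if folds < 2:
        raise ShapeError("need at least 2 folds")
    if n < folds:
        raise ShapeError(f"cannot split {n} rows into {folds} folds")
    y = np.asarray(y)
    if y.shape[0] != n:
        raise ShapeError("label vector length must equal n")
    rng = np.random.default_rng(seed)
    # deal class by class, round-robin through a running fold pointer so
    # that overall fold sizes stay within one of each other
    assignment = np.empty(n, dtype=np.int64)
    pointer = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        for i in idx:
            assignment[i] = pointer % folds
            pointer += 1
    out = []
    all_rows = np.arange(n)
    for f in range(folds):
        test = all_rows[assignment == f]
        train = all_rows[assignment != f]
        out.append((train, test))
    return out


# ---------------------------------------------------------------------------
# classifier backends
#
# Contract: a backend is a callable (X, y01, params, seed) -> predictor,
# where the predictor has .predict(X) -> 0/1 labels and
# .selected_features() -> indices into the columns of the given X.


class _LassoPredictor:
    def __init__(self, model):
        self.model = model

    def predict(self, X):
        return self.model.predict(X)

    def selected_features(self):
        return np.flatnonzero(np.abs(self.model.coef_[0]) > 0)


def _fit_lasso(X, y, params, seed):
    # liblinear solves min ||w||_1 + C * sum(loss), so C = 1/lambda
    lam = params["lambda"]
    model = LogisticRegression(
        l1_ratio=1.0, C=1.0 / lam, solver="liblinear", random_state=seed
    )
    model.fit(X, y)
    return _LassoPredictor(model)


class _ForestPredictor:
    def __init__(self, model):
        self.model = model

    def predict(self, X):
        return self.model.predict(X)

    def selected_features(self):
        return np.flatnonzero(self.model.feature_importances_ > 0)


def _fit_forest(X, y, params, seed):
    model = RandomForestClassifier(
        n_estimators=int(params["num.trees"]),
        min_samples_leaf=int(params["min.node.size"]),
        random_state=seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return _ForestPredictor(model)


class _SvmPredictor:
    def __init__(self, model, p):
        self.model = model
        self.p = p

    def predict(self, X):
        return self.model.predict(X)

    def selected_features(self):
        return np.arange(self.p)  # no embedded selection


def _fit_svm(X, y, params, seed):
    model = SVC(kernel="rbf", gamma=params["sigma"], C=params["C"])
    model.fit(X, y)
    return _SvmPredictor(model, X.shape[1])


class _GlmBoostPredictor:
    """Componentwise gradient boosting for the logistic loss.

    Each iteration fits a one-feature linear least-squares base learner
    to the negative gradient and adds a damped step (learning rate 0.1)
    for the best-fitting feature.  The selected features are exactly the
    features whose base learner was used in at least one iteration.
    """

    def __init__(self, X, y, m_stop, nu=0.1):
        n, p = X.shape
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        sumsq = np.einsum("ij,ij->j", Xc, Xc)
        degenerate = sumsq <= 0
        sumsq = np.where(degenerate, np.inf, sumsq)
        pbar = min(max(y.mean(), 1e-12), 1 - 1e-12)
        self.offset_ = math.log(pbar / (1 - pbar))
        self.coef_ = np.zeros(p)
        f = np.full(n, self.offset_)
        used = np.zeros(p, dtype=bool)
        for _ in range(int(m_stop)):
            u = y - 1.0 / (1.0 + np.exp(-f))  # negative gradient
            s = Xc.T @ u
            crit = s * s / sumsq
            j = int(np.argmax(crit))  # argmax ties -> lowest index
            if crit[j] <= 0:
                break
            b = s[j] / sumsq[j]
            self.coef_[j] += nu * b
            f = f + nu * b * Xc[:, j]
            used[j] = True
        self.used_ = used

    def decision_function(self, X):
        return self.offset_ + (np.asarray(X) - self.mean_) @ self.coef_

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(np.int64)

    def selected_features(self):
        return np.flatnonzero(self.used_)


def _fit_glmboost(X, y, params, seed):
    return _GlmBoostPredictor(X, y, params["m_stop"])


_BACKENDS: Dict[str, Callable] = {
    "lasso-logreg": _fit_lasso,
    "random-forest": _fit_forest,
    "svm-rbf": _fit_svm,
    "glmboost": _fit_glmboost,
}


# ---------------------------------------------------------------------------
# fitting one configuration on one training set


def _filter_indices(X, y, config: Configuration) -> np.ndarray:
    p = X.shape[1]
    if config.filter == "none":
        return np.arange(p)
    k = min(config.n_feats, p)
    if config.filter == "variance":
        return select_top_k(variance_filter(X), k)
    if config.filter == "auc":
        return select_top_k(auc_filter(X, y), k)
    if config.filter == "mrmr":
        scores = mrmr_select(X, y, k)
        return np.sort(scores.order)
    raise ConfigError(f"unknown filter {config.filter!r}")


class _Pipeline:
    """A fitted filter + classifier cascade operating on full-width rows."""

    def __init__(self, filtered: np.ndarray, predictor):
        self.filtered = filtered
        self.predictor = predictor

    def predict(self, X):
        return self.predictor.predict(np.asarray(X)[:, self.filtered])

    def selected_features(self) -> np.ndarray:
        local = self.predictor.selected_features()
        return self.filtered[local]


def fit_and_extract(train: LabeledDataset, config: Configuration, seed: int = 0):
    """Fit one configuration on a training set.

    Returns ``(pipeline, feature_set)`` where the feature set contains
    the indices (into the dataset's columns) of the features actually
    used by the fitted model — the cascade of the filter selection and
    the classifier's embedded selection.
    """
    X = train.matrix()
    y = train.binary_labels()
    return _fit_rows(X, y, config, seed)


def _fit_rows(X, y, config: Configuration, seed: int):
    filtered = _filter_indices(X, y, config)
    backend = _BACKENDS[config.classifier]
    try:
        predictor = backend(X[:, filtered], y, config.params, seed)
    except Exception as exc:  # noqa: BLE001 - wrapped for the caller
        raise BackendError(
            f"{config.classifier} backend failed: {exc}"
        ) from exc
    pipe = _Pipeline(filtered, predictor)
    return pipe, frozenset(pipe.selected_features().tolist())


# ---------------------------------------------------------------------------
# configuration evaluation


def evaluate_configuration(
    data: LabeledDataset,
    config: Configuration,
    folds: int = 10,
    measures: Optional[Sequence[str]] = None,
    alphas: Sequence[float] = (0, 1, 2, 10),
    seed: int = 0,
    cor: Optional[FeatureCorrelationMatrix] = None,
) -> EvaluationResult:
    """Evaluate one configuration by stratified k-fold cross-validation.

    The filter and the classifier see only the training rows of each
    fold.  The correlation context for the correlation-adjusted measure
    (SZ) is computed once on the full data matrix unless supplied.
    """
    X = data.matrix()
    y = data.binary_labels()
    splits = cv_splits(data.n, folds, y, seed)
    fold_errors = []
    fold_sets = []
    for f, (train, test) in enumerate(splits):
        pipe, fset = _fit_rows(X[train], y[train], config, seed=seed + f)
        pred = pipe.predict(X[test])
        fold_errors.append(float(np.mean(pred != y[test])))
        fold_sets.append(fset)
    ensemble = SelectionEnsemble(p=data.p, sets=tuple(fold_sets))
    if measures is None or "SZ" in measures:
        if cor is None:
            cor = FeatureCorrelationMatrix.from_data(X)
    stability = dict(
        all_stabilities(ensemble, cor=cor, alphas=alphas, measures=measures)
    )
    return EvaluationResult(
        configuration=config,
        error=float(np.mean(fold_errors)),
        size=float(np.mean(ensemble.sizes)),
        ensemble=ensemble,
        stability=stability,
        folds=folds,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# hyperparameter space and random search


@dataclass(frozen=True)
class SearchSpace:
    """Sampling ranges for the random hyperparameter search.

    ``n_feats`` is sampled uniformly on {1..max_n_feats}; integer
    parameters uniformly on {1..max}; the continuous parameters lambda,
    sigma and C are sampled as 2^x with x uniform on
    [log2_lo, log2_hi].  ``methods`` lists the augmented methods
    (filter, classifier) included in the search.
    """

    max_n_feats: int
    max_m_stop: int = 2**15
    max_num_trees: int = 2**15
    max_min_node_size: int = 2**5
    log2_lo: float = -15.0
    log2_hi: float = 15.0
    filters: Tuple[str, ...] = ("variance", "auc", "mrmr")
    classifiers: Tuple[str, ...] = CLASSIFIERS

    @property
    def methods(self) -> List[Tuple[str, str]]:
        return [(f, c) for f in self.filters for c in self.classifiers]

    def sample(self, filter: str, classifier: str, rng) -> Configuration:
        params: Dict[str, float] = {}
        for name in _CLASSIFIER_PARAMS[classifier]:
            if name == "m_stop":
                params[name] = int(rng.integers(1, self.max_m_stop + 1))
            elif name == "num.trees":
                params[name] = int(rng.integers(1, self.max_num_trees + 1))
            elif name == "min.node.size":
                params[name] = int(rng.integers(1, self.max_min_node_size + 1))
            else:  # lambda, sigma, C: log2-uniform
                params[name] = float(
                    2.0 ** rng.uniform(self.log2_lo, self.log2_hi)
                )
        n_feats = int(rng.integers(1, self.max_n_feats + 1))
        return Configuration(filter, n_feats, classifier, params)


def full_space(p: int) -> SearchSpace:
    """The full search space: all integer ranges up to 2^15."""
    return SearchSpace(max_n_feats=p)


def desk_space(p: int) -> SearchSpace:
    """Desk-scale search space used for the built-in studies.

    Same shape as :func:`full_space` (same methods, same parameters,
    same distributions) with the iteration-count ceilings reduced —
    num.trees to 2^10 and m_stop to 2^12 — which keeps a few-hundred
    configuration sweep on a p≈300 matrix tractable on one CPU without
    changing which model classes are reachable.
    """
    return SearchSpace(max_n_feats=p, max_m_stop=2**12, max_num_trees=2**10)


def sample_configurations(
    space: SearchSpace,
    n_configs: int,
    seed: int,
    per_method: bool = True,
) -> List[Configuration]:
    """Draw random configurations from the space.

    With ``per_method=True``, draws ``n_configs`` configurations for each
    augmented method (a per-method sweep); otherwise draws a total of
    ``n_configs``, cycling round-robin through the augmented methods.
    """
    rng = np.random.default_rng(seed)
    methods = space.methods
    configs = []
    if per_method:
        for f, c in methods:
            configs.extend(space.sample(f, c, rng) for _ in range(n_configs))
    else:
        for i in range(n_configs):
            f, c = methods[i % len(methods)]
            configs.append(space.sample(f, c, rng))
    return configs


def random_search(
    data: LabeledDataset,
    space: Optional[SearchSpace] = None,
    n_configs: int = 100,
    seed: int = 0,
    folds: int = 10,
    measures: Optional[Sequence[str]] = None,
    alphas: Sequence[float] = (0, 1, 2, 10),
    per_method: bool = False,
    n_jobs: int = 1,
) -> List[EvaluationResult]:
    """Random hyperparameter search over augmented methods.

    Samples configurations from ``space`` (default: the full space for
    the data's dimensionality), evaluates each by ``folds``-fold CV and
    returns all results in sampling order.  A configuration whose
    backend fails is logged and recorded with ``error = nan`` rather
    than aborting the sweep.  Results are a deterministic function of
    ``seed`` regardless of ``n_jobs``.
    """
    if space is None:
        space = full_space(data.p)
    configs = sample_configurations(space, n_configs, seed, per_method=per_method)
    # one base seed per configuration, derived from the master seed
    child_seeds = np.random.SeedSequence(seed).generate_state(len(configs)) % (
        2**31 - 1
    )
    cor = FeatureCorrelationMatrix.from_data(data.matrix())

    def run(i, config):
        try:
            return evaluate_configuration(
                data,
                config,
                folds=folds,
                measures=measures,
                alphas=alphas,
                seed=int(child_seeds[i]),
                cor=cor,
            )
        except Exception as exc:  # noqa: BLE001 - sweep keeps going
            logger.warning("configuration %s failed: %s", config.label(), exc)
            return EvaluationResult(
                configuration=config,
                error=float("nan"),
                size=float("nan"),
                ensemble=SelectionEnsemble(p=data.p, sets=(frozenset(), frozenset())),
                stability={},
                folds=folds,
                seed=int(child_seeds[i]),
            )

    if n_jobs == 1:
        results = []
        for i, config in enumerate(configs):
            logger.info("evaluating %d/%d: %s", i + 1, len(configs), config.label())
            results.append(run(i, config))
        return results
    return Parallel(n_jobs=n_jobs)(
        delayed(run)(i, c) for i, c in enumerate(configs)
    )
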