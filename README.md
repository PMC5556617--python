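# stabsel

Stability-aware multicriteria selection of sparse predictive models on
high-dimensional data.

On gene-expression-scale problems (p ≫ n, two classes) many different
feature subsets predict equally well, so a model chosen only by
cross-validated error typically rests on a feature set that changes
wholesale under resampling — a problem for anyone who wants to interpret
the selected genes. `stabsel` is for biostatisticians and machine-learning
practitioners who want to pick a *configuration* — a univariate filter
(variance, AUC, or greedy MRMR), its feature count, a classifier
(componentwise GLM boosting, lasso logistic regression, random forest,
RBF-SVM) and hyperparameters — by jointly considering three criteria:

* **error** — mean misclassification rate over k cross-validation folds,
* **size** — mean number of features the fold models actually use (the
  cascade of filter and embedded selection),
* **stability** — how similar the selected sets V₁..V_m across folds are.

Nine stability measures are implemented: the pairwise Jaccard (SJ), Dice
(SD), Ochiai (SO) indices, a correlation-adjusted Jaccard (SZ) in which
different but highly correlated features still count as agreement, the
chance-corrected index of Lustgarten et al. (SL), the entropy-based
consistency (SN), the frequency measure of Davis et al. with sparsity
penalty α (SD-α), the relative weighted consistency (SS), and the mean
Pearson correlation of the selection indicator vectors (SC, the phi
coefficient), e.g.

SJ = 2/(m(m−1)) Σ_{i<j} |V_i ∩ V_j| / |V_i ∪ V_j|,  SC = 2/(m(m−1)) Σ_{i<j} Cor(z_i, z_j),

with z_i ∈ {0,1}^p the indicator of V_i. SL, SS and SC are corrected for
chance: their expected value under random selection does not grow with
the number of selected features. Configurations within an *accuracy
band* (error ≤ c* + 0.05, c* the best observed error) are then filtered
to the Pareto front over (1 − stability, size), exposing sparse, stable
models that give up almost no accuracy.

## Worked example

Evaluate one configuration — AUC filter keeping 10 features, then lasso
logistic regression — by 10-fold CV on a generated data set with 150
samples, 300 features, 5 of them informative
(`examples/evaluate_configuration.py`):

```python
from stabsel import Configuration, GeneratorSpec, evaluate_configuration, make_dataset

data = make_dataset(GeneratorSpec(seed=7))
config = Configuration(filter="auc", n_feats=10,
                       classifier="lasso-logreg", params={"lambda": 1.0})
res = evaluate_configuration(data, config, folds=10, seed=1,
                             measures=["SJ", "SC", "SD-alpha"], alphas=[1])
```

prints

```
mean misclassification rate: 0.020
mean number of chosen features: 8.6
stability SJ: 0.651
stability SC: 0.779
stability SD-1: 0.586
```

2% of held-out samples are misclassified; on average 8.6 of the 10
filtered features survive the lasso; every fold keeps the 5 informative
features (0–4) but the folds disagree on the noise features they add,
which is what SJ = 0.651 < 1 quantifies. A small random search plus the
band/Pareto step (`examples/pareto_band_analysis.py`) then prints, per
front member, lines such as

```
error=0.008  size=  5.0  SC=1.000  variance+glmboost(n_feats=20, m_stop=69)
```

— a configuration whose ten fold models use the identical 5 features
(SC = 1) at near-best error: the sparse, stable alternative to the
accuracy-optimal pick.

The same steps are available from the shell via the `stabsel` CLI
(`simulate`, `filter`, `stability`, `tune`, `pareto`); every run writes
a manifest with resolved parameters, seed and input hashes next to its
output.

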