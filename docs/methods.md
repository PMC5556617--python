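# Methods

## Problem setting

High-dimensional two-class prediction problems — microarray or RNA-seq
matrices with thousands of gene-expression features and a few hundred
samples — admit many distinct feature subsets with nearly identical
predictive accuracy. A model chosen purely by cross-validated error will
often rest on a feature set that changes wholesale when the data are
resampled, which undermines any biological reading of the selected
genes. `stabsel` treats model selection as a multicriteria problem: a
*configuration* (a univariate filter, its feature count `n.feats`, a
classifier family and its hyperparameters) is scored on three criteria —
cross-validated misclassification rate, mean model size, and the
*stability* of the feature selection across folds — and the
configurations worth considering are the Pareto-optimal ones.

## Stability measures

Resampling a data set m times and selecting features each time yields
sets V₁..V_m over p candidate features, with cardinalities |V_i|,
selection counts h_j (number of sets containing feature j),
q = Σ_j h_j, and indicator vectors z_i ∈ {0,1}^p. All measures map an
ensemble to a single number; larger is more stable.

Pairwise measures average a set-similarity score over all m(m−1)/2
unordered pairs:

| id | pairwise score for (V_i, V_j) |
|----|-------------------------------|
| SJ | \|V_i∩V_j\| / \|V_i∪V_j\| (Jaccard) |
| SD | 2\|V_i∩V_j\| / (\|V_i\|+\|V_j\|) (Dice) |
| SO | \|V_i∩V_j\| / √(\|V_i\|·\|V_j\|) (Ochiai) |
| SZ | (\|V_i∩V_j\| + c_ij + d_ij) / \|V_i∪V_j\| (correlation-adjusted Jaccard) |
| SL | (\|V_i∩V_j\| − \|V_i\|\|V_j\|/p) / (min(\|V_i\|,\|V_j\|) − max(0, \|V_i\|+\|V_j\|−p)) |
| SC | Pearson correlation of z_i and z_j (= phi coefficient of their 2×2 table) |

For SZ, c_ij sums, over x ∈ V_i and y ∈ V_j∖V_i, the correlations
Cor(x,y) exceeding the median correlation r_ij among all distinct
feature pairs of V_i∪V_j, scaled by 1/|V_j| (d_ij symmetrically); two
different but strongly correlated features then still count toward
agreement. With all off-diagonal correlations zero, SZ equals SJ
exactly.

Frequency measures use the counts h_j:

* **SN** (entropy-based): (1/(q·log₂m)) Σ_{j∈V} h_j log₂ h_j, with
  V = ∪V_i.
* **SD-α** (Davis): max(0, (1/|V|) Σ_j h_j/m − α·median(|V₁|..|V_m|)/p);
  α ≥ 0 trades frequency reward against a model-size penalty.
* **SS** (relative weighted consistency): the weighted consistency
  D = Σ_j (h_j/q)(h_j−1)/(m−1) rescaled by its extremes c_min, c_max
  attainable at the observed q, giving a value in [0,1].

Key theoretical properties: SJ, SD, SO, SZ, SN and SD-0 attain exactly 1
for a deterministic selection of the same k features (0 < k < p); SD-α
then attains only max(0, 1 − kα/p); SL attains 1 − k/p for k < p/2; SS
can attain 1 even for non-deterministic ensembles (e.g. m=2, V₁={0,1},
V₂={0}). SL, SS and SC are corrected for chance: under uniformly random
k-subset selection their expectation does not grow with k, whereas the
uncorrected measures increase toward 1 as k → p. The acceptance suite
verifies all of this, and checks every measure against an independently
coded brute-force oracle to 1e-12.

Ranges: SJ, SD, SO, SZ, SN, SS ∈ [0,1]; SL, SC ∈ [−1,1]; SD-α ∈
[0, max(1−α/p, 1/(m(m−1)/2))].

## Degenerate inputs

The corrected measures are undefined on degenerate ensembles and the
package raises typed errors rather than imputing values: empty sets
(`EmptySetError`) for all pairwise measures, q = 0 for SN/SS, an empty
union for SD-α; a vanishing SL pair denominator, c_max = c_min for SS,
and constant indicator vectors (|V_i| ∈ {0, p}) for SC raise
`DegenerateSelectionError`. The dispatcher `all_stabilities` converts
these into explicit *undefined* scores carrying the reason, and the
serialization layer writes them as null, never as a numeric sentinel.
Constant features make Pearson correlations undefined; the correlation
matrix stores them as NaN and SZ rejects ensembles whose union touches
one (`UndefinedCorrelationError`).

## Numerical and tie-breaking choices

* SZ's threshold indicator is interpreted **strictly** (Cor > r_ij, the
  open interval); consequently, for a two-feature union the single
  correlation never exceeds its own median and SZ reduces to SJ there.
  The helper is written so the closed variant is a one-argument switch.
* The median in SD-α and in r_ij is the standard sample median (mean of
  the two central order statistics for even counts).
* Score ties in the filters and in top-k selection always break toward
  the lowest feature index. This is not cosmetic: tie handling directly
  affects measured stability, so it is fixed and documented.
* MRMR's first pick maximizes relevance (redundancy over an empty set is
  taken as undefined, not zero). Later candidates with redundancy
  exactly 0 get quotient +∞ and are ranked among themselves by
  relevance, then by index. The often-claimed monotone decrease of the
  greedy quotient is *not* assumed: all candidate quotients are computed
  at every step (the example runs show the quotient is in fact not
  monotone).
* Variance uses the unbiased n−1 denominator; only the ranking matters.
* AUC is computed rank-based with midrank tie handling (normalized
  Mann–Whitney U); the filter score is |0.5 − AUC| ∈ [0, 0.5], so
  perfect separation and perfect anti-separation are equally
  informative.
* "Attains the theoretical maximum" assertions use an absolute
  tolerance of 1e-9.

## Cross-validated configuration evaluation

`evaluate_configuration` runs stratified k-fold CV (default k = 10).
Stratification is by class, with fold sizes differing by at most one
both overall and per class; the split is a pure function of the seed.
Within each fold the filter is fitted on the training rows only, the
classifier is fitted on the filtered training matrix, and the held-out
rows are predicted; leakage-freedom is asserted by tests that corrupt
held-out rows and require identical selections.

Feature extraction per classifier family:

* **lasso-logreg** — L1-penalized logistic regression
  (scikit-learn/liblinear, C = 1/λ); features with nonzero coefficients.
* **glmboost** — componentwise gradient boosting for the logistic loss,
  implemented in-package: each of `m_stop` iterations fits a
  one-feature linear least-squares base learner to the negative
  gradient and takes a damped step (learning rate 0.1); a feature is
  selected iff its base learner was used in ≥ 1 iteration.
* **random-forest** — scikit-learn forest with `num.trees` and
  `min.node.size`; features with impurity importance strictly > 0.
* **svm-rbf** — RBF-kernel SVM (γ = σ); no embedded selection, all
  features entering the model count as selected.

The SZ correlation context inside CV is computed once on the full data
matrix (passing a per-fold matrix would silently change r_ij between
pairs); `evaluate_configuration` accepts an explicit `cor` argument for
callers who want a different convention. Probabilistic predictors are
thresholded at 0.5.

## Random search and the desk-scale space

`random_search` samples configurations per augmented method
(filter × classifier; 3 × 4 = 12 methods by default) or round-robin to a
fixed total. Integer parameters are uniform on their sets; λ, σ, C are
sampled as 2^x with x uniform on [−15, 15]. The full space
(`full_space`) uses n.feats ∈ {1..p}, m_stop, num.trees ∈ {1..2¹⁵},
min.node.size ∈ {1..2⁵}. The built-in studies use `desk_space`, which
keeps the identical shape and distributions but caps num.trees at 2¹⁰
and m_stop at 2¹², the package's choice of problem size for
single-workstation runs; the reachable model classes are unchanged
(forests of ≥ 1000 trees and boosting paths of ≥ 4000 steps are already
deep in their plateau on n ≈ 150 data). The end-to-end study evaluates
200 configurations by 10-fold CV on the default generator data set; all
randomness derives from one master seed through per-configuration child
seeds, so results are independent of parallelization.

Backend failures inside a sweep are logged and recorded as NaN-error
results rather than aborting the run.

## Accuracy band and Pareto analysis

All criteria are minimized; stability enters as 1 − stability. The
band2d analysis computes c* (the best CV error among all candidates),
retains configurations with error ≤ c* + δ (default δ = 0.05), and
extracts the Pareto front over (1 − stability, size); the 3d mode skips
the band and uses (error, 1 − stability, size). The front is an O(n²)
dominance scan; duplicate criteria vectors are all kept because each
carries a distinct configuration. Configurations with an undefined
stability value are excluded from that measure's front with a warning
(`strict=True` raises instead). c* is global across all augmented
methods, not per method.

## Synthetic data generator

The generator emulates two-class expression-like data: all features are
unit-variance Gaussian noise; `n_informative` features receive a class
mean shift of ±effect/2 (effect in noise-SD units, default 2);
correlated blocks of given size share a latent factor,
x = √ρ·f + √(1−ρ)·ε, so every within-block pair has correlation exactly
ρ in expectation (default one block of 10 at ρ = 0.9, placed after the
informative features unless `blocks_overlap_informative` is set). Class
counts are deterministic (round(n·balance)), so both classes are always
present. Defaults — n = 150, p = 300, 5 informative, effect 2 — define
the desk-scale study condition used by the tests and the acceptance
script.

What the generator does **not** emulate: count-valued RNA-seq data
(negative binomial, library-size effects), batch effects, missing
values, heavy-tailed or heteroscedastic noise, and realistic
correlation structure beyond exchangeable blocks. Tests passing on this
generator therefore validate the machinery and its qualitative
behaviour (e.g. that sparse, stable configurations exist inside the
accuracy band), not quantitative claims about any particular real data
set.

## Known limitations

* Classifier backends follow the stated extraction contracts but are
  not numerically equivalent to other implementations of the same
  families; regularization-path details (e.g. liblinear's penalized
  intercept) differ across libraries.
* The O(n²) front scan is quadratic; fine up to tens of thousands of
  configurations, not for millions.
* Only binary classification is supported; the AUC filter has no
  multi-class generalization here.
* SZ requires a full p×p correlation matrix (O(p²) memory); for very
  large p a chunked implementation would be needed.
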