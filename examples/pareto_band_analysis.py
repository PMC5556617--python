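"""Find sparse, stable configurations without giving up accuracy.

Runs a small random search over filter + classifier configurations on a
synthetic data set, restricts to the accuracy band (error within 0.05 of
the best), and extracts the Pareto front over (1 - stability, model
size).  Front members are sparse AND stable while staying near the best
achievable error — the alternative to picking purely by accuracy.
"""

import numpy as np

from stabsel import (
    GeneratorSpec,
    SearchSpace,
    accuracy_band,
    desirable_configurations,
    make_dataset,
    random_search,
)

data = make_dataset(GeneratorSpec(n=120, p=150, n_informative=5, seed=3))
space = SearchSpace(max_n_feats=data.p, max_m_stop=2**9, max_num_trees=2**7)
results = random_search(data, space, n_configs=48, seed=11, folds=5,
                        measures=["SC"], alphas=[])
ok = [r for r in results if np.isfinite(r.error)]

band = accuracy_band(ok, delta=0.05)
print(f"best CV error c* = {band.c_star:.3f}; "
      f"{len(band.retained)}/{len(ok)} configurations inside c* + 0.05")

front = desirable_configurations(ok, measure="SC", delta=0.05, mode="band2d")
print(f"{len(front)} Pareto-optimal configuration(s) over (1 - SC, size):")
for pt in front:
    r = pt.result
    print(f"  error={r.error:.3f}  size={r.size:5.1f}  "
          f"SC={r.stability_value('SC'):.3f}  {r.configuration.label()}")

# Each front line is a configuration no other band member beats in both
# stability and sparsity simultaneously; choosing among them trades a
# smaller model against a more reproducible feature selection.
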