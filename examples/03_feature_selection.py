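"""Wrapper feature selection with the Aquila Optimizer.

Continuous positions in [0, 1]^D are thresholded into binary masks and
scored by F = mu * cv_error + (1 - mu) * subset_fraction; the optimizer
searches for the mask minimizing F.
"""

from dermao.ao import AOConfig
from dermao.selection import FSConfig, select_features
from dermao.synthetic import SyntheticFeatureSpec, gen_feature_dataset

spec = SyntheticFeatureSpec(
    n_samples=200, n_features=20, n_informative=4, effect_size=2.0, seed=3
)
X, y, informative = gen_feature_dataset(spec)

config = FSConfig(ao=AOConfig(pop_size=15, max_iter=40, seed=3), cv_folds=5, seed=3)
result = select_features(X, y, config)

recovered = set(result.mask.indices.tolist())
print(f"features: {result.features_before} -> {result.features_after} "
      f"({result.reduction_pct:.2f}% reduction)")
print(f"cross-validated error of the selected subset: {result.cv_error:.4f}")
print(f"wrapper fitness (lower is better): {result.fitness:.4f}")
print(f"planted informative: {sorted(informative)}")
print(f"selected:            {sorted(recovered)}")
print(f"planted columns recovered: {len(recovered & informative)}/{len(informative)} "
      "(extra noise columns can survive when they do not hurt the CV error)")
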