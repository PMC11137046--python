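"""Fit a simultaneous regression+classification forest and query it.

Builds a small synthetic expression-like dataset with an imbalanced binary
response, fits the class-weighted forest, and prints a point prediction,
the class-vote proportions, and a conditional 5%-95% quantile pair for one
held-out sample.  The vote proportion is the forest's certainty notion; the
quantile pair brackets the plausible continuous response.
"""

import numpy as np

from sauroncp import (ForestParams, GeneratorConfig, compute_sample_weights,
                      fit_forest, make_regression_classification)

cfg = GeneratorConfig(n_samples=400, n_features=20, seed=7)
fm, bundle, _ = make_regression_classification(cfg)

weights = compute_sample_weights(bundle, "simple")
print(f"class counts: {bundle.scheme.counts}  ->  "
      f"minority weight {weights.w_star.max():.2f}")

forest = fit_forest(fm, bundle, weights, ForestParams(n_trees=100, seed=1))

x = fm.values[0]
pred = forest.predict(x)
q05, q95 = forest.predict_quantile(x, [0.05, 0.95])
print(f"sample {fm.sample_ids[0]}: true y = {bundle.y[0]:+.3f}, "
      f"true class = {bundle.d[0]}")
print(f"point value = {pred.point_value:+.3f}, point class = {pred.point_class}, "
      f"votes = {np.round(pred.class_votes, 2)}")
print(f"5%-95% conditional quantiles = [{q05:+.3f}, {q95:+.3f}]")
print("a wide quantile pair signals an unreliable continuous prediction")
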