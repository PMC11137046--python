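import numpy as np
import pytest

from sauroncp import (ForestParams, GeneratorConfig, ResponseBundle,
                      compute_sample_weights, fit_forest,
                      make_regression_classification, make_split)


@pytest.fixture(scope="session")
def small_dataset():
    """Small seeded regression+classification dataset (N=120, P=6)."""
    cfg = GeneratorConfig(n_samples=120, n_features=6, n_informative=3,
                          noise_sd=0.3, class_fractions=(0.3, 0.7), seed=11)
    fm, bundle, truth = make_regression_classification(cfg)
    return fm, bundle, truth


@pytest.fixture(scope="session")
def small_forest(small_dataset):
    """Forest on the small dataset, with bootstraps retained for oracles."""
    fm, bundle, _ = small_dataset
    w = compute_sample_weights(bundle, "simple")
    params = ForestParams(n_trees=10, min_leaf=3, seed=5)
    return fit_forest(fm, bundle, w, params, store_bootstraps=True)


@pytest.fixture(scope="session")
def small_split(small_dataset):
    fm, _, _ = small_dataset
    return make_split(fm.sample_ids, alpha=0.1, seed=7)


def make_uniform_bundle(rng, n=40):
    """Balanced binary bundle: simple weights are all 1."""
    y = rng.standard_normal(n)
    t = float(np.median(y))
    if np.any(y == t):  # nudge ties off the threshold
        y = y + 1e-9 * rng.standard_normal(n)
        t = float(np.median(y))
    return ResponseBundle.from_continuous(y, [t])
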