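import numpy as np
import pytest

from dendrorecon.chronology import build_chronology
from dendrorecon.synthetic import (ClimateSimConfig, ForestSimConfig,
                                   simulate_climate, simulate_forest)
from dendrorecon.types import pool


@pytest.fixture(scope="session")
def small_climate():
    """A 300-yr synthetic climate with no injected cycles (fast fixture)."""
    cfg = ClimateSimConfig(first_year=1719, n_years=300, seed=42)
    mc, truth = simulate_climate(cfg)
    return mc, truth


@pytest.fixture(scope="session")
def small_forest(small_climate):
    """A 2-site, 4-tree forest over the 300-yr climate."""
    mc, _ = small_climate
    cfg = ForestSimConfig(n_sites=2, trees_per_site=4, min_tree_age=120,
                          max_tree_age=280, seed=7)
    sites, truth = simulate_forest(cfg, mc)
    return sites, truth


@pytest.fixture(scope="session")
def small_chronology(small_forest):
    sites, _ = small_forest
    return build_chronology(pool(sites))


def ar1_series(rng, n, phi, sd=1.0):
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    c = sd * np.sqrt(1 - phi ** 2)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + rng.normal(0, c)
    return x
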