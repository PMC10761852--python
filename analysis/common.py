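"""Shared setup for the analysis drivers: one seeded study, one results tree.

Every numbered script re-simulates the same deterministic study (seed 1,
719-yr climate, 3 sites x 8 trees x 2 cores) and runs its own stage, so
each can be run standalone and in any order.
"""

from __future__ import annotations

import os

SEED = 1
RESULTS = os.path.join(os.path.dirname(__file__), "..", "results")
CAL_SPAN = (1965, 2018)
SEASON = [2, 3, 4, 5, 6]  # Feb-Jun


def results_path(*parts: str) -> str:
    path = os.path.join(RESULTS, *parts)
    os.makedirs(os.path.dirname(path), exist_ok=True)
    return path


def study(seed: int = SEED):
    """The default tuned study: (climate, climate_truth, sites, forest_truth)."""
    from dendrorecon.synthetic import (default_study_conditions, simulate_climate,
                                       simulate_forest)
    ccfg, fcfg = default_study_conditions(seed=seed)
    climate, ctruth = simulate_climate(ccfg)
    sites, ftruth = simulate_forest(fcfg, climate)
    return climate, ctruth, sites, ftruth


def composite_chronology(sites):
    from dendrorecon.chronology import build_chronology
    from dendrorecon.types import pool
    return build_chronology(pool(sites))
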