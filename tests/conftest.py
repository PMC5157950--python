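"""Shared fixtures.

The expensive evolutionary experiments (deterministic winner recovery and the
stochastic environment sweep on the reduced grid) are session-scoped so the
acceptance tests and the assay tests share a single computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from sporeloner import (
    EnvironmentSpec,
    LifeHistoryParams,
    REDUCED_GRID_SPEC,
    build_genotype_grid,
    run_evolution,
)
from sporeloner.config import seeded_rng

# environments for the scaled-down stochastic regime experiments: mean
# starvation times from fast (10 h) to slow (1e4 h); horizons grow with the
# cycle length so every run spans a few hundred to ten thousand cycles.
STOCHASTIC_CASES: list[tuple[float, float]] = [
    (10.0, 1e5),
    (31.6, 3e5),
    (100.0, 3e5),
    (200.0, 3e5),
    (316.0, 3e5),
    (1000.0, 3e5),
    (1e4, 1e6),
]
MASTER_SEED = 20260928


@pytest.fixture(scope="session")
def params() -> LifeHistoryParams:
    return LifeHistoryParams()


@pytest.fixture(scope="session")
def reduced_grid(params):
    return build_genotype_grid(REDUCED_GRID_SPEC, params)


@pytest.fixture(scope="session")
def deterministic_winners(params, reduced_grid):
    """Winner-recovery runs at T = 10, 158 and 199 h (reduced grid,
    1e6-hour horizon)."""
    out = {}
    for T in (10.0, 158.0, 199.0):
        env = EnvironmentSpec("deterministic", T=T, horizon=1e6)
        rng = seeded_rng(MASTER_SEED, f"det:{T}")
        out[T] = run_evolution(reduced_grid, env, params, rng)
    return out


@pytest.fixture(scope="session")
def stochastic_results(params, reduced_grid):
    """Reduced-grid winners across the stochastic lambda_T range,
    5 replicates each."""
    out = {}
    for lam, horizon in STOCHASTIC_CASES:
        env = EnvironmentSpec(
            "stochastic", lambda_T=lam, horizon=horizon, n_runs=5
        )
        rng = seeded_rng(MASTER_SEED, f"stoch:{lam}")
        out[lam] = run_evolution(reduced_grid, env, params, rng)
    return out


@pytest.fixture(scope="session")
def stochastic_winner_set(stochastic_results):
    """Unique winning genotypes ordered from fastest to slowest environment
    (the in-silico analogue of a strain collection)."""
    winners = []
    for lam in sorted(stochastic_results):
        w = stochastic_results[lam].winner
        if all(w.trait != o.trait or w.c != o.c for o in winners):
            winners.append(w)
    return winners
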