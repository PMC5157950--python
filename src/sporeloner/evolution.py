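"""Long-run genotype competition through many growth-starvation cycles.

An environment is characterised only by how food comes back: either every
starvation period lasts exactly ``T`` hours (deterministic), or the periods
are drawn i.i.d. from an exponential distribution with mean ``lambda_T``
(stochastic).  Each cycle delivers an identical resource pulse ``R0``.  All
genotypes on a grid compete for the shared pool; competitive exclusion leaves
a single winning strategy, identified as the most abundant genotype (spores +
solitary cells) at the first starvation onset at or after the time horizon.

Stochastic environments are replicated ``n_runs`` times with independent
seeds; the reported winner maximises the mean relative abundance across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cycle_dynamics import (
    ExtinctionError,
    PopulationState,
    run_cycle,
)
from .life_history import Genotype, LifeHistoryParams

__all__ = [
    "EnvironmentSpec",
    "EvolutionResult",
    "draw_starvation_time",
    "initialize_population",
    "run_evolution",
    "winner_sweep",
]

# hard stop against pathological configurations (e.g. horizon >> cycle length)
MAX_CYCLES = 20_000_000


@dataclass(frozen=True)
class EnvironmentSpec:
    """Feast-famine regime: resource pulses separated by starvation periods.

    ``kind`` is ``"deterministic"`` (fixed period ``T`` hours) or
    ``"stochastic"`` (exponential periods with mean ``lambda_T`` hours).
    ``R0`` is the pulse magnitude, ``horizon`` the simulated time span in
    hours, ``n_runs`` the number of independent replicates (stochastic only),
    ``initial_cells`` the total population the run starts from.
    """

    kind: str
    T: float | None = None
    lambda_T: float | None = None
    R0: float = 1e8
    horizon: float = 1e6
    n_runs: int = 1
    initial_cells: float = 1e8

    def __post_init__(self) -> None:
        if self.kind not in ("deterministic", "stochastic"):
            raise ValueError(f"unknown environment kind {self.kind!r}")
        if self.kind == "deterministic":
            if self.T is None or not self.T > 0:
                raise ValueError("deterministic environments need T > 0")
        else:
            if self.lambda_T is None or not self.lambda_T > 0:
                raise ValueError("stochastic environments need lambda_T > 0")
        if not (self.R0 > 0 and self.horizon > 0 and self.initial_cells > 0):
            raise ValueError("R0, horizon and initial_cells must be > 0")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    @property
    def timescale(self) -> float:
        return self.T if self.kind == "deterministic" else self.lambda_T  # type: ignore[return-value]

    def describe(self) -> str:
        if self.kind == "deterministic":
            return f"deterministic T={self.T:g} h"
        return f"stochastic lambda_T={self.lambda_T:g} h"


@dataclass
class EvolutionResult:
    """Outcome of one environment's competition."""

    environment: EnvironmentSpec
    genotypes: tuple[Genotype, ...]
    winner: Genotype
    winner_index: int
    # mean (over runs) relative abundance per genotype at measurement
    relative_abundance: np.ndarray
    per_run_winners: list[Genotype]
    per_run_cycles: list[int]
    metadata: dict = field(default_factory=dict)

    @property
    def n_cycles(self) -> int:
        return int(np.mean(self.per_run_cycles))


def draw_starvation_time(env: EnvironmentSpec, rng: np.random.Generator) -> float:
    """One starvation period: exactly T, or an exponential variate (mean
    lambda_T) for stochastic environments."""
    if env.kind == "deterministic":
        return float(env.T)  # type: ignore[arg-type]
    return float(rng.exponential(env.lambda_T))


def initialize_population(
    grid: Sequence[Genotype],
    total: float,
    rng: np.random.Generator,
    R: float = 0.0,
) -> PopulationState:
    """Initial vegetative abundances: i.i.d. standard log-normal draws,
    normalised so the whole population holds exactly ``total`` cells."""
    grid = tuple(grid)
    if len(grid) == 0:
        raise ValueError("empty genotype grid")
    draws = rng.lognormal(mean=0.0, sigma=1.0, size=len(grid))
    veg = draws * (total / draws.sum())
    return PopulationState.growth(grid, veg, R=R)


def _single_run(
    grid: tuple[Genotype, ...],
    env: EnvironmentSpec,
    params: LifeHistoryParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """One trajectory; returns (onset abundance at measurement, cycle count)."""
    state = initialize_population(grid, env.initial_cells, rng, R=env.R0)
    cycles = 0
    while True:
        T = draw_starvation_time(env, rng)
        state, record = run_cycle(state, T, params)
        cycles += 1
        onset_clock = state.clock - record.starvation_duration
        if onset_clock >= env.horizon:
            abundance = record.onset_abundance
            assert abundance is not None
            if float(abundance.sum()) <= 0.0:
                raise ExtinctionError(
                    "population extinct before the measurement point"
                )
            return abundance, cycles
        state.R = env.R0  # next pulse
        if cycles >= MAX_CYCLES:  # pragma: no cover
            raise RuntimeError("cycle budget exceeded before reaching horizon")


def run_evolution(
    grid: Sequence[Genotype],
    env: EnvironmentSpec,
    params: LifeHistoryParams,
    rng: np.random.Generator,
) -> EvolutionResult:
    """Compete every genotype of ``grid`` in environment ``env``.

    Deterministic environments use a single trajectory (initial-condition
    randomness does not change the winner); stochastic ones average the
    relative abundances over ``n_runs`` independent replicates.  The winner is
    the argmax of the (mean) relative abundance measured at the first
    starvation onset at or after the horizon.  Raises
    :class:`~sporeloner.cycle_dynamics.ExtinctionError` if every pool dies
    out, which is possible e.g. for all-non-aggregator grids in environments
    with starvation periods beyond T_sur.
    """
    grid = tuple(grid)
    n_runs = env.n_runs if env.kind == "stochastic" else 1
    rel = np.zeros(len(grid))
    per_run_winners: list[Genotype] = []
    per_run_cycles: list[int] = []
    for _ in range(n_runs):
        abundance, cycles = _single_run(grid, env, params, rng.spawn(1)[0])
        r = abundance / abundance.sum()
        rel += r
        per_run_winners.append(grid[int(np.argmax(r))])
        per_run_cycles.append(cycles)
    rel /= n_runs
    idx = int(np.argmax(rel))
    return EvolutionResult(
        environment=env,
        genotypes=grid,
        winner=grid[idx],
        winner_index=idx,
        relative_abundance=rel,
        per_run_winners=per_run_winners,
        per_run_cycles=per_run_cycles,
        metadata={"n_runs": n_runs},
    )


def winner_sweep(
    environments: Sequence[EnvironmentSpec],
    grid: Sequence[Genotype],
    params: LifeHistoryParams,
    rng: np.random.Generator,
) -> list[EvolutionResult]:
    """Run :func:`run_evolution` for each environment with independent,
    reproducible RNG streams (one spawn per environment, in order)."""
    grid = tuple(grid)
    streams = rng.spawn(len(environments))
    return [
        run_evolution(grid, env, params, stream)
        for env, stream in zip(environments, streams)
    ]


def default_stochastic_sweep(
    n_envs: int = 31,
    lo: float = 10.0,
    hi: float = 1e4,
    horizon: float = 1e6,
    n_runs: int = 20,
    R0: float = 1e8,
    initial_cells: float = 1e8,
) -> list[EnvironmentSpec]:
    """Log-spaced stochastic environments from fast (lambda_T = 10 h) to slow
    (lambda_T = 1e4 h); 31 of them by default, labelled 0..30."""
    return [
        EnvironmentSpec(
            "stochastic", lambda_T=float(lam), R0=R0, horizon=horizon,
            n_runs=n_runs, initial_cells=initial_cells,
        )
        for lam in np.geomspace(lo, hi, n_envs)
    ]


def default_deterministic_sweep(
    n_envs: int = 25,
    lo: float = 10.0,
    hi: float = 1e3,
    horizon: float = 1e6,
    R0: float = 1e8,
    initial_cells: float = 1e8,
) -> list[EnvironmentSpec]:
    """Log-spaced deterministic environments, T from 10 h to 1e3 h."""
    return [
        EnvironmentSpec(
            "deterministic", T=float(T), R0=R0, horizon=horizon,
            initial_cells=initial_cells,
        )
        for T in np.geomspace(lo, hi, n_envs)
    ]
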