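"""Growth-starvation cycle mechanics against independent ODE oracles."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from sporeloner.cycle_dynamics import (
    ExtinctionError,
    IntegrationError,
    MechanismMismatchError,
    PopulationState,
    aggregation_time,
    continuous_starvation,
    germinate,
    integrate_growth,
    partition_discrete,
    run_cycle,
    starve_discrete,
)
from sporeloner.life_history import Genotype, LifeHistoryParams, survival_hazard, survival_probability


def _discrete(alpha, c):
    return Genotype("discrete", c=c, alpha=alpha)


def _reference_growth(X0, R0, cs, R_half, t_end):
    """Independent fine-tolerance integration of the consumer-resource ODEs."""

    def rhs(_t, y):
        X, R = y[:-1], max(y[-1], 0.0)
        phi = R / (R_half + R)
        dX = cs * phi * X
        return np.append(dX, -phi * float(np.dot(cs, X)))

    sol = solve_ivp(rhs, (0.0, t_end), np.append(X0, R0), method="LSODA",
                    rtol=1e-12, atol=1e-6)
    assert sol.success
    return sol.y[:-1, -1], sol.y[-1, -1]


# ---------------------------------------------------------------------------
# growth


def test_growth_conserves_cells_plus_resources(params):
    state = PopulationState.growth([_discrete(0.5, 0.2)], [1e3], R=1e8)
    out, elapsed = integrate_growth(state, params)
    assert out.phase == "starvation"
    assert out.R == 0.0
    assert elapsed > 0.0
    assert float(out.veg.sum()) == pytest.approx(1.00001e8, rel=1e-8)


def test_growth_conservation_multi_genotype(params):
    rng = np.random.default_rng(7)
    gens = [_discrete(a, c) for a in (0.0, 0.5, 1.0) for c in (0.05, 0.2, 0.45)]
    X0 = rng.uniform(1e2, 1e6, len(gens))
    R0 = 3e7
    state = PopulationState.growth(gens, X0, R=R0)
    out, _ = integrate_growth(state, params)
    assert float(out.veg.sum()) == pytest.approx(X0.sum() + R0, rel=1e-8)
    assert np.all(out.veg >= X0)  # every genotype is non-decreasing


def test_growth_zero_resources_is_a_no_op(params):
    state = PopulationState.growth([_discrete(0.5, 0.2)], [1e3], R=0.0)
    out, elapsed = integrate_growth(state, params)
    assert elapsed == 0.0
    assert float(out.veg.sum()) == 1e3


def test_faster_divider_wins_growth_and_matches_reference(params):
    gens = [_discrete(0.0, 0.1), _discrete(0.0, 0.2)]
    state = PopulationState.growth(gens, [1e3, 1e3], R=1e8)
    out, elapsed = integrate_growth(state, params)
    assert out.veg[1] > out.veg[0]
    ref_X, ref_R = _reference_growth(
        np.array([1e3, 1e3]), 1e8, np.array([0.1, 0.2]), params.R_half, elapsed
    )
    assert out.veg == pytest.approx(ref_X, rel=1e-6)


def test_partial_growth_matches_reference(params):
    gens = [_discrete(0.0, 0.1), _discrete(0.0, 0.3)]
    state = PopulationState.growth(gens, [1e4, 1e4], R=1e8)
    out, elapsed = integrate_growth(state, params, t_limit=10.0)
    assert elapsed == 10.0
    assert out.phase == "growth"
    assert 0.0 < out.R < 1e8
    ref_X, ref_R = _reference_growth(
        np.array([1e4, 1e4]), 1e8, np.array([0.1, 0.3]), params.R_half, 10.0
    )
    assert out.veg == pytest.approx(ref_X, rel=1e-8)
    assert out.R == pytest.approx(ref_R, rel=1e-6)


def test_growth_without_cells_cannot_exhaust(params):
    state = PopulationState.growth([_discrete(0.5, 0.2)], [0.0], R=1e8)
    with pytest.raises(IntegrationError):
        integrate_growth(state, params)


# ---------------------------------------------------------------------------
# partitioning and discrete starvation


def test_partition_arithmetic(params):
    gens = [_discrete(0.5, 0.2), _discrete(0.0, 0.2), _discrete(1.0, 0.2)]
    state = PopulationState.growth(gens, [1000.0, 1000.0, 1000.0], R=0.0)
    state, _ = integrate_growth(state, params)  # flips to starvation
    onset = partition_discrete(state, params)
    assert onset.spores == pytest.approx([400.0, 0.0, 800.0], abs=1e-12)
    assert onset.solitary == pytest.approx([500.0, 1000.0, 0.0], abs=1e-12)
    assert onset.stalk == pytest.approx([100.0, 0.0, 200.0], abs=1e-12)
    # the three pools sum to X exactly
    total = onset.spores + onset.solitary + onset.stalk
    assert total == pytest.approx([1000.0, 1000.0, 1000.0], abs=0.0)


def test_partition_rejects_continuous(params):
    g = Genotype("continuous", c=0.2, gamma=0.1)
    state = PopulationState.growth([g], [1e3], R=0.0)
    state, _ = integrate_growth(state, params)
    with pytest.raises(MechanismMismatchError):
        partition_discrete(state, params)


def test_starve_discrete_closed_forms(params):
    gens = [_discrete(0.5, 0.2)]
    state = PopulationState.growth(gens, [2e6], R=0.0)
    state, _ = integrate_growth(state, params)
    onset = partition_discrete(state, params)
    # T = 0 leaves everything unchanged
    sp0, sol0 = starve_discrete(onset, 0.0, params)
    assert sp0 == pytest.approx(onset.spores, abs=0.0)
    assert sol0 == pytest.approx(onset.solitary, abs=0.0)
    # spores decay exponentially: 1e6 spores (alpha=0.5, s=0.8 on 2.5e6 cells)
    sp, sol = starve_discrete(onset, 100.0, params)
    assert sp[0] == pytest.approx(8e5 * math.exp(-0.01), rel=1e-12)
    assert sol[0] == pytest.approx(
        1e6 * survival_probability(0.2, 100.0, params), rel=1e-12
    )
    # beyond the maximum lifetime every solitary cell is dead
    _, sol_end = starve_discrete(onset, params.T_sur, params)
    assert sol_end[0] == 0.0
    with pytest.raises(ValueError):
        starve_discrete(onset, -1.0, params)


# ---------------------------------------------------------------------------
# continuous mechanism


def test_continuous_gamma_zero_never_aggregates(params):
    g = Genotype("continuous", c=0.15, gamma=0.0)
    pools = continuous_starvation(1e6, g, 50.0, params)
    assert pools["aggregated"] == 0.0
    assert pools["spores"] == 0.0
    assert pools["solitary"] == pytest.approx(
        1e6 * survival_probability(0.15, 50.0, params), rel=1e-12
    )


def test_continuous_solitary_closed_form(params):
    g = Genotype("continuous", c=0.15, gamma=0.1)
    pools = continuous_starvation(1.0, g, 10.0, params.with_(delta=0.0))
    assert pools["solitary"] == pytest.approx(0.36755419721889027, rel=1e-10)


def test_continuous_matches_ode_oracle(params):
    """Quadrature pools equal a fine-step integration of
    dN/dt = -(gamma + hazard) N, dA/dt = gamma N - delta A."""
    rng = np.random.default_rng(11)
    for _ in range(6):
        gamma = float(rng.uniform(0.01, 1.0))
        c = float(rng.uniform(0.05, 0.45))
        t_end = float(rng.uniform(5.0, 195.0))
        g = Genotype("continuous", c=c, gamma=gamma)

        def rhs(t, y):
            h = survival_hazard(c, min(t, params.T_sur - 1e-9), params)
            return [-(gamma + h) * y[0], gamma * y[0] - params.delta * y[1]]

        sol = solve_ivp(rhs, (0.0, t_end), [1.0, 0.0], method="LSODA",
                        rtol=1e-11, atol=1e-14)
        assert sol.success
        pools = continuous_starvation(1.0, g, t_end, params)
        assert pools["solitary"] == pytest.approx(sol.y[0, -1], rel=1e-6, abs=1e-12)
        assert pools["aggregated"] == pytest.approx(sol.y[1, -1], rel=1e-6)


def test_continuous_fast_aggregation_limit_matches_discrete(params):
    """gamma -> infinity reproduces the discrete all-aggregator strategy."""
    g = Genotype("continuous", c=0.15, gamma=1e3)
    pools = continuous_starvation(1e6, g, params.T_sur, params)
    discrete_spores = params.s * 1e6 * math.exp(-params.delta * params.T_sur)
    assert pools["spores"] == pytest.approx(discrete_spores, rel=1e-3)
    assert pools["solitary"] == 0.0


def test_continuous_monotone_in_gamma(params):
    t = 40.0
    sols = [
        continuous_starvation(
            1.0, Genotype("continuous", c=0.15, gamma=g), t, params
        )["solitary"]
        for g in (0.0, 0.05, 0.2, 1.0)
    ]
    assert all(a > b for a, b in zip(sols, sols[1:]))


def test_aggregation_time_properties(params):
    t0 = aggregation_time(Genotype("continuous", c=0.15, gamma=0.0), params)
    assert t0 == pytest.approx(params.T_sur, abs=1e-2)
    times = [
        aggregation_time(Genotype("continuous", c=0.15, gamma=g), params)
        for g in (0.0, 0.1, 0.5, 2.0)
    ]
    assert all(t <= params.T_sur for t in times)
    assert all(a >= b for a, b in zip(times, times[1:]))
    # coarser epsilon is reached no later than a finer one
    g = Genotype("continuous", c=0.15, gamma=0.1)
    assert aggregation_time(g, params, epsilon=0.5) <= aggregation_time(
        g, params, epsilon=1e-6
    )


# ---------------------------------------------------------------------------
# germination


def test_germination_viability_split(params):
    recruits, remaining = germinate(1e5, 0.45, params, resources_available=True)
    assert recruits == pytest.approx(2e4, rel=1e-12)
    assert remaining == 0.0
    recruits, remaining = germinate(1e5, 0.05, params, resources_available=True)
    assert recruits == pytest.approx(1e5, rel=1e-12)  # nu = 1: all recruit
    recruits, remaining = germinate(0.0, 0.45, params, resources_available=True)
    assert recruits == 0.0
    # no food at the end of the lag: spores stay dormant
    recruits, remaining = germinate(1e5, 0.45, params, resources_available=False)
    assert recruits == 0.0 and remaining == 1e5


# ---------------------------------------------------------------------------
# full cycles


def test_cycle_all_aggregators(params):
    X0, R0, T = 1e3, 1e8, 100.0
    state = PopulationState.growth([_discrete(1.0, 0.2)], [X0], R=R0)
    out, rec = run_cycle(state, T, params)
    expected = params.s * (X0 + R0) * math.exp(-params.delta * T)
    assert out.spores[0] == pytest.approx(expected, rel=1e-6)
    assert out.veg[0] == 0.0
    assert rec.onset_total == pytest.approx(X0 + R0, rel=1e-8)


def test_cycle_all_loners_die_out_in_long_starvation(params):
    state = PopulationState.growth([_discrete(0.0, 0.2)], [1e3], R=1e8)
    out, _ = run_cycle(state, params.T_sur + 10.0, params)
    assert out.total_cells() == 0.0
    out.R = 1e8
    with pytest.raises(ExtinctionError):
        run_cycle(out, 10.0, params)


def test_cycle_zero_starvation_keeps_spores_and_loners(params):
    X0, R0 = 1e3, 1e8
    state = PopulationState.growth([_discrete(0.5, 0.2)], [X0], R=R0)
    out, _ = run_cycle(state, 0.0, params)
    survivors = out.total_cells()
    assert survivors == pytest.approx(0.9 * (X0 + R0), rel=1e-6)


def test_cycle_spores_stay_dormant_when_food_runs_out_early(params):
    # a huge vegetative population exhausts the pulse before the lag tau ends
    gens = [_discrete(0.5, 0.2)]
    state = PopulationState.growth(gens, [1e11], R=1e8)
    state.spores = np.array([1e6])
    out, rec = run_cycle(state, 10.0, params)
    assert rec.growth_duration < params.tau
    assert not rec.germinated
    # carried spores only decayed, never recruited
    carried = 1e6 * math.exp(-params.delta * (rec.growth_duration + 10.0))
    new_spores = out.spores[0]
    assert new_spores > carried  # partition added fresh spores on top


def test_cycle_spore_only_population_waits_out_the_lag(params):
    state = PopulationState.growth([_discrete(1.0, 0.2)], [0.0], R=1e8)
    state.spores = np.array([1e6])
    out, rec = run_cycle(state, 50.0, params)
    assert rec.germinated
    assert rec.growth_duration > params.tau
    # recruits ate the whole pulse: onset total ~= nu * spores + R0
    assert rec.onset_total == pytest.approx(
        spore_recruits_expected(params) + 1e8, rel=1e-4
    )


def spore_recruits_expected(params):
    nu = params.nu_a0 - params.nu_a1 * 0.2
    return nu * 1e6 * math.exp(-params.delta * params.tau)
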