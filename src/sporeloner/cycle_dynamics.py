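"""One growth-starvation cycle of the amoeba life cycle.

A cycle has four stages:

1. **Growth** — all genotypes share a single resource pool, consumed with
   Michaelis-Menten kinetics: ``dX_i/dt = c_i phi X_i``,
   ``dR/dt = -phi sum_i c_i X_i`` with ``phi = R / (R_half + R)``.  One unit of
   resource makes one cell, so the cell + resource total is conserved.
   Integration uses the exact time-change ``u(t) = integral phi dt``, under
   which ``X_i(u) = X_i(0) e^{c_i u}`` and
   ``R(u) = R(0) - sum_i X_i(0)(e^{c_i u} - 1)``: exhaustion is a scalar root
   find and conservation holds to round-off by construction.  Wall-clock time
   is recovered from ``dt/du = (R_half + R)/R``.
2. **Partitioning at starvation onset** — discrete mechanism: a fraction
   ``alpha`` of each genotype aggregates instantaneously; a fraction ``s`` of
   aggregated cells become spores, the rest die building the stalk.  The
   continuous mechanism instead converts solitary cells into aggregated ones
   at rate ``gamma`` throughout the starvation phase.
3. **Starvation mortality** — spores decay at the constant rate ``delta``;
   solitary cells follow the truncated-Weibull survival curve ``S_c(t)``.
   Both have closed forms, evaluated analytically (no ODE stepping).
4. **Germination at the next pulse** — surviving solitary cells eat
   immediately; spores germinate only ``tau`` hours after the pulse and only a
   fraction ``nu(c)`` succeed.  If the new resources are exhausted before the
   lag ends, spores stay dormant until the next pulse.

Since resources only reach zero asymptotically under Michaelis-Menten kinetics,
starvation onset is triggered at ``R <= eps_frac * R(0)`` (default 1e-9) and R
is then clamped to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .life_history import Genotype, LifeHistoryParams, spore_viability

__all__ = [
    "IntegrationError",
    "ExtinctionError",
    "MechanismMismatchError",
    "PopulationState",
    "StarvationOnset",
    "CycleRecord",
    "integrate_growth",
    "partition_discrete",
    "starve_discrete",
    "continuous_starvation",
    "aggregation_time",
    "germinate",
    "run_cycle",
]

DEFAULT_EPS_FRAC = 1e-9

_GL_X, _GL_W = np.polynomial.legendre.leggauss(64)
_GL32_X, _GL32_W = np.polynomial.legendre.leggauss(32)


class IntegrationError(RuntimeError):
    """Numerical integration failed or was called on a degenerate state."""


class ExtinctionError(RuntimeError):
    """Every pool of every genotype has reached zero."""


class MechanismMismatchError(ValueError):
    """An operation for one aggregation mechanism received the other."""


# ---------------------------------------------------------------------------
# per-grid cached arrays


@dataclass(frozen=True)
class _GridArrays:
    mechanism: str
    c: np.ndarray
    trait: np.ndarray  # alpha (discrete) or gamma (continuous)
    beta: np.ndarray
    nu: np.ndarray
    fT: np.ndarray  # exp(-(mu T_sur)^beta)


def grid_arrays(
    genotypes: Sequence[Genotype], params: LifeHistoryParams
) -> _GridArrays:
    mechs = {g.mechanism for g in genotypes}
    if len(mechs) != 1:
        raise MechanismMismatchError("mixed mechanisms in one population")
    mech = mechs.pop()
    c = np.array([g.c for g in genotypes], dtype=float)
    trait = np.array([g.trait for g in genotypes], dtype=float)
    beta = params.beta_b0 - params.beta_b1 * c
    nu = params.nu_a0 - params.nu_a1 * c
    fT = np.exp(-((params.mu * params.T_sur) ** beta))
    return _GridArrays(mech, c, trait, beta, nu, fT)


def _survival_factor(T: float, ga: _GridArrays, params: LifeHistoryParams) -> np.ndarray:
    """Vector S_c(T) over the grid (closed form)."""
    if T >= params.T_sur:
        return np.zeros_like(ga.c)
    f = np.exp(-((params.mu * T) ** ga.beta))
    return (f - ga.fT) / (1.0 - ga.fT)


# ---------------------------------------------------------------------------
# state containers


@dataclass
class PopulationState:
    """Per-genotype pools plus the shared resource level and clock.

    ``veg`` are actively growing cells (growth phase), ``solitary`` are
    starving non-aggregators, ``spores`` are dormant spores.  Counts are
    continuous densities (no demographic noise).  ``onset_veg`` keeps the
    vegetative snapshot X-tilde taken at the most recent starvation onset.
    """

    genotypes: tuple[Genotype, ...]
    R: float
    veg: np.ndarray
    solitary: np.ndarray
    spores: np.ndarray
    clock: float = 0.0
    phase: str = "growth"
    onset_veg: np.ndarray | None = None

    @classmethod
    def growth(
        cls,
        genotypes: Sequence[Genotype],
        veg,
        R: float,
        spores=None,
        clock: float = 0.0,
    ) -> "PopulationState":
        genotypes = tuple(genotypes)
        n = len(genotypes)
        veg = np.asarray(veg, dtype=float).copy()
        spores = (
            np.zeros(n) if spores is None else np.asarray(spores, dtype=float).copy()
        )
        state = cls(genotypes, float(R), veg, np.zeros(n), spores, clock, "growth")
        state.validate()
        return state

    def validate(self) -> None:
        n = len(self.genotypes)
        for name in ("veg", "solitary", "spores"):
            arr = getattr(self, name)
            if arr.shape != (n,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({n},)")
            if not np.all(np.isfinite(arr)) or np.any(arr < 0):
                raise IntegrationError(f"non-finite or negative counts in {name}")
        if not (np.isfinite(self.R) and self.R >= 0):
            raise IntegrationError(f"invalid resource level R={self.R}")
        if self.phase not in ("growth", "starvation"):
            raise ValueError(f"unknown phase {self.phase!r}")

    def total_cells(self) -> float:
        return float(self.veg.sum() + self.solitary.sum() + self.spores.sum())

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.genotypes,
            self.R,
            self.veg.copy(),
            self.solitary.copy(),
            self.spores.copy(),
            self.clock,
            self.phase,
            None if self.onset_veg is None else self.onset_veg.copy(),
        )


@dataclass(frozen=True)
class StarvationOnset:
    """Per-genotype pools the instant the population stops growing."""

    genotypes: tuple[Genotype, ...]
    spores: np.ndarray
    solitary: np.ndarray
    stalk: np.ndarray


@dataclass(frozen=True)
class CycleRecord:
    """Bookkeeping for one completed growth-starvation cycle."""

    growth_duration: float
    starvation_duration: float
    onset_total: float
    onset_spores: float
    onset_solitary: float
    onset_stalk: float
    survivors_at_pulse: float
    germinated: bool
    # per-genotype spores + solitary the instant growth stops (the
    # winner-measurement point of the evolution engine)
    onset_abundance: np.ndarray | None = None


# ---------------------------------------------------------------------------
# growth phase


def _grow_to_exhaustion(X: np.ndarray, R: float, c: np.ndarray, R_half: float,
                        eps: float) -> tuple[float, float]:
    """Return (u_e, elapsed_hours) to bring the shared resource from R to eps.

    u_e is the accumulated time-change integral: every genotype multiplies by
    exp(c_i * u_e).  Elapsed time splits the log-divergent tail of
    dt/du = (R_half + R)/R off analytically (linearised resource L(s) near the
    exhaustion point) and integrates the smooth remainder by Gauss-Legendre.
    """
    mask = X > 0.0
    if not mask.any():
        raise IntegrationError("no vegetative cells: resources are never exhausted")
    logX = np.log(X[mask])
    cm = c[mask]
    Xtot = float(X.sum())
    target = R - eps
    if target <= 0.0:
        return 0.0, 0.0
    u_hi = math.log1p(target / Xtot) / float(cm.min())

    def gap(u: float) -> float:
        grown = np.exp(np.minimum(logX + cm * u, 700.0))
        return float(grown.sum()) - Xtot - target

    # for a single genotype the analytic bound *is* the root; pad the bracket
    # so floating-point rounding cannot leave gap(u_hi) < 0
    u_hi *= 1.0 + 1e-12
    for _ in range(60):
        if gap(u_hi) >= 0.0:
            break
        u_hi *= 2.0
    u_e = brentq(gap, 0.0, u_hi, xtol=1e-15, rtol=4 * np.finfo(float).eps)
    grown_e = np.exp(logX + cm * u_e)
    D = float((cm * grown_e).sum())  # -dR/du at exhaustion
    # nodes on [0, u_e]
    s = 0.5 * u_e * (_GL_X + 1.0)
    w = 0.5 * u_e * _GL_W
    Rs = (R + Xtot) - np.exp(logX[:, None] + cm[:, None] * s[None, :]).sum(axis=0)
    Rs = np.maximum(Rs, eps * 1e-9)
    L = eps + D * (u_e - s)
    I_reg = float(np.sum(w * (1.0 / Rs - 1.0 / L)))
    I_sing = math.log1p(D * u_e / eps) / D
    elapsed = u_e + R_half * (I_reg + I_sing)
    if not (np.isfinite(u_e) and np.isfinite(elapsed) and elapsed >= 0.0):
        raise IntegrationError("growth integration produced a non-finite result")
    return u_e, elapsed


def _grow_for_time(X: np.ndarray, R: float, c: np.ndarray, R_half: float,
                   t_limit: float) -> tuple[float, float]:
    """Return (u, R_remaining) after growing for exactly t_limit hours."""
    mask = X > 0.0
    logX = np.log(X[mask])
    cm = c[mask]
    Xtot = float(X.sum())

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        grown = np.exp(np.minimum(logX + cm * y[0], 700.0))
        Ru = max((R + Xtot) - float(grown.sum()), 0.0)
        return [Ru / (R_half + Ru)]

    sol = solve_ivp(rhs, (0.0, t_limit), [0.0], method="RK45",
                    rtol=1e-10, atol=1e-13)
    if not sol.success:  # pragma: no cover
        raise IntegrationError(f"partial growth integration failed: {sol.message}")
    u = float(sol.y[0, -1])
    grown = np.exp(np.minimum(logX + cm * u, 700.0))
    R_left = max((R + Xtot) - float(grown.sum()), 0.0)
    return u, R_left


def integrate_growth(
    state: PopulationState,
    params: LifeHistoryParams,
    t_limit: float | None = None,
    eps_frac: float = DEFAULT_EPS_FRAC,
) -> tuple[PopulationState, float]:
    """Advance a growth-phase state to resource exhaustion (or ``t_limit``).

    Returns the new state and the elapsed hours.  On exhaustion R is clamped
    to zero, the phase flips to ``"starvation"`` and the vegetative snapshot
    X-tilde is stored on the state.  Resources are conserved: the increase in
    total cells equals the resource drawdown to relative round-off.
    """
    state.validate()
    if state.phase != "growth":
        raise ValueError("integrate_growth requires a growth-phase state")
    new = state.copy()
    ga = grid_arrays(state.genotypes, params)
    eps = eps_frac * state.R
    if state.R <= 0.0:
        new.R = 0.0
        new.phase = "starvation"
        new.onset_veg = new.veg.copy()
        return new, 0.0
    if float(state.veg.sum()) <= 0.0:
        if t_limit is None:
            raise IntegrationError(
                "no vegetative cells: resources are never exhausted"
            )
        new.clock += t_limit
        return new, float(t_limit)

    u_e, t_exh = _grow_to_exhaustion(state.veg, state.R, ga.c, params.R_half, eps)
    if t_limit is not None and t_exh > t_limit:
        u, R_left = _grow_for_time(state.veg, state.R, ga.c, params.R_half, t_limit)
        new.veg = state.veg * np.exp(ga.c * u)
        new.R = R_left
        new.clock += t_limit
        return new, float(t_limit)

    new.veg = state.veg * np.exp(ga.c * u_e)
    new.R = 0.0
    new.phase = "starvation"
    new.onset_veg = new.veg.copy()
    new.clock += t_exh
    return new, t_exh


# ---------------------------------------------------------------------------
# starvation-onset partitioning and starvation mortality (discrete mechanism)


def partition_discrete(
    state: PopulationState, params: LifeHistoryParams
) -> StarvationOnset:
    """Split the vegetative snapshot at starvation onset.

    Per genotype with aggregated fraction ``alpha``: spores = s * alpha * X,
    solitary = (1 - alpha) * X, stalk = (1 - s) * alpha * X.  The three pools
    sum to X exactly; stalk cells are lost to the system.
    """
    ga = grid_arrays(state.genotypes, params)
    if ga.mechanism != "discrete":
        raise MechanismMismatchError(
            "partition_discrete requires discrete-mechanism genotypes"
        )
    X = state.onset_veg if state.onset_veg is not None else state.veg
    aggregated = ga.trait * X
    spores = params.s * aggregated
    stalk = aggregated - spores
    solitary = X - aggregated
    return StarvationOnset(state.genotypes, spores, solitary, stalk)


def starve_discrete(
    onset: StarvationOnset, T: float, params: LifeHistoryParams
) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form pools after ``T`` hours of starvation.

    Spores decay exponentially at rate delta; solitary cells follow the
    survival curve: ``solitary(T) = solitary(0) * S_c(T)`` (zero beyond
    T_sur).  No ODE stepping is involved.
    """
    if T < 0.0:
        raise ValueError("starvation duration must be >= 0")
    ga = grid_arrays(onset.genotypes, params)
    spores_T = onset.spores * math.exp(-params.delta * T)
    solitary_T = onset.solitary * _survival_factor(T, ga, params)
    return spores_T, solitary_T


# ---------------------------------------------------------------------------
# continuous mechanism


def _aggregate_integral(gamma: float, c: float, t: float,
                        params: LifeHistoryParams) -> float:
    """integral_0^min(t,T_sur) gamma e^{-gamma u} S_c(u) e^{delta u} du.

    Computed in the variable w = e^{-gamma u} (so large gamma is handled
    exactly), on a composite Gauss-Legendre rule with geometric breakpoints to
    resolve the logarithmic map near w = 0.
    """
    tm = min(t, params.T_sur)
    if gamma <= 0.0 or tm <= 0.0:
        return 0.0
    beta = params.beta_b0 - params.beta_b1 * c
    fT = math.exp(-((params.mu * params.T_sur) ** beta))
    wm = math.exp(-gamma * tm)
    pts = [wm] + [p for p in (1e-16, 1e-12, 1e-8, 1e-4, 1e-2) if p > wm] + [1.0]
    total = 0.0
    expo = params.delta / gamma
    for a, b in zip(pts[:-1], pts[1:]):
        x = 0.5 * (b - a) * (_GL32_X + 1.0) + a
        wgt = 0.5 * (b - a) * _GL32_W
        u = -np.log(x) / gamma
        f = np.exp(-((params.mu * u) ** beta))
        S = np.clip((f - fT) / (1.0 - fT), 0.0, 1.0)
        total += float(np.sum(wgt * S * x**-expo))
    return total


def continuous_starvation(
    N0, genotype: Genotype | Sequence[Genotype], t: float,
    params: LifeHistoryParams,
):
    """Pools of a continuous-mechanism genotype ``t`` hours into starvation.

    Solitary cells leave the pool both by aggregating (rate gamma) and by
    dying (hazard of the survival curve), independently:
    ``N(t) = N0 e^{-gamma t} S_c(t)``.  The aggregated pool obeys
    ``dA/dt = gamma N - delta A`` with A(0) = 0, and the spore count is the
    fraction ``s`` of it.  Returns a dict with ``solitary``, ``aggregated``
    and ``spores`` (scalars for a single genotype, arrays for a sequence).
    """
    if t < 0.0:
        raise ValueError("t must be >= 0")
    single = isinstance(genotype, Genotype)
    gens = [genotype] if single else list(genotype)
    N0s = np.broadcast_to(np.asarray(N0, dtype=float), (len(gens),))
    sol = np.empty(len(gens))
    agg = np.empty(len(gens))
    for i, g in enumerate(gens):
        if g.mechanism != "continuous":
            raise MechanismMismatchError(
                "continuous_starvation requires continuous-mechanism genotypes"
            )
        if g.gamma is not None and g.gamma < 0.0:
            raise ValueError("gamma must be >= 0")
        beta = params.beta_b0 - params.beta_b1 * g.c
        fT = math.exp(-((params.mu * params.T_sur) ** beta))
        if t >= params.T_sur:
            S = 0.0
        else:
            S = (math.exp(-((params.mu * t) ** beta)) - fT) / (1.0 - fT)
        sol[i] = N0s[i] * math.exp(-g.gamma * t) * S  # type: ignore[operator]
        agg[i] = (
            N0s[i]
            * math.exp(-params.delta * t)
            * _aggregate_integral(g.gamma, g.c, t, params)  # type: ignore[arg-type]
        )
    spores = params.s * agg
    if single:
        return {
            "solitary": float(sol[0]),
            "aggregated": float(agg[0]),
            "spores": float(spores[0]),
        }
    return {"solitary": sol, "aggregated": agg, "spores": spores}


def aggregation_time(
    genotype: Genotype, params: LifeHistoryParams, epsilon: float = 1e-6
) -> float:
    """Hours until all solitary cells of a continuous genotype have either
    aggregated or died: smallest t with ``N(t)/N0 < epsilon``.

    Always <= T_sur (survival vanishes there); non-increasing in gamma.
    """
    if genotype.mechanism != "continuous":
        raise MechanismMismatchError("aggregation_time requires a continuous genotype")
    if not 0.0 < epsilon < 1.0:
        raise ValueError("epsilon must be in (0, 1)")
    gamma, c = genotype.gamma, genotype.c
    beta = params.beta_b0 - params.beta_b1 * c
    fT = math.exp(-((params.mu * params.T_sur) ** beta))

    def frac(t: float) -> float:
        if t >= params.T_sur:
            return 0.0
        S = (math.exp(-((params.mu * t) ** beta)) - fT) / (1.0 - fT)
        return math.exp(-gamma * t) * S  # type: ignore[operator]

    if frac(0.0) < epsilon:  # pragma: no cover - epsilon < 1 guards this
        return 0.0
    lo, hi = 0.0, params.T_sur
    while hi - lo > 1e-10 * params.T_sur:
        mid = 0.5 * (lo + hi)
        if frac(mid) < epsilon:
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# germination


def germinate(
    spores, c, params: LifeHistoryParams, resources_available: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Recruit spores into the vegetative pool after the germination lag.

    If resources remain ``tau`` hours after the pulse, a fraction ``nu(c)`` of
    the spore pool joins the vegetative cells and the remainder dies; the
    spore pool empties.  Otherwise germination is not triggered and all spores
    stay dormant.  Returns (recruits, remaining_spores).
    """
    spores = np.asarray(spores, dtype=float)
    nu = spore_viability(c, params)
    if resources_available:
        recruits = nu * spores
        remaining = np.zeros_like(spores)
    else:
        recruits = np.zeros_like(spores)
        remaining = spores.copy()
    if spores.ndim == 0:
        return float(recruits), float(remaining)  # type: ignore[return-value]
    return recruits, remaining


# ---------------------------------------------------------------------------
# one full cycle


def run_cycle(
    state: PopulationState,
    T: float,
    params: LifeHistoryParams,
    eps_frac: float = DEFAULT_EPS_FRAC,
) -> tuple[PopulationState, CycleRecord]:
    """Advance one full growth-starvation cycle.

    ``state`` must be in the growth phase with the fresh resource pulse
    already applied to ``state.R``.  Sequence: grow (with spore germination
    ``tau`` hours after the pulse, provided resources last that long), detect
    exhaustion, partition into spores / solitary / stalk, then apply ``T``
    hours of closed-form starvation mortality.  Stalk cells leave the system.
    The returned state is in the growth phase again, with the starvation
    survivors as vegetative cells (their starvation clocks reset on feeding)
    and any dormant spores carried over, and ``R = 0`` awaiting the next
    pulse.
    """
    if T < 0.0:
        raise ValueError("starvation duration must be >= 0")
    state.validate()
    if state.phase != "growth":
        raise ValueError("run_cycle requires a growth-phase state")
    ga = grid_arrays(state.genotypes, params)
    params_tau = params.tau
    veg = state.veg.copy()
    spores = state.spores.copy()
    R = state.R
    elapsed = 0.0
    germinated = False

    if float(veg.sum()) + float(spores.sum()) <= 0.0:
        raise ExtinctionError("population extinct: no cells at the pulse")

    if float(spores.sum()) > 0.0 and R > 0.0:
        if float(veg.sum()) > 0.0:
            u_e, t_exh = _grow_to_exhaustion(veg, R, ga.c, params.R_half,
                                             eps_frac * R)
            if t_exh <= params_tau:
                # resources gone before the lag ends: spores stay dormant
                veg = veg * np.exp(ga.c * u_e)
                spores = spores * math.exp(-params.delta * t_exh)
                R = 0.0
                elapsed = t_exh
            else:
                u_tau, R_left = _grow_for_time(veg, R, ga.c, params.R_half,
                                               params_tau)
                veg = veg * np.exp(ga.c * u_tau)
                spores = spores * math.exp(-params.delta * params_tau)
                recruits, spores = germinate(spores, ga.c, params, True)
                veg = veg + recruits
                germinated = True
                R = R_left
                elapsed = params_tau
        else:
            # nobody eats during the lag; the pulse is intact at tau
            spores = spores * math.exp(-params.delta * params_tau)
            recruits, spores = germinate(spores, ga.c, params, True)
            veg = recruits
            germinated = True
            elapsed = params_tau
            if float(veg.sum()) <= 0.0:
                raise ExtinctionError("population extinct: no viable recruits")

    if R > 0.0:
        if float(veg.sum()) <= 0.0:
            raise ExtinctionError("population extinct: nothing can grow")
        u_e, t_exh = _grow_to_exhaustion(veg, R, ga.c, params.R_half,
                                         eps_frac * R)
        veg = veg * np.exp(ga.c * u_e)
        spores = spores * math.exp(-params.delta * t_exh)
        elapsed += t_exh
        R = 0.0

    onset_clock = state.clock + elapsed
    X_onset = veg

    if ga.mechanism == "discrete":
        aggregated = ga.trait * X_onset
        new_spores = params.s * aggregated
        stalk = aggregated - new_spores
        solitary_onset = X_onset - aggregated
        onset_spore_total = float(new_spores.sum() + spores.sum())
        onset_abundance = spores + new_spores + solitary_onset
        # starvation (closed forms)
        spores_T = (spores + new_spores) * math.exp(-params.delta * T)
        solitary_T = solitary_onset * _survival_factor(T, ga, params)
    else:
        solitary_onset = X_onset
        stalk = np.zeros_like(X_onset)
        N0 = X_onset
        surv = _survival_factor(T, ga, params)
        N_T = N0 * np.exp(-ga.trait * T) * surv
        A_T = np.array(
            [
                N0[i]
                * math.exp(-params.delta * T)
                * _aggregate_integral(ga.trait[i], ga.c[i], T, params)
                for i in range(len(N0))
            ]
        )
        new_spores_T = params.s * A_T
        onset_spore_total = float(spores.sum())
        onset_abundance = spores + X_onset
        spores_T = spores * math.exp(-params.delta * T) + new_spores_T
        solitary_T = N_T
        stalk = (1.0 - params.s) * A_T  # lost at spore differentiation

    record = CycleRecord(
        growth_duration=elapsed,
        starvation_duration=T,
        onset_total=float(X_onset.sum() + spores.sum()),
        onset_spores=onset_spore_total,
        onset_solitary=float(solitary_onset.sum()),
        onset_stalk=float(stalk.sum()) if ga.mechanism == "discrete" else float("nan"),
        survivors_at_pulse=float(spores_T.sum() + solitary_T.sum()),
        germinated=germinated,
        onset_abundance=onset_abundance,
    )
    next_state = PopulationState(
        genotypes=state.genotypes,
        R=0.0,
        veg=solitary_T,  # survivors feed immediately at the next pulse
        solitary=np.zeros_like(solitary_T),
        spores=spores_T,
        clock=onset_clock + T,
        phase="growth",
        onset_veg=X_onset.copy(),
    )
    return next_state, record
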