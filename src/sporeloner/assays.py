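"""Single-cycle experimental emulations.

Two families of in-silico experiments mirror the lab protocols used on social
amoebae:

* **Clonal assays** — one genotype, one growth phase on a fixed resource
  pulse, measured at starvation onset (no starvation mortality).  Because one
  resource unit makes one cell and growth-phase death is neglected, every
  genotype reaches the same carrying capacity ``P = X0 + R0``; what differs is
  the split ``alpha P`` aggregators vs ``(1 - alpha) P`` non-aggregators.  A
  variant grows the clone exponentially for a fixed time on unlimited food and
  then starves it abruptly, which instead makes spore numbers increase with
  the division rate.

* **Chimeric mixes** — a 50:50 mix of two genotypes; a genotype's *chimeric
  success* (CS) is its fraction of the spores the mix produces.  The
  starvation-only protocol (``mode="S"``) skips growth: spores form straight
  from the initial mix.  The growth-starvation protocol (``mode="GS"``) lets
  the mix grow to exhaustion first, so the division rate competes with the
  aggregated fraction in setting CS; it reduces to the starvation-only
  protocol at high cell-to-resource density.  For continuous-mechanism
  genotypes spores are counted after ``T_sur`` hours of starvation, when every
  genotype has completed aggregation.  Pairwise CS values always satisfy
  ``cs_A + cs_B = 1``; a mix in which neither side makes spores is scored as a
  0.5/0.5 tie by convention.

Dominance tournaments collect all pairwise mixes of a genotype set into a
win/loss/tie matrix, rank genotypes by wins, and check whether the hierarchy
is linear (transitive).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .cycle_dynamics import (
    MechanismMismatchError,
    PopulationState,
    _aggregate_integral,
    integrate_growth,
)
from .life_history import Genotype, LifeHistoryParams

__all__ = [
    "ClonalAssayResult",
    "ChimeraResult",
    "clonal_growth_assay",
    "exponential_starve_assay",
    "chimeric_success_starvation",
    "chimeric_success_growth_starvation",
    "average_chimeric_success",
    "dominance_matrix",
    "rank_and_check_linearity",
]

Mode = Literal["S", "GS"]


@dataclass(frozen=True)
class ClonalAssayResult:
    """Pools of a clonal culture at starvation onset after one growth phase."""

    genotype: Genotype
    P: float  # population at starvation onset
    aggregators: float  # alpha * P
    non_aggregators: float  # (1 - alpha) * P
    spores: float  # s * alpha * P


def clonal_growth_assay(
    genotype: Genotype, X0: float, R0: float, params: LifeHistoryParams
) -> ClonalAssayResult:
    """Grow a clone of ``X0`` cells on ``R0`` resources to exhaustion and
    report the pools at starvation onset.

    Conservation makes ``P = X0 + R0`` up to the exhaustion threshold,
    independent of ``c`` and ``alpha``; no starvation mortality is applied.
    """
    if genotype.mechanism != "discrete":
        raise MechanismMismatchError("clonal_growth_assay expects a discrete genotype")
    if not (X0 > 0 and R0 > 0):
        raise ValueError("X0 and R0 must be > 0")
    state = PopulationState.growth([genotype], [X0], R=R0)
    state, _ = integrate_growth(state, params)
    P = float(state.veg[0])
    alpha = genotype.alpha or 0.0
    return ClonalAssayResult(
        genotype=genotype,
        P=P,
        aggregators=alpha * P,
        non_aggregators=(1.0 - alpha) * P,
        spores=params.s * alpha * P,
    )


def exponential_starve_assay(
    genotype: Genotype, X0: float, t_grow: float, params: LifeHistoryParams
) -> ClonalAssayResult:
    """Exponential growth on unlimited food for ``t_grow`` hours, then abrupt
    starvation: ``P = X0 e^{c t}`` and spores = ``s alpha P``."""
    if genotype.mechanism != "discrete":
        raise MechanismMismatchError(
            "exponential_starve_assay expects a discrete genotype"
        )
    if t_grow < 0:
        raise ValueError("t_grow must be >= 0")
    if genotype.c * t_grow > 700.0:
        raise OverflowError("c * t_grow too large: population would overflow")
    P = X0 * math.exp(genotype.c * t_grow)
    alpha = genotype.alpha or 0.0
    return ClonalAssayResult(
        genotype=genotype,
        P=P,
        aggregators=alpha * P,
        non_aggregators=(1.0 - alpha) * P,
        spores=params.s * alpha * P,
    )


# ---------------------------------------------------------------------------
# pairwise spore production


def _check_pair(gA: Genotype, gB: Genotype) -> str:
    if gA.mechanism != gB.mechanism:
        raise MechanismMismatchError("mixed mechanisms in one chimera")
    return gA.mechanism


def _spores_from_onset(
    g: Genotype, X_onset: float, params: LifeHistoryParams
) -> float:
    """Spores a genotype contributes, measured at spore formation.

    Discrete: instantaneous, ``s alpha X``.  Continuous: counted after T_sur
    hours of starvation, when aggregation is complete for every genotype.
    """
    if g.mechanism == "discrete":
        return params.s * (g.alpha or 0.0) * X_onset
    A = (
        X_onset
        * math.exp(-params.delta * params.T_sur)
        * _aggregate_integral(g.gamma, g.c, params.T_sur, params)  # type: ignore[arg-type]
    )
    return params.s * A


def _pair_spores_starvation(
    gA: Genotype, gB: Genotype, X0: float, params: LifeHistoryParams
) -> tuple[float, float]:
    _check_pair(gA, gB)
    if not X0 > 0:
        raise ValueError("X0 must be > 0")
    half = 0.5 * X0
    return (
        _spores_from_onset(gA, half, params),
        _spores_from_onset(gB, half, params),
    )


def _pair_spores_growth_starvation(
    gA: Genotype, gB: Genotype, X0: float, R0: float, params: LifeHistoryParams
) -> tuple[float, float, float, float]:
    """Returns (spores_A, spores_B, X_onset_A, X_onset_B)."""
    _check_pair(gA, gB)
    if not (X0 > 0 and R0 > 0):
        raise ValueError("X0 and R0 must be > 0")
    state = PopulationState.growth([gA, gB], [0.5 * X0, 0.5 * X0], R=R0)
    state, _ = integrate_growth(state, params)
    XA, XB = float(state.veg[0]), float(state.veg[1])
    return (
        _spores_from_onset(gA, XA, params),
        _spores_from_onset(gB, XB, params),
        XA,
        XB,
    )


def _cs_from_spores(spA: float, spB: float) -> tuple[float, float, bool]:
    total = spA + spB
    if total <= 0.0:
        return 0.5, 0.5, True  # neither side sporulates: tie by convention
    return spA / total, spB / total, False


def chimeric_success_starvation(
    gA: Genotype, gB: Genotype, X0: float, params: LifeHistoryParams
) -> tuple[float, float]:
    """CS of each genotype in a 50:50 starving mix (no growth phase).

    For the discrete mechanism this reduces to
    ``cs_A = alpha_A / (alpha_A + alpha_B)`` — the factor ``s`` and the equal
    split cancel.
    """
    spA, spB = _pair_spores_starvation(gA, gB, X0, params)
    csA, csB, _ = _cs_from_spores(spA, spB)
    return csA, csB


def chimeric_success_growth_starvation(
    gA: Genotype, gB: Genotype, X0: float, R0: float, params: LifeHistoryParams
) -> tuple[float, float]:
    """CS of each genotype after one shared growth phase and natural
    starvation; the division rate now matters through the growth phase."""
    spA, spB, _, _ = _pair_spores_growth_starvation(gA, gB, X0, R0, params)
    csA, csB, _ = _cs_from_spores(spA, spB)
    return csA, csB


# ---------------------------------------------------------------------------
# tournaments over genotype sets


@dataclass
class ChimeraResult:
    """All pairwise mixes of a genotype set.

    ``cs_matrix[i, j]`` is genotype i's spore fraction against j (diagonal
    0.5); ``outcome[i, j]`` is +1/-1/0 for win/loss/tie at the relative
    spore-difference tolerance ``tie_tol``.  ``avg_cs`` is the mean CS over a
    genotype's ``N_st - 1`` partners.  ``avg_aggregators`` /
    ``avg_non_aggregators`` are the genotype's mean per-mix pool sizes at
    measurement (used for trait-correlation readouts).
    """

    genotypes: tuple[Genotype, ...]
    mode: Mode
    cs_matrix: np.ndarray
    outcome: np.ndarray
    tie_mask: np.ndarray
    avg_cs: np.ndarray
    wins: np.ndarray
    losses: np.ndarray
    ties: np.ndarray
    ranking: list[int]
    is_transitive: bool
    violations: list[tuple[int, int, int]]
    avg_aggregators: np.ndarray
    avg_non_aggregators: np.ndarray
    setup: dict = field(default_factory=dict)


def average_chimeric_success(
    genotypes: Sequence[Genotype],
    mode: Mode,
    X0: float,
    R0: float | None,
    params: LifeHistoryParams,
) -> np.ndarray:
    """Per-genotype mean CS over all pairwise mixes with the other
    ``N_st - 1`` genotypes of the set."""
    res = dominance_matrix(genotypes, mode, X0, R0, params)
    return res.avg_cs


def dominance_matrix(
    genotypes: Sequence[Genotype],
    mode: Mode,
    X0: float,
    R0: float | None,
    params: LifeHistoryParams,
    tie_tol: float = 1e-9,
) -> ChimeraResult:
    """Run every pairwise mix of the set and assemble the tournament.

    ``mode="S"`` uses the starvation-only protocol, ``mode="GS"`` the
    growth-starvation one (``R0`` required).  A mix is a tie when the relative
    spore difference is at most ``tie_tol`` (or neither side sporulates).
    """
    gens = tuple(genotypes)
    n = len(gens)
    if n < 2:
        raise ValueError("a tournament needs at least two genotypes")
    if mode not in ("S", "GS"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "GS" and (R0 is None or R0 <= 0):
        raise ValueError("mode='GS' requires a positive R0")
    cs = np.full((n, n), 0.5)
    outcome = np.zeros((n, n), dtype=int)
    tie = np.zeros((n, n), dtype=bool)
    np.fill_diagonal(tie, True)
    # per-mix pools of the focal genotype at spore formation
    agg_sum = np.zeros(n)
    nonagg_sum = np.zeros(n)
    for i, j in itertools.combinations(range(n), 2):
        if mode == "S":
            spA, spB = _pair_spores_starvation(gens[i], gens[j], X0, params)
            XA = XB = 0.5 * X0
        else:
            spA, spB, XA, XB = _pair_spores_growth_starvation(
                gens[i], gens[j], X0, R0, params  # type: ignore[arg-type]
            )
        csA, csB, zero_tie = _cs_from_spores(spA, spB)
        cs[i, j], cs[j, i] = csA, csB
        scale = max(spA, spB)
        is_tie = zero_tie or (scale > 0 and abs(spA - spB) <= tie_tol * scale)
        tie[i, j] = tie[j, i] = is_tie
        if not is_tie:
            if spA > spB:
                outcome[i, j], outcome[j, i] = 1, -1
            else:
                outcome[i, j], outcome[j, i] = -1, 1
        for k, g, X in ((i, gens[i], XA), (j, gens[j], XB)):
            if g.mechanism == "discrete":
                agg_sum[k] += (g.alpha or 0.0) * X
                nonagg_sum[k] += (1.0 - (g.alpha or 0.0)) * X
            else:
                sp = _spores_from_onset(g, X, params) / params.s
                agg_sum[k] += sp
                nonagg_sum[k] += X - sp
    avg_cs = (cs.sum(axis=1) - 0.5) / (n - 1)
    wins = (outcome == 1).sum(axis=1)
    losses = (outcome == -1).sum(axis=1)
    ties = tie.sum(axis=1) - 1  # exclude the diagonal
    ranking, transitive, violations = rank_and_check_linearity(outcome, avg_cs)
    return ChimeraResult(
        genotypes=gens,
        mode=mode,
        cs_matrix=cs,
        outcome=outcome,
        tie_mask=tie,
        avg_cs=avg_cs,
        wins=wins,
        losses=losses,
        ties=ties,
        ranking=ranking,
        is_transitive=transitive,
        violations=violations,
        avg_aggregators=agg_sum / (n - 1),
        avg_non_aggregators=nonagg_sum / (n - 1),
        setup={"mode": mode, "X0": X0, "R0": R0, "tie_tol": tie_tol},
    )


def rank_and_check_linearity(
    outcome: np.ndarray, avg_cs: np.ndarray | None = None
) -> tuple[list[int], bool, list[tuple[int, int, int]]]:
    """Rank a tournament by win count and test it for linearity.

    ``outcome`` is an antisymmetric matrix of +1 (row beats column), -1, 0.
    Ties in win count are broken by average CS (when given), then by input
    order.  The hierarchy is linear (transitive) iff no cyclic triple
    ``i > j > k > i`` exists among strict wins; all violating triples are
    returned.
    """
    outcome = np.asarray(outcome)
    n = outcome.shape[0]
    if outcome.shape != (n, n) or not np.all(outcome == -outcome.T):
        raise ValueError("outcome must be a square antisymmetric win/loss matrix")
    wins = (outcome == 1).sum(axis=1)
    if avg_cs is None:
        order = sorted(range(n), key=lambda i: (-wins[i], i))
    else:
        order = sorted(range(n), key=lambda i: (-wins[i], -avg_cs[i], i))
    win = outcome == 1
    violations = [
        (i, j, k)
        for i, j, k in itertools.combinations(range(n), 3)
        for a, b, c in ((i, j, k), (i, k, j))
        if win[a, b] and win[b, c] and win[c, a]
    ]
    return order, len(violations) == 0, violations
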