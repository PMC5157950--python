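"""Genotype space and life-history tradeoff curves.

The model follows starving social amoebae (Dictyostelium-like) whose heritable
strategy has two components: how the clone responds to starvation (a discrete
aggregated fraction ``alpha``, or a continuous aggregation rate ``gamma``) and
how fast it divides (``c``, per hour).  Faster division trades off against
starvation survival of solitary (non-aggregated) cells and against the
germination viability of spores, through two linear cost curves:

* survivorship exponent  ``beta(c) = b0 - b1 * c``  entering the Weibull-type
  survival curve of solitary cells, with ``beta > 1`` so mortality starts slow;
* spore viability  ``nu(c) = a0 - a1 * c``  in [0, 1], the fraction of spores
  that germinate successfully when food returns.

Everything in this module is a pure function of the parameters; no simulation
state is involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "ConfigurationError",
    "Genotype",
    "LifeHistoryParams",
    "GenotypeGridSpec",
    "beta_cost",
    "spore_viability",
    "survival_probability",
    "survival_hazard",
    "survival_zero_time",
    "build_genotype_grid",
    "DETERMINISTIC_GRID_SPEC",
    "STOCHASTIC_GRID_SPEC",
    "REDUCED_GRID_SPEC",
]

Mechanism = Literal["discrete", "continuous"]


class ConfigurationError(ValueError):
    """A parameter set violates one of the model's structural constraints."""


@dataclass(frozen=True)
class Genotype:
    """A heritable strategy: aggregation trait plus division rate.

    Exactly one of ``alpha`` (discrete mechanism: fraction of the population
    that aggregates at starvation onset) or ``gamma`` (continuous mechanism:
    per-hour rate at which starving solitary cells join the aggregate) is set,
    matching ``mechanism``.  ``c`` is the division rate in 1/h; the doubling
    time is ``ln 2 / c``.
    """

    mechanism: Mechanism
    c: float
    alpha: float | None = None
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in ("discrete", "continuous"):
            raise ConfigurationError(f"unknown mechanism {self.mechanism!r}")
        if self.mechanism == "discrete":
            if self.alpha is None or self.gamma is not None:
                raise ConfigurationError(
                    "discrete genotypes set alpha and leave gamma unset"
                )
            if not 0.0 <= self.alpha <= 1.0:
                raise ConfigurationError(f"alpha={self.alpha} outside [0, 1]")
        else:
            if self.gamma is None or self.alpha is not None:
                raise ConfigurationError(
                    "continuous genotypes set gamma and leave alpha unset"
                )
            if self.gamma < 0.0:
                raise ConfigurationError(f"gamma={self.gamma} must be >= 0")
        if not self.c > 0.0:
            raise ConfigurationError(f"division rate c={self.c} must be > 0")

    @property
    def trait(self) -> float:
        """The aggregation trait value (alpha or gamma, per mechanism)."""
        return self.alpha if self.mechanism == "discrete" else self.gamma  # type: ignore[return-value]

    @property
    def doubling_time(self) -> float:
        return math.log(2.0) / self.c

    def label(self) -> str:
        sym = "alpha" if self.mechanism == "discrete" else "gamma"
        return f"{sym}={self.trait:g},c={self.c:g}"


@dataclass(frozen=True)
class LifeHistoryParams:
    """All non-evolving model constants.

    Defaults follow the published parameterization where a value is printed in
    the model description (s, T_sur, the beta and nu coefficients, the c
    range); the remaining constants (delta, tau, mu, R_half) are
    order-of-magnitude choices, configurable and tagged "assumed" in run
    metadata (see :mod:`sporeloner.config`).

    s        spore fraction of aggregated cells (the 20%:80% stalk:spore split)
    delta    spore death rate, 1/h (spores are dormant, mortality very low)
    tau      germination lag, hours, between a food pulse and spore recruitment
    mu       survivorship time-scale rate, 1/h, in the Weibull-type curve
    T_sur    maximum solitary-cell survival time, hours (survival is exactly 0 there)
    beta_b0, beta_b1   coefficients of beta(c) = b0 - b1 c
    nu_a0, nu_a1       coefficients of nu(c) = a0 - a1 c
    R_half   Michaelis-Menten half-saturation constant, resource units
    c_min, c_max       admissible division-rate range, 1/h
    """

    s: float = 0.8
    delta: float = 1e-4
    tau: float = 4.0
    mu: float = 0.005
    T_sur: float = 200.0
    beta_b0: float = 3.1
    beta_b1: float = 4.0
    nu_a0: float = 1.1
    nu_a1: float = 2.0
    R_half: float = 1e7
    c_min: float = 0.05
    c_max: float = 0.45

    def __post_init__(self) -> None:
        if not 0.0 < self.s <= 1.0:
            raise ConfigurationError(f"s={self.s} must be in (0, 1]")
        if self.delta < 0.0:
            raise ConfigurationError("delta must be >= 0")
        if self.tau < 0.0:
            raise ConfigurationError("tau must be >= 0")
        if not self.mu > 0.0:
            raise ConfigurationError("mu must be > 0")
        if not self.T_sur > 0.0:
            raise ConfigurationError("T_sur must be > 0")
        if not 0.0 < self.c_min <= self.c_max:
            raise ConfigurationError("need 0 < c_min <= c_max")
        # beta > 1 over the whole admissible range guarantees the slow initial
        # decay of the survival curve; beta is linear so the endpoints suffice.
        for c in (self.c_min, self.c_max):
            b = self.beta_b0 - self.beta_b1 * c
            if not b > 1.0:
                raise ConfigurationError(
                    f"beta(c)={b:g} at c={c:g}: the survivorship exponent must "
                    "satisfy beta > 1 on the admissible division-rate range"
                )
            v = self.nu_a0 - self.nu_a1 * c
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(
                    f"nu(c)={v:g} at c={c:g}: spore viability must lie in [0, 1]"
                )

    def with_(self, **kwargs) -> "LifeHistoryParams":
        return replace(self, **kwargs)


def _check_c(c, params: LifeHistoryParams) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if np.any(c < params.c_min - 1e-12) or np.any(c > params.c_max + 1e-12):
        raise ValueError(
            f"division rate outside admissible range "
            f"[{params.c_min}, {params.c_max}]"
        )
    return c


def beta_cost(c, params: LifeHistoryParams):
    """Survivorship exponent ``beta(c) = b0 - b1 c`` (dimensionless, > 1)."""
    c = _check_c(c, params)
    out = params.beta_b0 - params.beta_b1 * c
    return float(out) if out.ndim == 0 else out


def spore_viability(c, params: LifeHistoryParams):
    """Spore germination success ``nu(c) = a0 - a1 c``, a probability."""
    c = _check_c(c, params)
    out = params.nu_a0 - params.nu_a1 * c
    return float(out) if out.ndim == 0 else out


def survival_probability(c, t, params: LifeHistoryParams):
    """Probability that a solitary (non-aggregated) cell of division rate ``c``
    is still alive ``t`` hours after starvation onset.

    The curve is a truncated-Weibull survivorship

        S_c(t) = (exp(-(mu t)^beta) - exp(-(mu T_sur)^beta))
                 / (1 - exp(-(mu T_sur)^beta)),

    normalised so S_c(0) = 1 and constructed so S_c(T_sur) = 0 exactly: cells
    live off internal reserves (autophagy), mortality is slow at first
    (beta > 1), and nobody outlives T_sur.  Faster dividers (smaller beta) die
    sooner at every intermediate time provided mu * t <= 1.
    """
    c = _check_c(c, params)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("t must be >= 0")
    beta = params.beta_b0 - params.beta_b1 * c
    fT = np.exp(-((params.mu * params.T_sur) ** beta))
    f = np.exp(-((params.mu * np.minimum(t, params.T_sur)) ** beta))
    s = (f - fT) / (1.0 - fT)
    s = np.where(t >= params.T_sur, 0.0, s)
    return float(s) if s.ndim == 0 else s


def survival_hazard(c, t, params: LifeHistoryParams):
    """Instantaneous death rate ``-S'/S`` of a starving solitary cell, 1/h.

    Analytic companion of :func:`survival_probability`:
    ``exp(-integral_0^t hazard) == S_c(t)`` identically.  Vanishes at t = 0
    (beta > 1) and diverges as t approaches T_sur, where survival hits zero
    with finite probability density.
    """
    c = _check_c(c, params)
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("t must be >= 0")
    if np.any(t >= params.T_sur):
        raise ValueError("hazard is undefined at t >= T_sur (survival is zero)")
    beta = params.beta_b0 - params.beta_b1 * c
    mt = params.mu * t
    fT = np.exp(-((params.mu * params.T_sur) ** beta))
    with np.errstate(divide="ignore"):
        f = np.exp(-(mt**beta))
        h = beta * params.mu * mt ** (beta - 1.0) * f / (f - fT)
    h = np.where(t == 0.0, 0.0, h)
    return float(h) if h.ndim == 0 else h


def survival_zero_time(c, params: LifeHistoryParams, tol: float = 1e-9) -> float:
    """Smallest ``t`` at which the survival curve evaluates to exactly zero.

    Located by bisection on the sign of :func:`survival_probability`; by
    construction of the curve this is T_sur for every admissible ``c``.
    """
    lo, hi = 0.0, float(params.T_sur)
    if survival_probability(c, hi, params) != 0.0:  # pragma: no cover
        raise RuntimeError("survival does not vanish at T_sur")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if survival_probability(c, mid, params) > 0.0:
            lo = mid
        else:
            hi = mid
    return hi


@dataclass(frozen=True)
class GenotypeGridSpec:
    """Cartesian trait grid: aggregation-trait segments x division-rate range.

    ``trait_segments`` is a list of (start, stop, step) triples for alpha (or
    gamma); segments may share endpoints, duplicates are removed.  ``c_range``
    is a single (start, stop, step) triple.  Endpoints are included; values are
    built by integer-index arithmetic to avoid floating-point step drift.
    """

    mechanism: Mechanism = "discrete"
    trait_segments: tuple[tuple[float, float, float], ...] = ((0.0, 1.0, 0.01),)
    c_range: tuple[float, float, float] = (0.05, 0.45, 0.01)

    def __post_init__(self) -> None:
        for seg in list(self.trait_segments) + [self.c_range]:
            start, stop, step = seg
            if not step > 0.0:
                raise ConfigurationError(f"grid step must be > 0 in {seg}")
            if stop < start:
                raise ConfigurationError(f"grid segment reversed: {seg}")

    def trait_values(self) -> np.ndarray:
        vals: list[np.ndarray] = []
        for start, stop, step in self.trait_segments:
            vals.append(_segment_values(start, stop, step))
        out = np.unique(np.round(np.concatenate(vals), 12))
        if out.size == 0:
            raise ConfigurationError("empty trait grid")
        return out

    def c_values(self) -> np.ndarray:
        out = np.unique(np.round(_segment_values(*self.c_range), 12))
        if out.size == 0:
            raise ConfigurationError("empty c grid")
        return out


def _segment_values(start: float, stop: float, step: float) -> np.ndarray:
    n = int(round((stop - start) / step))
    # include both endpoints; integer-index arithmetic avoids accumulation drift
    vals = start + step * np.arange(n + 1)
    return vals[vals <= stop + 0.5 * step]


# Grids matching the published simulations: the deterministic-environment grid
# (101 alpha x 41 c = 4141 genotypes) and the stochastic one with its refined
# alpha sampling near zero (1e-4 steps on [0, 0.1], 1e-2 above).
DETERMINISTIC_GRID_SPEC = GenotypeGridSpec(
    mechanism="discrete",
    trait_segments=((0.0, 1.0, 0.01),),
    c_range=(0.05, 0.45, 0.01),
)
STOCHASTIC_GRID_SPEC = GenotypeGridSpec(
    mechanism="discrete",
    trait_segments=((0.0, 0.1, 1e-4), (0.1, 1.0, 0.01)),
    c_range=(0.05, 0.45, 0.01),
)
# Desk-scale grid used throughout the examples and the reduced experiments:
# alpha in {0, 0.125, ..., 1}, c in {0.05, 0.15, 0.25, 0.35, 0.45}.
REDUCED_GRID_SPEC = GenotypeGridSpec(
    mechanism="discrete",
    trait_segments=((0.0, 1.0, 0.125),),
    c_range=(0.05, 0.45, 0.10),
)


def build_genotype_grid(
    spec: GenotypeGridSpec, params: LifeHistoryParams | None = None
) -> list[Genotype]:
    """Enumerate the full Cartesian genotype grid defined by ``spec``.

    Returns ``len(trait_values) * len(c_values)`` genotypes, sorted by
    (trait, c).  Raises :class:`ConfigurationError` for an empty grid or for
    division rates outside the admissible range of ``params``.
    """
    traits = spec.trait_values()
    cs = spec.c_values()
    if params is not None:
        _check_c(cs, params)
    if spec.mechanism == "discrete" and (traits[0] < 0 or traits[-1] > 1):
        raise ConfigurationError("alpha grid must stay inside [0, 1]")
    out: list[Genotype] = []
    for tr in traits:
        for c in cs:
            if spec.mechanism == "discrete":
                out.append(Genotype("discrete", c=float(c), alpha=float(tr)))
            else:
                out.append(Genotype("continuous", c=float(c), gamma=float(tr)))
    return out
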