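# Methods

## Model summary and assumptions

`sporeloner` simulates a well-mixed population of sporulating social amoebae
cycling between feast and famine.  The model is *socially neutral*: genotypes
never interact except through the shared resource pool, and the spatial
aggregation process is not modelled.  Whatever "dominance" the assays report
is therefore attributable to ecology and life-history tradeoffs alone — that
is the point of the package.

Assumptions baked into the equations:

* No cell death during growth (starvation causes essentially all mortality).
* One resource unit converts into one cell, so `Σ X + R` is invariant during
  growth.
* Partitioning (discrete mechanism) and stalk/spore differentiation are
  instantaneous at starvation onset; stalk cells are committed at onset and
  leave the system.
* Counts are continuous densities: no demographic noise, no mutation,
  no recombination.  The only stochasticity is the environment (exponential
  starvation times) and the log-normal initial condition.
* Spore germination is nutrient-triggered: if a pulse is exhausted before the
  lag `τ` has elapsed, the spores stay dormant (still decaying at `δ`) until
  the next pulse.  Starving solitary cells that survive to the next pulse
  feed immediately and their survival clock resets; they re-partition at the
  next onset together with their descendants.
* Continuous mechanism: aggregation (rate `γ`) and intrinsic mortality (the
  hazard of the survival curve) act independently on solitary cells, so
  `N(t) = N₀ e^{−γt} S_c(t)`; the aggregated pool obeys
  `dA/dt = γN − δA`, and the spore fraction `s` is applied to the aggregated
  pool at measurement.  The aggregation-versus-survival race this encodes is
  the package's own formulation of the continuous switch.

## Parameters

| symbol | meaning | unit | default | provenance |
|---|---|---|---|---|
| `s` | spore fraction of aggregated cells | — | 0.8 | reference parameterization |
| `δ` | spore death rate | 1/h | 1e-4 | assumed ("very low") |
| `τ` | germination lag | h | 4 | assumed |
| `μ` | survivorship time-scale rate | 1/h | 0.005 | assumed (= 1/T_sur) |
| `T_sur` | maximum solitary-cell lifetime | h | 200 | reference parameterization |
| `β(c)` | survivorship exponent `3.1 − 4c` | — | — | reference parameterization |
| `ν(c)` | spore viability `1.1 − 2c` | — | — | reference parameterization |
| `R_half` | Michaelis–Menten half-saturation | resource | 1e7 | assumed |
| `c` range | admissible division rates | 1/h | 0.05–0.45 | reference parameterization |
| `R₀` | resource pulse | resource | 1e8 | reference parameterization |

`μ = 1/T_sur` keeps `μt ≤ 1` on the whole survival domain, which makes the
survival curves ordered in `c` at *every* time (faster dividers never
outlive slower ones while starving) — the ordering the model's tradeoff
narrative needs.  `δ`, `τ` and `R_half` are order-of-magnitude choices; all
four are plain configuration values, and every echoed configuration tags each
parameter `paper`/`assumed`/`user` so downstream results carry their
provenance.  Validation enforces `β(c) > 1` and `0 ≤ ν(c) ≤ 1` over the
admissible `c` range at construction time; the sensitivity variants
(`β = 5.1 − 8c`, `5.5 − 10c`, `19 − 40c`) are reachable by overriding the two
`β` coefficients, with no separate code path.

Trait grids include both endpoints and are built with integer-index
arithmetic (`start + k·step`) to avoid floating-point step accumulation.  The
refined stochastic-environment sampling (step 1e-4 on `α ∈ [0, 0.1]`, step
0.01 above) enumerates 1091 aggregation-trait values — 1001 below 0.1 and 91
above, sharing the 0.1 endpoint — times 41 division rates.

## Numerical scheme

**Growth.**  Instead of stepping the consumer-resource ODEs, the integrator
uses the exact substitution `u(t) = ∫ R/(R_half+R) dt`, under which every
genotype grows as `X_i(0) e^{c_i u}` and
`R(u) = R(0) − Σ_i X_i(0)(e^{c_i u} − 1)`.  Resource exhaustion becomes a
one-dimensional root find (Brent, bracket padded so a single-genotype
population cannot land exactly on the analytic bound), and conservation of
`Σ X + R` holds to round-off *by construction*.  Terms are evaluated as
`exp(log X_i + c_i u)` so that near-extinct genotypes can coexist with large
ones without overflow.  Because Michaelis–Menten resources reach zero only
asymptotically, starvation fires at `R ≤ 1e-9 · R(0)`, after which R is
clamped to zero; the bias is a 1e-9 relative loss per cycle.  Wall-clock
time is recovered from `dt/du = (R_half + R)/R`: the logarithmically
divergent part near exhaustion is integrated analytically against the
linearised resource and the smooth remainder by 64-point Gauss–Legendre.
Partial growth up to a fixed time (needed for the germination lag) integrates
the scalar ODE `du/dt = R(u)/(R_half + R(u))` with `solve_ivp` at
`rtol = 1e-10`.

**Starvation.**  All starvation-phase dynamics have closed forms (exponential
spore decay; `X̃ · S_c(T)` for solitary pools) and are evaluated
analytically — no ODE stepping.  The continuous-mechanism aggregated pool
needs the integral `∫ γ e^{−γu} S_c(u) e^{δu} du`, computed in the variable
`w = e^{−γu}` (exact for arbitrarily large `γ`, which is how the
`γ → ∞ ≡ α = 1` consistency check passes to 0.1%) on a composite 32-point
Gauss–Legendre rule with geometric breakpoints toward `w = 0`.  Tests verify
both pools against an independent fine-tolerance `solve_ivp` integration of
the hazard + decay system to 1e-6 relative.

**Degenerate inputs and tie-breaks.**  A zero-resource pulse is an immediate
starvation onset; a population with spores but no vegetative cells waits out
the lag with the pulse untouched; total extinction raises `ExtinctionError`
rather than returning silently.  Chimeric mixes in which neither genotype
sporulates (two all-loner strains) are scored 0.5/0.5 and flagged as ties — a
convention, needed because fast-environment winners have `α = 0`.  Dominance
ties use a relative spore-difference tolerance of 1e-9; ranking ties are
broken by average chimeric success, then input order, both recorded.

## Simulated experiments and scale

The paper-scale configuration (44k-genotype grids, 10⁸-hour horizons,
20 replicates) is expressible but deliberately guarded behind
`--allow-paper-scale`; the package's own experiments run at desk scale:

* a reduced grid of 9 `α` values × 5 `c` values (45 genotypes);
* deterministic winner recovery at `T = 10, 158, 199` h with a 10⁶-hour
  horizon (≈ 10⁵, 6×10³ and 5×10³ cycles respectively);
* stochastic sweeps over `λ_T ∈ [10, 10⁴]` h with 5 replicates and horizons
  of 10⁵–10⁶ h chosen so each run spans hundreds to tens of thousands of
  cycles.

At these sizes the qualitative selection structure is already unambiguous:
deterministic environments select pure strategies with the `α = 0 → α = 1`
switch between 158 h and 199 h (near the loner lifespan), and stochastic
environments select `α = 0` at `λ_T = 10` h, interior bet-hedging values at
intermediate `λ_T`, and `α = 1` at `λ_T = 10⁴` h, with per-replicate winners
almost always identical.  Winner determination measures spores + solitary
cells per genotype at the first starvation onset at or after the horizon — a
well-defined event at which every living cell is classified — and stochastic
environments take the argmax of the mean relative abundance across
replicates (per-run winners are also reported).

## What the synthetic environments do and do not capture

The environment generator reproduces the modelled world exactly: i.i.d.
exponential starvation times, fixed-size resource pulses, log-normal initial
abundances.  It does not emulate features of real populations outside the
model's scope — spatial structure and dispersal, seasonally correlated
starvation times, variable pulse sizes, demographic noise at low cell
numbers, mutation, or within-aggregate genotype interactions (including
stalk-height/dispersal tradeoffs and social-parasite mutants).  Passing tests
therefore demonstrate the internal logic of the socially-neutral tradeoff
model, not a calibrated prediction for any particular strain collection.

## Known limitations

* With pruning disabled (the default) near-extinct genotypes are carried as
  denormally small floats; this is intentional, since pruning can in
  principle alter long-run winners, but it makes paper-scale runs slower.
* The continuous mechanism's evolution loop evaluates one quadrature per
  genotype per cycle (Python loop); it is intended for small grids.
* `CycleRecord.onset_stalk` is reported as NaN for the continuous mechanism,
  where stalk commitment is spread over the starvation phase rather than
  located at onset.
* Deterministic-environment winners are computed from a single trajectory;
  the initial-condition randomness only affects transients, which was spot
  checked but is not re-verified per run.
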