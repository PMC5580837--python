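# Methods

This note documents the models, numerical choices and synthetic study
conditions behind `aquarecon`, and what the test suite does and does
not demonstrate.

## Scope and philosophy

The package reconstructs monthly mean drinking-water VOC concentrations
by chaining physically based simulators constrained to the kinds of
records that survive from the 1950s–1980s: well service dates and
capacities, treatment-plant demand, utility log books, and sparse
measurements. No real site data are included; the synthetic-site
generator reproduces the *structure* of such a study area so that every
stage can be verified against closed forms and against truths the
package itself generates at finer resolution. Passing tests therefore
demonstrate internal correctness and recoverability under the stated
synthetic conditions — not calibration to any real aquifer.

The pipeline has no health-outcome inputs of any kind; it produces
exposure estimates only, which keeps exposure modelling structurally
blinded to outcomes.

## Groundwater flow

Confined (linear) Darcy flow on a uniform cell-centred grid,
7-point stencil. Layers are `aquifer` (horizontal transmissivity
`kh·b` plus vertical exchange) or `aquitard` (vertical leakance
`kv/b` only, no horizontal flow), mirroring a stacked
aquifer/semi-confining-unit sequence; the default stack is 7 layers
with layers 0, 2, 4, 6 as aquifers. Confined flow keeps the system
linear and robust at desk scale; water-table (unconfined)
nonlinearity is out of scope and not needed by any verification here.

* Intercell conductance: harmonic composition; vertical conductance
  between layer centres uses series resistances `b/2kv`.
* Boundaries: Dirichlet constant-head cells; streams as one-way-coupled
  head-dependent flux `Q = C·(stage − h)` with fixed stage (creeks act
  as boundary controls on flow direction, no stage routing).
* Wells: monthly stress periods (rates constant within a month, months
  atomic); extraction is apportioned across a well's screened layers by
  layer-transmissivity share, fixed a priori so flow and transport
  agree on what a well draws.
* Transient stepping: implicit Euler with `substeps_per_month` equal
  sub-steps (default 2); storage coefficient `Ss·b` per cell. The LU
  factorization is reused across sub-steps with equal length.
* Budgets: every stress period closes a volumetric budget from exact
  per-sub-step balances; discrepancy above 0.5 % raises.

Verification: exact Laplace profile on a strip; the 1-D recharge
closed form; second-order convergence against a sinusoidal-recharge
solution; Theis drawdown within 5 % for radii 2–10 cells (domain sized
so the month-one radius of influence stays inside the boundary);
maximum principle; face-flow divergence closure.

## Transport

Operator splitting per sub-step, in order: advection, dispersion,
decay.

* **Advection**: explicit first-order upwind in flux form on the flow
  solver's face flows, automatically sub-stepped so every cell's
  Courant number stays ≤ 1. Upwind was chosen over higher-order/TVD
  schemes for monotonicity and simplicity; its numerical dispersion is
  acknowledged and absorbed into the 5 % benchmark tolerances.
  Boundary inflows (recharge, stream gain, constant-head inflow) carry
  clean water; outflows and wells remove water at the cell
  concentration; elastic-storage exchange carries the cell
  concentration so transient water-balance closure does not distort
  concentrations.
* **Dispersion**: backward Euler on a 7-point diffusion operator with
  the diagonal (longitudinal/transverse) approximation of the
  dispersion tensor, `D_xx = αL·vx²/|v| + αT·(|v|² − vx²)/|v| + Dm`,
  face coefficients by arithmetic averaging. The linear system is
  solved by conjugate gradients on the similarity-symmetrized form with
  warm starts (`rtol 1e-12`); this replaces a per-month LU
  factorization and dominates neither runtime nor accuracy.
* **Decay**: exact exponential, rate `λ/R`.
* **Retardation** divides velocities, dispersion and decay — a retarded
  solute follows the conservative solution with time stretched by `R`.
* **Sources** are constant-concentration cells (not mass loadings) held
  at their value during their active window and released afterwards;
  this matches how source histories are documented (concentration and
  duration) and preserves a testable maximum principle.
* Monthly snapshots are the state at the final sub-step of each month —
  the "last day of the month" convention used by every downstream
  stage.
* Decay by-products are not tracked; each VOC is treated as an
  independent contaminant.

Verification: exact reaction step; Ogata–Banks breakthrough within 5 %
at grid Peclet 2; conservative-tracer mass constancy within 0.5 %;
linearity in source strength to 1e-9; no new extrema from advection;
monotone dilution after sources expire and pumping stops.

## Well schedules and WTP mixing

Demand is allocated capacity-proportionally across in-service wells.
This is the minimal rule consistent with the documented constraints
(capacities, service windows, monthly totals); alternative policies can
be slotted in, and demand exceeding in-service capacity is an error
rather than silently renormalized. Mixing at the treatment plant is a
flow-weighted mean (continuity + conservation of mass) with no
treatment removal; the mixed value stands for the whole service area.
Months without pumping are explicitly missing — never zero, since "no
pumping" is not "clean water". Exceedance periods are maximal runs of
months *strictly* above the MCL ("exceeds" is a strict inequality; a
fixed tie rule is required and this is it); missing months break runs.
Monthly rates rather than pumped volumes serve as mixing weights — the
two are indistinguishable at monthly resolution.

## Interconnection (two-state Markov model)

Transfer/no-transfer at monthly resolution over an April–August active
season; each season is an independent chain (the dry-season conditions
that drive transfers reset annually). Transition probabilities are
maximum-likelihood counts over documented consecutive-month pairs
within a season; pairs spanning unknown months or season gaps are
excluded. Undocumented months are imputed by exact bridge sampling:
`P(s_t | s_{t−1}, next documented b at lag d) ∝ P(s_t|s_{t−1})·P^d[s_t,b]`,
which uses the documented record on *both* sides of a gap; the sampler
is unit-tested against full path enumeration on seasons with up to
three unknown months. Monthly means blend an on-month's transfer hours
at the transfer concentration with background for the rest of the
month; documented hours override the configured default (no default is
claimed from any source — event duration is a template parameter).

The generator's truth chain is parameterized by stationary
on-probability `p_on` and autocorrelation `persistence`
(`P(on|on) = persistence + (1−persistence)·p_on`,
`P(on|off) = (1−persistence)·p_on`), so `p_on = 0` is all-off and
`persistence = 0` is i.i.d.

## Distribution network

Demand-driven extended-period simulation in the EPANET-2 sense:
nodal continuity with Hazen–Williams head loss, solved per time step by
Newton iteration on junction heads with a backtracking line search;
pump curves `h0 − rQ²` are extended linearly past shutoff during
iteration (with a check valve on the converged flow) to avoid dead
zones. Water quality is Lagrangian plug flow — parcel queues per pipe,
complete mixing at nodes, nodes processed in flow-topological order so
pass-through within a step is exact — with no decay (VOC loss over
hours-to-days in mains is negligible at monthly aggregation). The
contaminated sending system is abstracted as an infinite reservoir at
fixed head and concentration behind the booster pump; a bypass valve
scenario feeds by gravity with the pump absent. Area means are
demand-weighted over an area's junctions and the event window. Tanks
and pressure-dependent demands are out of scope. A minimal EPANET-INP
dialect (RESERVOIRS/JUNCTIONS/PIPES/PUMPS/VALVES/DEMANDS/PATTERNS/
STATUS; m, mm, m³/day) is read for interoperability; other sections are
rejected by name.

Because network transport is conservative and linear in the boundary
concentration, one event simulation at a reference concentration gives
per-area response fractions valid for any month's WTP value; the
two-system reconstruction exploits this instead of re-running the EPS
per month.

## Uncertainty

Parameters address any numeric field of the YAML configuration by
dotted path. Distributions: uniform, log-uniform, normal, log-normal,
triangular, truncated to finite bounds via CDF rescaling. LHS uses
scipy's LatinHypercube engine (one draw per equal-probability stratum
per parameter, strata permuted independently). Each realization re-runs
the full flow→transport→mixing chain on the small template; failures
are recorded and reported, not dropped (dropped tails bias
percentiles), and > 20 % failures abort. Percentile bands (2.5, 25, 50,
75, 97.5) are computed per month; the uncertainty ratio is
97.5th/2.5th at the peak-median month.

## Synthetic study conditions

The templates hard-code qualitative geometry only: sources up-gradient
of the well field, a constant-head upland boundary, a stream boundary
with a bend that curves plumes, wells screened in the deeper aquifers.
The study conditions are fixed once in the generator:

* grid 7 layers × 20×20 cells (16×16 for the landfill) at 90 m spacing;
  thicknesses 8/3/10/3/15/5/20 m; aquifer `kh` 10–20 m/day (kv =
  kh/10), aquitard `kv` 5e-4–5e-3 m/day; porosity 0.2/0.35; recharge
  4e-4 m/day — generic coastal-plain magnitudes;
* a 15-year monthly clock; sources switch on in the second January
  (30 months of predevelopment-plus-startup lead-in) and persist;
* source concentrations 2000–8000 μg/L; TCE-like transport parameters
  (R = 2, λ = 1e-4 /day, αL = 30 m, αT = 3 m, MCL 5 μg/L);
* 4 wells (industrial) including a disjoint replacement pair, or 1
  late-starting well (landfill) that begins pumping 7½ years after the
  source switches on and is removed a year before the clock ends;
* demand at half the weakest in-service capacity with a mild seasonal
  cycle, so the schedule is always feasible;
* observation noise: head SD 0.3 m, concentration SD 25 μg/L (truncated
  Gaussian; a multiplicative log-normal option exists because
  water-quality data are non-negative and right-skewed) — magnitudes
  chosen as plausible field values, not taken from any source;
* interconnection: April–August seasons, `p_on` 0.45, persistence 0.6,
  half of months documented, default event 120 h.

One global seed fans out to per-component substreams via
`np.random.default_rng([seed, component_id])`, so adding a component
never perturbs another's draws.

What the synthetic sites do **not** emulate: real geometry or
calibrated parameter fields, variably spaced grids, unconfined
water-table dynamics, multiphase (LNAPL) fuel transport, tanks and
pressure-dependent network demands, and measured-data calibration
loops. The residual report plus OAT tooling stand in for the
expert-in-the-loop calibration cycle; there is no automatic optimizer.

## Problem sizes and determinism

Default verification sizes were chosen so the whole suite runs on one
CPU in minutes: the small template (2 800 cells × 180 months) runs the
full chain in about one second; the Monte Carlo acceptance batch uses
n = 200 realizations; the Markov recovery uses 5 000 synthetic months;
the Theis and Ogata–Banks benchmarks use 81×81 and 100-cell grids.
Every stochastic path is seeded; re-running any stage with the same
configuration and seed reproduces outputs byte-for-byte (CSV reports
included).

## Known limitations

* First-order upwind advection smears sharp fronts; the Ogata–Banks
  tolerance (5 %) absorbs this at grid Peclet 2, but coarse grids will
  under-predict peak concentrations at sharp plume edges.
* The dispersion tensor's off-diagonal terms are dropped (diagonal
  approximation); cross-dispersion in strongly rotating flow fields is
  under-represented.
* Static transmissivity shares for well extraction ignore transient
  vertical flow redistribution along the screen.
* The Markov model has two states and no hydrologic covariates; a
  drought-driven transfer process would need exogenous forcing.
* Uncertainty propagation treats parameters as independent;
  correlations (e.g. kh across layers) are not modelled.
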