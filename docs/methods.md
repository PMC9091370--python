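# Methods

## Model and assumptions

fermenet analyzes *steady states only*. The chemostat is glucose-limited
and perfectly mixed; tracked macroscopic variables are biomass density X
(gDW L⁻¹), one substrate (glucose, mM) and one product (citramalate,
mM). Setting the time derivatives of the tank balances to zero yields

* growth: μ = D (a hard equality — see "washout" below),
* substrate: D·c_g = u_g·X + D·s_g with s_g ≥ 0,
* product: |u_c|·X = D·s_c with s_c ≥ 0,

where the cell-side fluxes u_g, u_c, μ come from a genome-scale
constraint-based model embedded in the same Flexible Net. The cell is
assumed to be at internal steady state (the FBA assumption): S·v = 0
with L ≤ v ≤ U. Concentration-independent kinetics inside the cell, no
maintenance beyond what the metabolic model encodes, no transporter
saturation caps on uptake or secretion (a known refinement), and no
additional medium components are modeled.

Sign conventions: FN transition fluxes are non-negative, so reversible
reactions are unfolded into `_f`/`_b` copies and product secretion —
negative in the ODE convention — is carried by an arc oriented out of
the cell; in every solution s_c ≥ 0.

## Steady-state constraint semantics

Variables: one flux `v[t]` per transition, one concentration `m[p]` per
place observed by an intensity handler, one contribution `w[h]` per
handler. A transition with no handlers has `v[t]` bounded directly by
its λ₀ interval; otherwise `v[t] = λ0[t] + Σ w[h]`. Unguarded handler
relations are linear rows; *guarded* handlers have no monolithic linear
encoding and are solved region-wise. Place balances sum the event-handler
stoichiometries times their transitions' fluxes to zero.

## The piecewise relaxation

Each bilinear coupling w = v·X is replaced, inside region
[X_{i−1}, X_i] of a partition of [Xmin, Xmax], by
X_{i−1}·v ≤ w ≤ X_i·v. One partition of X serves all three couplings.
Properties relied on (and tested):

* any exact bilinear point is feasible in its region ⇒ the region-wise
  maximum is an **upper bound** on the true optimum;
* nested refinement shrinks every region's feasible set ⇒ the bound is
  **non-increasing** in n for nested partitions (the convergence study
  uses n = 1, 2, 4, …);
* a fixed-X grid enumeration (`oracle_solve`) is a **lower bound**; the
  two sandwich the true optimum and meet as both are refined.

Regions are solved as independent LPs (HiGHS via scipy); interior
breakpoints belong to both adjacent regions (closed intervals), which is
harmless when maximizing and avoids boundary infeasibility. Ties across
regions keep the lowest index, for determinism. An equivalent
single-MILP formulation (one binary per region, big-M on the bilinear
rows, exact indicator rows on X) is available as `mode="milp"` purely as
a cross-check; it requires finite exchange bounds and is tested for
equivalence on the toy producer.

A consequence of relaxation worth knowing: in the region touching
Xmin = 0 the lower bracket is 0·v ≤ w, so a coarse partition can report
nonzero product output even with zero feed; the artifact vanishes as
n grows and never affects the exact fixed-X (prediction) mode.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| regions n | 100 | – | plateau of the convergence study; good accuracy/run-time trade-off |
| Xmin | 0 | gDW L⁻¹ | cell density cannot be negative |
| Xmax | 1.5·0.5·c_g | gDW L⁻¹ | 0.5 gDW per g glucose is a generous aerobic yield; ×1.5 headroom — bounds need not be tight, they only frame the partition |
| MW glucose | 180.16 | g mol⁻¹ | tank I/O is in g L⁻¹, internals in mM |
| MW citramalate | 148.12 | g mol⁻¹ | idem |
| oracle grid | 2001 points | – | resolves the toy optimum to ≪1 % |
| LP feasibility / optimality tol | 1e−9 / 1e−6 | – | standard HiGHS practice |

Productivity conversions: VP (g L⁻¹ h⁻¹) = flux(t_cout) in mM h⁻¹ ×
MW_product/1000; PS = VP/c_s; Y_P/S = VP/(D·c_s). The identities
VP = PS·c_s and VP = D·s_c hold by construction and are asserted in
tests at 1e−9 and 1e−6.

## Washout

μ = D is imposed as an equality in all modes. If D exceeds the cell
model's maximal growth rate the constraint system is infeasible — there
is no steady state with growing biomass — and drivers return an explicit
`status="infeasible"` result rather than X = 0 with idle cells. This is
a deliberate modeling choice: the zero-biomass "solution" is degenerate
(cell fluxes are unconstrained by the tank at X = 0) and reporting it as
optimal would be misleading.

## Prediction mode

With X fixed to a measured biomass the couplings are linear and a single
exact LP is solved. Among the (generally non-unique) steady states
compatible with (c_g, D, X) the mode reports the one maximizing product
outflow — the same objective as optimization mode — so predicted
concentrations are the model's best-case; this is an assumption, not a
derived fact, and alternative objectives (e.g. maximize growth margin)
would change predictions. Relative error against a measurement is
100·(observed − predicted)/predicted.

## Synthetic generator

`make_toy_producer(k=0.1, u_max=10)` builds the smallest cell with the
full macro/micro structure: bounded uptake, growth at μ = k·v_b, 1:1
partitioning of internal substrate between biomass precursor and
product. Its chemostat optimum has the closed form
VP* = D·c_g·(1 − D/(k·u_max)) at X* = D·c_g/u_max (re-derived in the
`toy_closed_form` docstring and confirmed against the oracle in tests).
Defaults give μ_max = 1 h⁻¹ — a realistic *E. coli* ceiling — and, at
the default operating point (c_g = 10 g L⁻¹, D = 0.5 h⁻¹), an interior
optimum that genuinely exercises the relaxation. What it does *not*
emulate: genome-scale degeneracy (thousands of alternate optima),
maintenance ATP, byproduct secretion, transporter saturation — so
passing tests demonstrate the correctness of the coupling/relaxation
machinery, not predictive accuracy on real organisms.
`random_small_cbm` generates seeded random models (bounded source, sink,
sparse integer internal stoichiometry, ~⅓ reversible) for the FBA
equivalence and unfolding property tests.

## Numerical and degenerate-input choices

* Guards tile the observed range half-open [lo, hi), last region closed
  at Xmax, so boundary membership is deterministic; `active_region` at
  a threshold returns the upper region.
* Reactions forced backward (U < 0) unfold to forward copy [0, 0] and
  backward copy [−U, −L] (the naive formula would produce an invalid
  interval).
* Infeasible and unbounded LPs are reported as statuses, never as large
  sentinel numbers.
* Zero feed (c_g = 0) pins the feed transition's λ₀ to 0; uptake and
  residual substrate are forced to zero.
* Problem sizes used in the shipped tests and acceptance script: the
  4-reaction textbook model, the 3-reaction toy producer with up to 256
  regions and a 2001-point oracle grid, and twenty ~7-reaction random
  models — all chosen so the full suite solves thousands of small LPs in
  well under a minute.

## Known limitations

* Steady states only; no transient (time-course) integration of the
  tank ODEs, no batch/fed-batch modes.
* Genome-scale predictions inherit whatever medium/uptake bounds the
  SBML carries; fermenet does not curate media.
* Intensity-handler inequality relations (uncertain kinetics bands) are
  supported structurally but not exercised by any shipped study.
* The region-wise solver assumes the partitioned variable is X; 
  partitioning a flux instead is not implemented (X keeps the region
  count — and hence the work — independent of the number of couplings).
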