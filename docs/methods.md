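# Methods

## The model

A constraint-based metabolic model is a stoichiometric matrix S (m
metabolites × n reactions) with per-reaction flux bounds LB_j ≤ v_j ≤ UB_j
(mmol·gDW⁻¹·h⁻¹). Under the steady-state approximation, feasible flux
distributions satisfy S v = 0. Flux balance analysis (FBA) selects among
them by maximizing one flux, conventionally the biomass pseudo-reaction —
a single LP solved here with HiGHS through `scipy.optimize.linprog`.

Reaction deletions enter through binary variables y_j on the inessential
reactions J_I (the essential set J_E is never knockable):

    LB_j (1 − y_j) ≤ v_j ≤ UB_j (1 − y_j),   j ∈ J_I,
    Σ_j y_j = K.

Because LB/UB are constants this is linear in (v, y) for bounds of any
sign — no big-M reformulation. The cardinality constraint defaults to
equality (exactly K deletions); a flag relaxes it to ≤ K, which avoids
padding a design with deletions of zero-flux reactions when fewer suffice.

## Bi-objective frontier

The design problem maximizes the tuple (v_product, v_biomass) over this
mixed-binary feasible set. `solve_bop` computes the nondominated frontier
exactly by dichotomic weighted-sum search: solve the two lexicographic
anchor problems (product-first and biomass-first), then for each adjacent
pair of points probe the weight vector normal to their chord; a probe that
beats the chord by more than 1e-6 (relative) yields a new point and two
subproblems, otherwise the segment is closed. This returns every **extreme
supported** nondominated point. Two classes of nondominated points are
deliberately outside this default path:

- *supported but collinear* points (lying exactly on the chord between two
  extreme points), which no weighted-sum scheme can certify, and
- *unsupported* points (inside the convex hull), which exist in general
  MILPs.

Both are reachable through `epsilon_constraint_front`, a sweep that fixes a
grid of floors on the product flux and maximizes biomass lexicographically;
its resolution is the user-chosen grid step. For the branched networks used
in testing, all nondominated extreme points are supported and the
weighted-sum front is complete.

Ties among equally-scored weighted optima are broken by lexicographic
re-optimization (first-listed objective first) with a 1e-9 relative slack
when pinning intermediate scores, so reported points are deterministic
regardless of which optimum the solver visits first. Witness knockout sets
remain solver-dependent where several sets support the same point — the
enumeration stage exists precisely to list them all.

## Enumeration of equivalent deletion sets

For a frontier point (v*_prod, v*_bio), the feasibility program pins both
objective fluxes and searches for any (v, y). Each discovered deletion set
ȳ is excluded, together with all of its supersets, by the no-good cut
Σ_{j∈supp(ȳ)} y_j ≤ K − 1, and the program is re-solved until infeasible.
The final infeasibility is a certificate of completeness (`exhausted=True`).
A `max_sets` budget (default 1000, warning logged) guards against the
combinatorial growth of equivalent sets with K; at most C(|J_I|, K)
iterations are possible. Results are reported in canonical lexicographic
order so output bytes do not depend on discovery order.

The MOMA-restricted variant first minimizes the Manhattan adjustment
f(v) = Σ_i |v_i − v̄̄_i| to a reference flux (by default the biomass-optimal
FBA solution, i.e. the wild-type proxy), linearized with deviation
variables z_i ≥ ±(v_i − v̄̄_i). The L1 norm — rather than the classical
quadratic form — keeps the program integer-linear and favors sparse
adjustments. After the first solve proves f*, the constraint f(v) ≤ f* + δ
pins the distance and the same cut loop enumerates only distance-minimal
sets, a subset of the full list.

## Numerical choices

- **Objective pinning.** Exact equality on floating MILP objectives is
  brittle; point values are pinned as two-sided windows of half-width
  `objective_match_tol` (default 1e-6).
- **Distance ties.** Pinning the objectives in a ±δ window perturbs each
  deletion set's attainable L1 distance by O(δ); sets tied at the exact
  point can therefore separate by a few δ inside the window. Distance
  minimality is judged at 10·δ (`MOMA_TIE_FACTOR`), applied identically in
  the MILP cap and in the brute-force oracle, so "distance-minimal subset"
  is well defined on both code paths.
- **Solver tolerances.** MILPs run with a zero relative MIP gap and
  feasibility tolerances of 1e-9 — the default MIP feasibility tolerance
  (1e-6) is the same width as the pinning windows and degenerates inside
  the solver; LPs use HiGHS defaults.
- **Infinite bounds** must be capped (±1000 by convention, matching common
  genome-scale practice) before any MILP; `cap_infinite_bounds` is
  idempotent and the builders refuse uncapped models rather than guessing.
- **Degenerate inputs.** K = 0 enumerations return the unique empty set and
  stop (the no-good cut of the empty set would read 0 ≤ −1 and is signaled
  explicitly as an error if requested directly). Infeasible pinned points
  yield an empty result flagged `inconsistent-point`. Infeasible anchors
  yield an empty front with `status="infeasible"`.
- **Determinism.** HiGHS is deterministic single-threaded; all writers sort
  canonically; `SolverConfig.random_seed` is recorded for provenance only.

## Synthetic networks and oracles

The generator emulates the core trade-off of strain design: one bounded
uptake feeding a hub metabolite drained by parallel branches (biomass,
product, by-products), each with its own capacity, optionally with a
duplicated product branch so genuinely equivalent deletions exist. Closed
forms follow from capacities alone (e.g. growth equals uptake when branches
are unconstrained), and exhaustive K-subset enumeration is cheap.

The brute-force oracles are an independent code path built only from
single-objective LPs: `brute_force_front` scans every K-subset over a dense
weight grid (default 101 points; the endpoints are the lexicographic
anchors) with the same lexicographic tie-break, dominance-filters the
union, and reduces it to the vertices of its upper convex envelope — the
extreme-supported notion the dichotomic search is contracted to return,
with the collinearity tolerance (1e-6, scaled) matched to the dichotomic
stopping rule. `brute_force_enumerate` tests every K-subset by feasibility
LP and computes per-subset minimal L1 distances.

What these fixtures do **not** emulate: reversible fluxes, internal cycles,
cofactor coupling, alternate optima of genome-scale FBA, and realistic
network topology. Passing the oracle-equivalence tests therefore certifies
the optimization machinery (frontier exactness, enumeration completeness,
distance restriction), not biological fidelity on genome-scale models. On
real models the choice of FBA reference among alternate optima can affect
which sets the MOMA restriction keeps; the reference is an explicit input
for exactly that reason.

## Problem sizes

Tests and the acceptance script run the toy (6 reactions) plus seeded
branched networks with 3–5 branches (|J_I| ≤ 6) at K ∈ {1, 2}, sizes at
which the brute-force oracle is exact and fast while exercising every MILP
path; the oracle guard refuses instances beyond 10⁴ subsets. Genome-scale
runs (thousands of reactions, hundreds of candidates) use the same code
path and are driven by `scripts/yeast_case_study.py` against a
user-supplied SBML file.

## Known limitations

- Only two objectives are handled by the exact frontier algorithm;
  `weighted_sum_solve` accepts more but then samples supported points only.
- Deletions are reaction-level; gene–protein–reaction rules are out of
  scope, as are thermodynamic constraints and flux-variability analysis.
- Equivalent-set counts at loosely pinned points can depend on the pinning
  tolerance; the defaults are stated above and configurable.
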