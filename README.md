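# paretoflux

Exact bi-objective knockout design for constraint-based metabolic models.

Metabolic engineers routinely face competing objectives: a target compound
(ethanol, succinate, ...) competes with biomass for the carbon source, so
maximizing one degrades the other. Instead of fixing a growth threshold a
priori (the bi-level OptKnock style), `paretoflux` computes the **entire
Pareto frontier** of the two objectives under exactly K reaction deletions,
then **enumerates every equivalent deletion set** behind each frontier
point — optionally keeping only the sets whose flux state is closest (in
Manhattan norm) to the wild type, the L1 form of minimization of metabolic
adjustment (MOMA). All programs are solved exactly with HiGHS
(mixed-integer, via SciPy); no heuristics.

## The optimization core

With stoichiometric matrix S, bounds LB/UB, binaries y_j marking deletions
of inessential reactions J_I:

    max (v_prod, v_biomass)
    s.t. S v = 0
         LB_j ≤ v_j ≤ UB_j                        j ∈ J_E
         LB_j (1−y_j) ≤ v_j ≤ UB_j (1−y_j)        j ∈ J_I
         Σ y_j = K,   y_j ∈ {0,1}

- **Frontier** — dichotomic weighted-sum search returning all extreme
  supported nondominated points (ε-constraint sweep available for the
  rest).
- **Enumeration** — at a frontier point (v*_prod, v*_bio), pin both fluxes
  and iterate no-good cuts Σ_{j∈found} y_j ≤ K−1 until the solver certifies
  no further deletion set exists.
- **MOMA restriction** — minimize f(v) = Σ_i |v_i − v̄̄_i| against a
  wild-type reference first, pin f*, then enumerate only distance-minimal
  sets.

Every piece is cross-checked in the test suite against an independent
brute-force oracle (exhaustive knockout subsets × plain LPs).

## Worked example

The bundled toy network routes a bounded uptake (10 units) into a hub that
drains through a biomass branch (R1) and a *duplicated* product branch
(R2, R2b):

```sh
paretoflux fixtures --out-dir fixtures      # writes fixtures/toy_b.json
paretoflux pipeline --model fixtures/toy_b.json --output-dir run \
    -K 1 --mode moma --candidate-mode all_inessential
```

The pipeline prints (abridged):

```
"reference_fba":  {"biomass_optimum": 10.0}
"candidates":     {"n_candidates": 3}
"pareto_front":   {"status": "ok", "n_points": 2}
"enumeration":    {"mode": "moma", "n_sets_total": 5, ...}
```

and `run/enumeration.tsv` contains:

```
point                       set_index  knockouts  f_star     exhausted
(9.99999999,0)              0          R1         39.999996  true
(9.99999999,0)              1          R2         39.999996  true
(9.99999999,0)              2          R2b        39.999996  true
(9.99999912e-09,9.99999999) 0          R2         0          true
(9.99999912e-09,9.99999999) 1          R2b        0          true
```

Reading: the frontier has two points, (10, 0) and (0, 10). At the
full-growth point either copy of the duplicated product branch can be
deleted at **zero** flux adjustment — the mutant can reuse the wild-type
flux state exactly. At the full-product point every singleton deletion
supports the fluxes, all at the same minimal adjustment f* = 40 (10 units
rerouted across four reactions: biomass branch off, product branch on,
biomass export off, product export on). `exhausted: true` means the solver
*proved* no further equivalent set exists.

Genome-scale models are read from SBML (L3/FBC v2); see
`scripts/yeast_case_study.py` for the yeast fermentation bound recipe
(glucose uptake −10, oxygen reduction ≤ 10, triose-phosphate isomerase
≤ 6, infinite bounds capped at ±1000) applied to a user-supplied consensus
model.

## Layout

- `paretoflux.model` — domain types, JSON dialect (schema in
  `docs/model_schema.md`), SBML reader, bound capping/overrides
- `paretoflux.lp` — FBA, knockout simulation, essentiality screen, the
  single-deletion OptKnock-style comparator
- `paretoflux.pareto` — weighted-sum / dichotomic frontier, dominance
  filter, ε-constraint sweep
- `paretoflux.enumeration` — no-good-cut enumeration, L1-MOMA restriction
- `paretoflux.synth` — toy generators and brute-force oracles
- `paretoflux.pipeline` / `paretoflux.cli` — the 4-step workflow
  (reference FBA → candidates → frontier → enumeration) as a CLI

See `docs/methods.md` for the model assumptions, numerical choices and
known limitations.
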