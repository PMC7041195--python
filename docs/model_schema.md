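# JSON model dialect

The canonical on-disk format for `paretoflux` models (the SBML L3+FBC v2
reader is the alternative input path; there is no SBML writer).

```json
{
 "metabolites": [
  {"id": "A", "name": "hub", "compartment": "c"}
 ],
 "reactions": [
  {"id": "EX_glc", "name": "uptake", "stoich": {"A": 1.0}, "lb": 0.0, "ub": 10.0},
  {"id": "R1", "stoich": {"A": -1.0, "B": 1.0}, "lb": 0.0, "ub": "inf"}
 ],
 "biomass": "EX_bio",
 "targets": ["EX_prod"],
 "essential": ["EX_glc", "EX_bio", "EX_prod"]
}
```

Rules:

- `metabolites[].id` — required, nonempty, unique. `name` and `compartment`
  are optional free text.
- `reactions[].id` — required, unique. `stoich` maps metabolite id to its
  coefficient (negative = consumed) and must be nonempty; every referenced
  metabolite must exist.
- `lb` / `ub` — required (a missing bound is a format error, never a silent
  default). Numbers, or the strings `"inf"` / `"-inf"` for unbounded
  reactions; `lb <= ub`. Reversibility is encoded purely by `lb < 0`.
- `biomass` — required; must name an existing reaction.
- `targets` — ordered list of product objective reaction ids (may be empty;
  the frontier solvers then require explicit `objective_ids`).
- `essential` — reaction ids that may never be knocked out (J_E); all other
  reactions form the knockout-candidate pool J_I.

List order is significant and preserved: the stoichiometric matrix uses
file order for rows and columns, and writers emit deterministic bytes so
identical models round-trip identically.

Bound overrides are supplied separately as a 3-column TSV
(`reaction_id  lower|upper  value`, `#` comments allowed).
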