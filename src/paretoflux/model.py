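"""Domain types for constraint-based metabolic models.

A model is a stoichiometric matrix S (rows = metabolites, columns =
reactions) together with per-reaction flux bounds, a designated biomass
reaction, one or more target (product) reactions, and an optional set of
essential reactions that may never be knocked out. Reversibility is encoded
purely through the bounds (a negative lower bound); there is no separate
flag.

Two on-disk dialects are supported: a small JSON format (canonical for this
package, schema in ``docs/model_schema.md``) and SBML Level 3 + FBC v2
(read-only, parsed through cobrapy/libsbml).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "BoundOverride",
    "ModelFormatError",
    "ModelValidationError",
    "load_model",
    "save_model",
    "model_to_dict",
    "model_from_dict",
    "cap_infinite_bounds",
    "apply_bound_overrides",
    "read_bound_overrides",
]

INF = math.inf


class ModelFormatError(ValueError):
    """A model file could not be parsed under the requested dialect."""


class ModelValidationError(ValueError):
    """A structurally invalid model (dangling ids, bad bounds, ...)."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass(frozen=True)
class Reaction:
    """A flux-carrying reaction: a stoichiometry column plus bounds.

    ``stoichiometry`` maps metabolite id to its coefficient (negative =
    consumed). Bounds are in mmol·gDW⁻¹·h⁻¹; infinite bounds are legal
    until :func:`cap_infinite_bounds` replaces them.
    """

    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float
    upper_bound: float
    name: str = ""

    @property
    def is_exchange(self) -> bool:
        """True when the reaction touches a single metabolite (boundary)."""
        return len(self.stoichiometry) == 1


@dataclass(frozen=True)
class BoundOverride:
    reaction_id: str
    which: str  # "lower" | "upper"
    value: float


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_id: str
    target_ids: tuple[str, ...] = ()
    essential_ids: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.target_ids = tuple(self.target_ids)
        self.essential_ids = frozenset(self.essential_ids)
        self.validate()

    # ---- structure -----------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction(self, rid: str) -> Reaction:
        try:
            return self.reactions[self.reaction_index(rid)]
        except KeyError:
            raise KeyError(f"unknown reaction id {rid!r}") from None

    def reaction_index(self, rid: str) -> int:
        idx = {r.id: i for i, r in enumerate(self.reactions)}
        return idx[rid]

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        """S as an m×n CSR matrix in file (list) order."""
        midx = {m.id: i for i, m in enumerate(self.metabolites)}
        rows, cols, data = [], [], []
        for j, rxn in enumerate(self.reactions):
            for mid, coef in rxn.stoichiometry.items():
                rows.append(midx[mid])
                cols.append(j)
                data.append(float(coef))
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(self.n_metabolites, self.n_reactions)
        )

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions], dtype=float)
        ub = np.array([r.upper_bound for r in self.reactions], dtype=float)
        return lb, ub

    def inessential_ids(self) -> list[str]:
        """Reaction ids eligible for knockout (J_I), in model order."""
        return [r.id for r in self.reactions if r.id not in self.essential_ids]

    def digest(self) -> str:
        """Stable content digest of the canonical JSON serialization."""
        payload = json.dumps(model_to_dict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    # ---- validation ----------------------------------------------------

    def validate(self) -> None:
        mids = [m.id for m in self.metabolites]
        if len(set(mids)) != len(mids):
            raise ModelValidationError("duplicate metabolite ids")
        if any(not m for m in mids):
            raise ModelValidationError("empty metabolite id")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise ModelValidationError("duplicate reaction ids")
        known = set(mids)
        for rxn in self.reactions:
            if not rxn.stoichiometry:
                raise ModelValidationError(f"reaction {rxn.id!r}: empty stoichiometry")
            for mid, coef in rxn.stoichiometry.items():
                if mid not in known:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references unknown metabolite {mid!r}"
                    )
                if math.isnan(coef) or math.isinf(coef):
                    raise ModelValidationError(
                        f"reaction {rxn.id!r}: non-finite coefficient for {mid!r}"
                    )
            if math.isnan(rxn.lower_bound) or math.isnan(rxn.upper_bound):
                raise ModelValidationError(f"reaction {rxn.id!r}: NaN bound")
            if rxn.lower_bound > rxn.upper_bound:
                raise ModelValidationError(
                    f"reaction {rxn.id!r}: lower bound {rxn.lower_bound} exceeds "
                    f"upper bound {rxn.upper_bound}"
                )
        rid_set = set(rids)
        if self.biomass_id not in rid_set:
            raise ModelValidationError(
                f"biomass reaction {self.biomass_id!r} not in the model"
            )
        for tid in self.target_ids:
            if tid not in rid_set:
                raise ModelValidationError(f"target reaction {tid!r} not in the model")
        extra = self.essential_ids - rid_set
        if extra:
            raise ModelValidationError(f"essential ids not in the model: {sorted(extra)}")


# ---- bound manipulation -----------------------------------------------


def cap_infinite_bounds(model: MetabolicModel, cap: float = 1000.0) -> MetabolicModel:
    """Replace every infinite bound by ±cap; finite bounds are untouched.

    Idempotent: reapplying with the same cap is a no-op.
    """
    if cap <= 0:
        raise ValueError("cap must be positive")
    reactions = []
    for rxn in model.reactions:
        lb = -cap if math.isinf(rxn.lower_bound) else rxn.lower_bound
        ub = cap if math.isinf(rxn.upper_bound) else rxn.upper_bound
        reactions.append(replace(rxn, lower_bound=lb, upper_bound=ub))
    return dataclasses.replace(model, reactions=reactions)


def apply_bound_overrides(
    model: MetabolicModel, overrides: Iterable[BoundOverride]
) -> MetabolicModel:
    """Return a new model with the stated bounds replaced, in order."""
    reactions = list(model.reactions)
    index = {r.id: i for i, r in enumerate(reactions)}
    for ov in overrides:
        if ov.reaction_id not in index:
            raise ModelValidationError(f"override for unknown reaction {ov.reaction_id!r}")
        if ov.which not in ("lower", "upper"):
            raise ModelValidationError(f"override 'which' must be lower|upper, got {ov.which!r}")
        i = index[ov.reaction_id]
        rxn = reactions[i]
        if ov.which == "lower":
            rxn = replace(rxn, lower_bound=float(ov.value))
        else:
            rxn = replace(rxn, upper_bound=float(ov.value))
        if rxn.lower_bound > rxn.upper_bound:
            raise ModelValidationError(
                f"override on {ov.reaction_id!r} makes lower bound "
                f"{rxn.lower_bound} exceed upper bound {rxn.upper_bound}"
            )
        reactions[i] = rxn
    return dataclasses.replace(model, reactions=reactions)


def read_bound_overrides(path) -> list[BoundOverride]:
    """Read a 3-column TSV: reaction_id, which (lower|upper), value."""
    overrides = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ModelFormatError(f"{path}:{lineno}: expected 3 tab-separated columns")
            rid, which, value = parts
            overrides.append(BoundOverride(rid, which, _parse_bound(value, f"{path}:{lineno}")))
    return overrides


# ---- JSON dialect ------------------------------------------------------


def _parse_bound(raw, where: str) -> float:
    if isinstance(raw, str):
        s = raw.strip().lower()
        if s in ("inf", "+inf", "infinity"):
            return INF
        if s in ("-inf", "-infinity"):
            return -INF
        try:
            return float(raw)
        except ValueError:
            raise ModelFormatError(f"{where}: unparseable bound {raw!r}") from None
    return float(raw)


def _bound_to_json(value: float):
    if value == INF:
        return "inf"
    if value == -INF:
        return "-inf"
    return value


def model_from_dict(doc: Mapping) -> MetabolicModel:
    try:
        raw_mets = doc["metabolites"]
        raw_rxns = doc["reactions"]
        biomass = doc["biomass"]
    except KeyError as exc:
        raise ModelFormatError(f"missing required key {exc.args[0]!r}") from None
    mets = []
    for m in raw_mets:
        if "id" not in m:
            raise ModelFormatError("metabolite without an 'id'")
        mets.append(Metabolite(m["id"], m.get("name", ""), m.get("compartment", "")))
    rxns = []
    for r in raw_rxns:
        for key in ("id", "stoich", "lb", "ub"):
            if key not in r:
                raise ModelFormatError(
                    f"reaction {r.get('id', '?')!r} missing required key {key!r}"
                )
        rxns.append(
            Reaction(
                id=r["id"],
                stoichiometry={k: float(v) for k, v in r["stoich"].items()},
                lower_bound=_parse_bound(r["lb"], f"reaction {r['id']!r}"),
                upper_bound=_parse_bound(r["ub"], f"reaction {r['id']!r}"),
                name=r.get("name", ""),
            )
        )
    try:
        return MetabolicModel(
            metabolites=mets,
            reactions=rxns,
            biomass_id=biomass,
            target_ids=tuple(doc.get("targets", ())),
            essential_ids=frozenset(doc.get("essential", ())),
        )
    except ModelValidationError:
        raise


def model_to_dict(model: MetabolicModel) -> dict:
    return {
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "stoich": {k: r.stoichiometry[k] for k in sorted(r.stoichiometry)},
                "lb": _bound_to_json(r.lower_bound),
                "ub": _bound_to_json(r.upper_bound),
            }
            for r in model.reactions
        ],
        "biomass": model.biomass_id,
        "targets": list(model.target_ids),
        "essential": sorted(model.essential_ids),
    }


def save_model(model: MetabolicModel, path) -> None:
    """Write the JSON dialect; canonical key order, deterministic bytes."""
    with open(path, "w") as fh:
        json.dump(model_to_dict(model), fh, indent=1, sort_keys=False)
        fh.write("\n")


def _load_sbml(
    path,
    biomass_id: str | None,
    target_ids: Sequence[str],
    essential_ids: Iterable[str],
) -> MetabolicModel:
    # cobrapy handles SBML L3 + FBC v2, including bound parameters and the
    # declared objective; we convert into our own container and keep file order.
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover
        raise ModelFormatError("SBML support requires cobrapy") from exc
    try:
        cmodel = cobra.io.read_sbml_model(str(path))
    except Exception as exc:
        raise ModelFormatError(f"SBML parse failure for {path}: {exc}") from exc
    mets = [
        Metabolite(m.id, m.name or "", m.compartment or "") for m in cmodel.metabolites
    ]
    rxns = []
    for r in cmodel.reactions:
        if r.lower_bound is None or r.upper_bound is None:  # pragma: no cover
            raise ModelFormatError(f"reaction {r.id!r} has missing bounds")
        rxns.append(
            Reaction(
                id=r.id,
                stoichiometry={m.id: float(c) for m, c in r.metabolites.items()},
                lower_bound=float(r.lower_bound),
                upper_bound=float(r.upper_bound),
                name=r.name or "",
            )
        )
    if biomass_id is None:
        obj_rxns = [r.id for r in cmodel.reactions if r.objective_coefficient]
        if len(obj_rxns) != 1:
            raise ModelFormatError(
                "cannot infer a unique biomass reaction from the SBML objective; "
                "pass biomass_id explicitly"
            )
        biomass_id = obj_rxns[0]
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        biomass_id=biomass_id,
        target_ids=tuple(target_ids),
        essential_ids=frozenset(essential_ids),
    )


def load_model(
    path,
    dialect: str = "json",
    biomass_id: str | None = None,
    target_ids: Sequence[str] = (),
    essential_ids: Iterable[str] = (),
) -> MetabolicModel:
    """Load a model from disk.

    Parameters
    ----------
    path:
        File path.
    dialect:
        ``"json"`` (this package's dialect) or ``"sbml"`` (L3 + FBC v2,
        read-only). For SBML, ``biomass_id`` defaults to the model's declared
        FBC objective when it is a single reaction.
    biomass_id, target_ids, essential_ids:
        Optional overrides; for the JSON dialect they replace the values
        stored in the file when given.
    """
    if dialect == "json":
        try:
            with open(path) as fh:
                doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ModelFormatError(f"invalid JSON in {path}: {exc}") from exc
        model = model_from_dict(doc)
        if biomass_id or target_ids or essential_ids:
            model = dataclasses.replace(
                model,
                biomass_id=biomass_id or model.biomass_id,
                target_ids=tuple(target_ids) or model.target_ids,
                essential_ids=frozenset(essential_ids) or model.essential_ids,
            )
        return model
    if dialect == "sbml":
        return _load_sbml(path, biomass_id, target_ids, essential_ids)
    raise ValueError(f"unknown dialect {dialect!r} (expected 'json' or 'sbml')")
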