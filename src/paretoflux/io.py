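"""Tab-separated and JSON writers for fluxes, fronts and enumerations.

All writers sort canonically so identical runs produce identical bytes.
"""

from __future__ import annotations

import json

import pandas as pd

from .enumeration import EnumerationResult
from .lp import FluxVector
from .pareto import ParetoFront

__all__ = [
    "write_flux_tsv",
    "write_simple_optknock_tsv",
    "write_front_tsv",
    "write_front_json",
    "write_enumeration_tsv",
]


def _fmt(x: float) -> str:
    return f"{x:.9g}"


def write_flux_tsv(flux: FluxVector, path) -> None:
    """Two columns: reaction_id, flux (model order)."""
    with open(path, "w") as fh:
        fh.write("reaction_id\tflux\n")
        for rid, v in flux.values.items():
            fh.write(f"{rid}\t{_fmt(v)}\n")


def write_simple_optknock_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.9g")


def write_front_tsv(front: ParetoFront, path, objective_names=("target", "biomass")) -> None:
    """One row per Pareto point: objectives, K, witness knockouts ;-joined."""
    with open(path, "w") as fh:
        cols = list(objective_names) + ["K", "witness_knockouts"]
        fh.write("\t".join(cols) + "\n")
        for p in front.points:
            row = [_fmt(v) for v in p.objectives]
            row.append(str(p.witness_knockouts.size))
            row.append(";".join(p.witness_knockouts.sorted_members()) or "-")
            fh.write("\t".join(row) + "\n")


def write_front_json(front: ParetoFront, path) -> None:
    doc = {
        "status": front.status,
        "problem_spec": front.problem_spec,
        "points": [
            {
                "objectives": list(p.objectives),
                "witness_knockouts": list(p.witness_knockouts.sorted_members()),
                "witness_flux": p.witness_flux.values,
            }
            for p in front.points
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_enumeration_tsv(results: list[EnumerationResult], path) -> None:
    """One row per (point, set): label, index, members, f_star-or-NA, exhausted."""
    with open(path, "w") as fh:
        fh.write("point\tset_index\tknockouts\tf_star\texhausted\n")
        for res in results:
            label = "(" + ",".join(_fmt(v) for v in res.point.objectives) + ")"
            fstar = _fmt(res.f_star) if res.f_star is not None else "NA"
            if not res.knockout_sets:
                fh.write(f"{label}\t-\t-\t{fstar}\t{str(res.exhausted).lower()}\n")
                continue
            for i, ks in enumerate(res.knockout_sets):
                members = ";".join(ks.sorted_members()) or "-"
                fh.write(
                    f"{label}\t{i}\t{members}\t{fstar}\t{str(res.exhausted).lower()}\n"
                )
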