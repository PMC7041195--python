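"""Single-objective LP machinery: FBA, knockout simulation, classification.

All LPs are solved with the HiGHS backend of :func:`scipy.optimize.linprog`.
The flux balance problem is

    max/min  v_obj
    s.t.     S v = 0
             LB_j <= v_j <= UB_j,

with knockouts simulated by pinning both bounds of the deleted reactions to
zero. ``simple_optknock`` is the classical single-deletion screen: for every
reaction, knock it out, maximize biomass, fix biomass at that optimum and
report the attainable range of the target flux.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = [
    "SolverConfig",
    "FluxVector",
    "InfeasibleProblem",
    "UnboundedProblem",
    "solve_fba",
    "simulate_knockout",
    "knockout_candidates",
    "classify_essential",
    "simple_optknock",
]


class InfeasibleProblem(RuntimeError):
    """The LP/MILP admits no feasible flux distribution."""


class UnboundedProblem(RuntimeError):
    """The objective is unbounded (typically before bound capping)."""


@dataclass(frozen=True)
class SolverConfig:
    """Numerical knobs shared by every solve in the package.

    feasibility_tol     mass-balance/bound violation accepted when checking
                        returned fluxes
    integrality_tol     threshold above which a binary y is read as 1
    zero_flux_tol       |v| below this counts as zero (candidate detection)
    objective_match_tol slack used when an objective value is fixed as a
                        constraint (Pareto-point pinning, MOMA f* pinning)
    random_seed         recorded for provenance; HiGHS itself is deterministic
    time_limit_s        per-solve wall-clock cap (None = unlimited)
    """

    feasibility_tol: float = 1e-6
    integrality_tol: float = 1e-6
    zero_flux_tol: float = 1e-6
    objective_match_tol: float = 1e-6
    random_seed: int = 0
    time_limit_s: float | None = None

    def __post_init__(self) -> None:
        for name in ("feasibility_tol", "integrality_tol", "zero_flux_tol", "objective_match_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_CONFIG = SolverConfig()


@dataclass
class FluxVector:
    """A steady-state flux assignment plus the objective it optimized."""

    values: dict[str, float]
    objective_value: float

    def __getitem__(self, rid: str) -> float:
        return self.values[rid]

    def as_array(self, model: MetabolicModel) -> np.ndarray:
        return np.array([self.values[r.id] for r in model.reactions], dtype=float)


def _linprog_options(config: SolverConfig) -> dict:
    opts: dict = {"presolve": True}
    if config.time_limit_s is not None:
        opts["time_limit"] = config.time_limit_s
    return opts


def _solve_lp_raw(
    model: MetabolicModel,
    c: np.ndarray,
    lb: np.ndarray,
    ub: np.ndarray,
    config: SolverConfig,
):
    res = linprog(
        c,
        A_eq=model.stoichiometric_matrix(),
        b_eq=np.zeros(model.n_metabolites),
        bounds=np.column_stack([lb, ub]),
        method="highs",
        options=_linprog_options(config),
    )
    if res.status == 2:
        raise InfeasibleProblem("flux balance LP is infeasible")
    if res.status == 3:
        raise UnboundedProblem(
            "objective is unbounded; cap infinite bounds before solving"
        )
    if res.status != 0:  # pragma: no cover - solver internal failures
        raise RuntimeError(f"LP solver failed: {res.message}")
    return res


def solve_fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    sense: str = "max",
    config: SolverConfig = DEFAULT_CONFIG,
    _fixed_bounds: Mapping[str, tuple[float, float]] | None = None,
) -> FluxVector:
    """Solve the flux balance LP for one objective reaction.

    Raises :class:`InfeasibleProblem` / :class:`UnboundedProblem` with the
    corresponding solver status; never returns a silent default.
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    objective_id = objective_id or model.biomass_id
    j = model.reaction_index(objective_id)
    lb, ub = model.bounds_arrays()
    if _fixed_bounds:
        ridx = {r.id: i for i, r in enumerate(model.reactions)}
        for rid, (lo, hi) in _fixed_bounds.items():
            lb[ridx[rid]] = lo
            ub[ridx[rid]] = hi
    c = np.zeros(model.n_reactions)
    c[j] = -1.0 if sense == "max" else 1.0
    res = _solve_lp_raw(model, c, lb, ub, config)
    values = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    return FluxVector(values=values, objective_value=float(res.x[j]))


def simulate_knockout(
    model: MetabolicModel,
    knockouts: Iterable[str],
    objective_id: str | None = None,
    sense: str = "max",
    config: SolverConfig = DEFAULT_CONFIG,
) -> FluxVector:
    """FBA with both bounds of every knocked-out reaction fixed to zero."""
    knockouts = set(knockouts)
    unknown = knockouts - set(model.reaction_ids)
    if unknown:
        raise KeyError(f"unknown knockout reaction ids: {sorted(unknown)}")
    fixed = {rid: (0.0, 0.0) for rid in knockouts}
    return solve_fba(model, objective_id, sense, config, _fixed_bounds=fixed)


def knockout_candidates(
    model: MetabolicModel,
    reference: FluxVector,
    config: SolverConfig = DEFAULT_CONFIG,
) -> set[str]:
    """Reactions carrying flux in the reference, minus the essential set.

    This is the J_I used by the knockout MILPs when the pipeline restricts
    candidates to reactions active in the wild type.
    """
    return {
        rid
        for rid, v in reference.values.items()
        if abs(v) > config.zero_flux_tol and rid not in model.essential_ids
    }


def classify_essential(
    model: MetabolicModel,
    biomass_floor: float | None = None,
    config: SolverConfig = DEFAULT_CONFIG,
) -> set[str]:
    """Single-knockout essentiality screen (convenience helper).

    A reaction is called essential when deleting it drops the biomass
    optimum strictly below ``biomass_floor`` (default: 1e-3 × the wild-type
    optimum). An explicit user-supplied essential set always takes
    precedence over this helper downstream.
    """
    if biomass_floor is None:
        wt = solve_fba(model, config=config)
        biomass_floor = 1e-3 * wt.objective_value
    if biomass_floor < 0:
        raise ValueError("biomass_floor must be nonnegative")
    essential = set()
    for rxn in model.reactions:
        try:
            mut = simulate_knockout(model, {rxn.id}, config=config)
            if mut.objective_value < biomass_floor:
                essential.add(rxn.id)
        except InfeasibleProblem:
            essential.add(rxn.id)
    return essential


def simple_optknock(
    model: MetabolicModel,
    target_id: str | None = None,
    config: SolverConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Single-deletion screen: per reaction, max biomass then target range.

    For every reaction j: knock out j, maximize biomass, pin biomass at that
    optimum (within ``objective_match_tol``) and report the maximum and
    minimum target flux. Infeasible sub-LPs are flagged, the run continues.

    Returns a DataFrame with columns
    ``reaction_id, biomass_max, target_max, target_min, status``.
    """
    target_id = target_id or (model.target_ids[0] if model.target_ids else None)
    if target_id is None:
        raise ValueError("no target reaction given and the model declares none")
    tol = config.objective_match_tol
    records = []
    for rxn in model.reactions:
        ko = {rxn.id: (0.0, 0.0)}
        try:
            bio = solve_fba(model, model.biomass_id, "max", config, _fixed_bounds=ko)
            pinned = dict(ko)
            pinned[model.biomass_id] = (
                bio.objective_value - tol,
                bio.objective_value + tol,
            )
            tmax = solve_fba(model, target_id, "max", config, _fixed_bounds=pinned)
            tmin = solve_fba(model, target_id, "min", config, _fixed_bounds=pinned)
            records.append(
                (rxn.id, bio.objective_value, tmax.objective_value, tmin.objective_value, "ok")
            )
        except InfeasibleProblem:
            records.append((rxn.id, np.nan, np.nan, np.nan, "infeasible"))
    return pd.DataFrame.from_records(
        records, columns=["reaction_id", "biomass_max", "target_max", "target_min", "status"]
    )
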