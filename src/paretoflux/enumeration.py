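"""Exhaustive enumeration of equivalent knockout sets per Pareto point.

Given a frontier point (v*_prod, v*_biomass), the feasibility program pins
both objective fluxes at their point values (within a small two-sided
tolerance) under the knockout constraints. Each solution's deletion set
ȳ is then excluded — together with every superset — by the no-good cut

    sum_{j in supp(ȳ)} y_j <= K - 1,

and the program is re-solved until the solver returns an infeasibility
certificate (no further equivalent set exists) or a budget is reached.

In MOMA mode the program first minimizes the Manhattan distance
f(v) = sum_i |v_i - v̄̄_i| to a reference flux (the wild-type FBA solution
by default), linearized via z_i >= ±(v_i - v̄̄_i); the optimum f* is then
pinned (f(v) <= f* + tol) so that only distance-minimal deletion sets are
enumerated — a subset of the full equivalent-set list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from ._milp import KnockoutMilp
from .lp import DEFAULT_CONFIG, FluxVector, InfeasibleProblem, SolverConfig, solve_fba
from .model import MetabolicModel
from .pareto import KnockoutSet, ParetoPoint

__all__ = [
    "LinearCut",
    "EnumerationResult",
    "no_good_cut",
    "enumerate_equivalent",
    "moma_distance_lp",
    "enumerate_moma",
]

logger = logging.getLogger(__name__)

MAX_SETS_DEFAULT = 1000


@dataclass(frozen=True)
class LinearCut:
    """sum_j coeffs[j] * y_j <= rhs"""

    coeffs: dict[str, float]
    rhs: float

    def __post_init__(self):
        object.__setattr__(self, "coeffs", dict(self.coeffs))


@dataclass
class EnumerationResult:
    point: ParetoPoint
    knockout_sets: list[KnockoutSet]
    mode: str  # "all" | "moma"
    f_star: float | None = None
    exhausted: bool = False
    status: str = "ok"  # "ok" | "inconsistent-point"
    distances: dict[frozenset, float] | None = None

    def sorted_sets(self) -> list[tuple[str, ...]]:
        return sorted(ks.sorted_members() for ks in self.knockout_sets)


def no_good_cut(found: KnockoutSet | frozenset | set) -> LinearCut:
    """Cut excluding ``found`` and every superset from further enumeration."""
    members = found.members if isinstance(found, KnockoutSet) else frozenset(found)
    if not members:
        raise ValueError(
            "cannot cut the empty knockout set (K=0): it is the unique "
            "solution and enumeration ends after reporting it"
        )
    return LinearCut(coeffs={rid: 1.0 for rid in sorted(members)}, rhs=len(members) - 1.0)


def _build_pinned(
    model: MetabolicModel,
    point: ParetoPoint,
    K: int,
    config: SolverConfig,
    candidates: list[str] | None,
    objective_ids: list[str] | None,
    cardinality_equality: bool,
) -> tuple[KnockoutMilp, list[str]]:
    if candidates is None:
        candidates = model.inessential_ids()
    if objective_ids is None:
        if not model.target_ids:
            raise ValueError("model declares no target reaction; pass objective_ids")
        objective_ids = [model.target_ids[0], model.biomass_id]
    if len(objective_ids) != len(point.objectives):
        raise ValueError("objective arity mismatch between point and objective_ids")
    prob = KnockoutMilp(
        model, list(candidates), K, config, cardinality_equality=cardinality_equality
    )
    for rid, value in zip(objective_ids, point.objectives):
        prob.fix_flux(rid, value)
    return prob, list(objective_ids)


def _enumeration_loop(prob, objective, config, max_sets):
    """Shared solve / cut / repeat loop; returns (sets, per-set values, exhausted)."""
    sets: list[frozenset] = []
    obj_values: dict[frozenset, float] = {}
    exhausted = False
    while len(sets) < max_sets:
        try:
            values, kos, obj_val = prob.solve(objective)
        except InfeasibleProblem:
            exhausted = True
            break
        sets.append(kos)
        obj_values[kos] = obj_val
        if not kos:
            # K=0: the empty set is the unique solution; a no-good cut would
            # be 0 <= -1, so enumeration terminates here by construction.
            exhausted = True
            break
        cut = no_good_cut(kos)
        prob.add_no_good_cut(cut.coeffs.keys())
    return sets, obj_values, exhausted


def enumerate_equivalent(
    model: MetabolicModel,
    point: ParetoPoint,
    K: int,
    config: SolverConfig = DEFAULT_CONFIG,
    max_sets: int = MAX_SETS_DEFAULT,
    candidates: list[str] | None = None,
    objective_ids: list[str] | None = None,
    cardinality_equality: bool = True,
) -> EnumerationResult:
    """All K-deletion sets attaining the point's objective values (ENUMP).

    ``exhausted`` is True only when the final solve proved infeasibility,
    i.e. the list is certified complete. Sets are reported in canonical
    (lexicographic) order regardless of solver discovery order.
    """
    prob, _ = _build_pinned(
        model, point, K, config, candidates, objective_ids, cardinality_equality
    )
    sets, _, exhausted = _enumeration_loop(prob, {model.biomass_id: 0.0}, config, max_sets)
    status = "ok"
    if not sets and exhausted and max_sets > 0:
        status = "inconsistent-point"
    if len(sets) >= max_sets and not exhausted:
        logger.warning(
            "enumeration stopped at max_sets=%d without an exhaustion certificate",
            max_sets,
        )
    result = EnumerationResult(
        point=point,
        knockout_sets=sorted(
            (KnockoutSet(s) for s in sets), key=lambda k: k.sorted_members()
        ),
        mode="all",
        exhausted=exhausted,
        status=status,
    )
    return result


def moma_distance_lp(
    model: MetabolicModel,
    point: ParetoPoint,
    K: int,
    reference: FluxVector | None = None,
    config: SolverConfig = DEFAULT_CONFIG,
    candidates: list[str] | None = None,
    objective_ids: list[str] | None = None,
    cardinality_equality: bool = True,
) -> tuple[float, KnockoutSet]:
    """Minimal L1 distance to the reference flux at a pinned Pareto point.

    Solves ENUMPM once: min f(v) = sum_i |v_i - v̄̄_i| subject to the pinned
    objectives and knockout constraints. The reference defaults to the
    biomass-optimal FBA flux (the wild-type proxy).
    """
    if reference is None:
        reference = solve_fba(model, config=config)
    missing = set(model.reaction_ids) - set(reference.values)
    if missing:
        raise ValueError(f"reference flux misses reactions: {sorted(missing)[:5]}")
    prob, _ = _build_pinned(
        model, point, K, config, candidates, objective_ids, cardinality_equality
    )
    prob.enable_moma(reference.values)
    _, kos, f_star = prob.solve("moma")
    return f_star, KnockoutSet(kos)


def enumerate_moma(
    model: MetabolicModel,
    point: ParetoPoint,
    K: int,
    reference: FluxVector | None = None,
    config: SolverConfig = DEFAULT_CONFIG,
    max_sets: int = MAX_SETS_DEFAULT,
    candidates: list[str] | None = None,
    objective_ids: list[str] | None = None,
    cardinality_equality: bool = True,
) -> EnumerationResult:
    """Distance-minimal equivalent deletion sets (ENUMPM enumeration).

    After the first solve proves the optimal adjustment f*, the constraint
    f(v) <= f* + tol pins the distance and the no-good-cut loop enumerates
    exactly those deletion sets admitting a flux at minimal distance — a
    subset of :func:`enumerate_equivalent`'s output.
    """
    if reference is None:
        reference = solve_fba(model, config=config)
    prob, _ = _build_pinned(
        model, point, K, config, candidates, objective_ids, cardinality_equality
    )
    prob.enable_moma(reference.values)
    try:
        _, first_set, f_star = prob.solve("moma")
    except InfeasibleProblem:
        return EnumerationResult(
            point=point, knockout_sets=[], mode="moma",
            exhausted=True, status="inconsistent-point",
        )
    prob.add_moma_cap(f_star)
    sets, dists, exhausted = _enumeration_loop(prob, "moma", config, max_sets)
    if max_sets > 0 and first_set not in sets and len(sets) < max_sets:
        # first solve already found a set; loop re-finds it, but guard anyway
        sets.append(first_set)
        dists[first_set] = f_star
    return EnumerationResult(
        point=point,
        knockout_sets=sorted(
            (KnockoutSet(s) for s in sets), key=lambda k: k.sorted_members()
        ),
        mode="moma",
        f_star=f_star,
        exhausted=exhausted,
        status="ok" if sets or max_sets == 0 else "inconsistent-point",
        distances={s: dists[s] for s in sets},
    )
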