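"""Bi-objective knockout optimization: Pareto fronts of competing fluxes.

The bi-objective knockout program maximizes a tuple of fluxes — by default
(v_product, v_biomass) — over steady-state flux distributions in which
exactly K candidate reactions are deleted. The nondominated frontier is
computed exactly by a dichotomic weighted-sum search (Aneja–Nair style):
solve the two lexicographic anchor problems, then recursively probe the
weight vector normal to each adjacent pair of points until no point above
the connecting chord remains. This yields every *extreme supported*
nondominated point. Nondominated points that are unsupported, or supported
but collinear with their neighbours, are reachable through the optional
ε-constraint sweep (:func:`epsilon_constraint_front`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from ._milp import KnockoutMilp
from .lp import DEFAULT_CONFIG, FluxVector, InfeasibleProblem, SolverConfig
from .model import MetabolicModel

__all__ = [
    "KnockoutSet",
    "ParetoPoint",
    "ParetoFront",
    "dominance_filter",
    "weighted_sum_solve",
    "solve_bop",
    "epsilon_constraint_front",
]

logger = logging.getLogger(__name__)

#: dichotomic recursion stops when a probe improves the chord by <= this
CHORD_IMPROVEMENT_TOL = 1e-6


@dataclass(frozen=True)
class KnockoutSet:
    """A set of deleted reactions (support of the binary vector y)."""

    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))

    def __iter__(self):
        return iter(sorted(self.members))


@dataclass
class ParetoPoint:
    """One nondominated objective tuple with a witness solution."""

    objectives: tuple[float, ...]
    witness_flux: FluxVector
    witness_knockouts: KnockoutSet


@dataclass
class ParetoFront:
    """Nondominated points sorted by the first objective, descending."""

    points: list[ParetoPoint]
    problem_spec: dict
    status: str = "ok"

    def objective_tuples(self) -> list[tuple[float, ...]]:
        return [p.objectives for p in self.points]

    def __len__(self) -> int:
        return len(self.points)


def dominance_filter(points, tol: float = 1e-6) -> list[tuple[float, ...]]:
    """Maximal (nondominated) subset of objective tuples, maximization sense.

    ``p`` dominates ``q`` when p >= q - tol componentwise and p > q + tol in
    at least one component. Duplicates within tol are collapsed. The result
    is sorted by the first objective, descending (stable).
    """
    pts = [tuple(float(x) for x in p) for p in points]
    if pts and any(len(p) != len(pts[0]) for p in pts):
        raise ValueError("objective tuples must share the same arity")
    kept: list[tuple[float, ...]] = []
    for p in pts:
        if any(all(abs(a - b) <= tol for a, b in zip(p, k)) for k in kept):
            continue  # duplicate
        dominated = False
        for k in kept:
            if all(a >= b - tol for a, b in zip(k, p)) and any(
                a > b + tol for a, b in zip(k, p)
            ):
                dominated = True
                break
        if dominated:
            continue
        kept = [
            k
            for k in kept
            if not (
                all(a >= b - tol for a, b in zip(p, k))
                and any(a > b + tol for a, b in zip(p, k))
            )
        ]
        kept.append(p)
    return sorted(kept, key=lambda t: tuple(-x for x in t))


def _resolve_setup(model, config, candidates, objective_ids):
    config = config or DEFAULT_CONFIG
    if candidates is None:
        candidates = model.inessential_ids()
    else:
        order = {rid: i for i, rid in enumerate(model.reaction_ids)}
        candidates = sorted(candidates, key=order.__getitem__)
    if objective_ids is None:
        if not model.target_ids:
            raise ValueError("model declares no target reaction; pass objective_ids")
        objective_ids = [model.target_ids[0], model.biomass_id]
    return config, list(candidates), list(objective_ids)


def weighted_sum_solve(
    model: MetabolicModel,
    K: int,
    weights: tuple[float, ...],
    range_limits: dict[str, tuple[float, float]] | None = None,
    config: SolverConfig | None = None,
    candidates: list[str] | None = None,
    objective_ids: list[str] | None = None,
    cardinality_equality: bool = True,
) -> ParetoPoint:
    """Optimize one nonnegative weighting of the objectives.

    Ties among equally-scored optima are broken by lexicographic
    re-optimization in the listed objective order, so the reported point is
    deterministic regardless of which optimum the solver visits first.
    """
    config, candidates, objective_ids = _resolve_setup(
        model, config, candidates, objective_ids
    )
    if len(weights) != len(objective_ids):
        raise ValueError("one weight per objective required")
    if all(w == 0 for w in weights) or any(w < 0 for w in weights):
        raise ValueError("weights must be nonnegative and not all zero")
    prob = KnockoutMilp(
        model, candidates, K, config,
        cardinality_equality=cardinality_equality, range_limits=range_limits,
    )
    values, kos, objectives = prob.solve_lexicographic(objective_ids, weights)
    flux = FluxVector(values=values, objective_value=objectives[0])
    return ParetoPoint(
        objectives=objectives,
        witness_flux=flux,
        witness_knockouts=KnockoutSet(frozenset(kos)),
    )


def solve_bop(
    model: MetabolicModel,
    K: int,
    range_limits: dict[str, tuple[float, float]] | None = None,
    config: SolverConfig | None = None,
    candidates: list[str] | None = None,
    objective_ids: list[str] | None = None,
    cardinality_equality: bool = True,
) -> ParetoFront:
    """Exact frontier of the bi-objective knockout program.

    Dichotomic weighted-sum search over two objectives; returns all extreme
    supported nondominated points, first objective descending. An infeasible
    anchor yields an empty front with ``status='infeasible'``.
    """
    config, candidates, objective_ids = _resolve_setup(
        model, config, candidates, objective_ids
    )
    if len(objective_ids) != 2:
        raise ValueError(
            "solve_bop handles exactly two objectives; use weighted_sum_solve "
            "over a simplex grid for more"
        )
    spec = {
        "model_digest": model.digest(),
        "K": K,
        "objective_ids": list(objective_ids),
        "range_limits": {k: list(v) for k, v in (range_limits or {}).items()},
        "cardinality": "eq" if cardinality_equality else "le",
    }

    def make_prob():
        return KnockoutMilp(
            model, candidates, K, config,
            cardinality_equality=cardinality_equality, range_limits=range_limits,
        )

    def lex_point(weights) -> ParetoPoint:
        values, kos, objectives = make_prob().solve_lexicographic(objective_ids, weights)
        return ParetoPoint(
            objectives=objectives,
            witness_flux=FluxVector(values=values, objective_value=objectives[0]),
            witness_knockouts=KnockoutSet(frozenset(kos)),
        )

    try:
        anchor1 = lex_point((1.0, 0.0))
        anchor2 = lex_point((0.0, 1.0))
    except InfeasibleProblem as exc:
        logger.warning("anchor problem infeasible: %s", exc)
        return ParetoFront(points=[], problem_spec=spec, status="infeasible")

    points: dict[tuple[float, float], ParetoPoint] = {}

    def keyed(p: ParetoPoint) -> tuple[float, float]:
        return (round(p.objectives[0], 9), round(p.objectives[1], 9))

    points[keyed(anchor1)] = anchor1
    points[keyed(anchor2)] = anchor2

    def recurse(a: ParetoPoint, b: ParetoPoint) -> None:
        # a has the larger first objective. Probe the chord normal.
        (a1, a2), (b1, b2) = a.objectives, b.objectives
        w1, w2 = b2 - a2, a1 - b1
        if w1 <= CHORD_IMPROVEMENT_TOL or w2 <= CHORD_IMPROVEMENT_TOL:
            return
        c = lex_point((w1, w2))
        score = w1 * c.objectives[0] + w2 * c.objectives[1]
        chord = w1 * a1 + w2 * a2
        if score <= chord + CHORD_IMPROVEMENT_TOL * (1.0 + abs(chord)):
            return
        if keyed(c) in points:
            return
        points[keyed(c)] = c
        recurse(a, c)
        recurse(c, b)

    recurse(anchor1, anchor2)

    nondom = dominance_filter(
        [p.objectives for p in points.values()], tol=config.objective_match_tol
    )
    nondom_set = {tuple(round(x, 9) for x in t) for t in nondom}
    front = [p for k, p in points.items() if k in nondom_set]
    front.sort(key=lambda p: (-p.objectives[0], -p.objectives[1]))
    logger.info("frontier: %d extreme supported points (K=%d)", len(front), K)
    return ParetoFront(points=front, problem_spec=spec)


def epsilon_constraint_front(
    model: MetabolicModel,
    K: int,
    grid_step: float,
    range_limits: dict[str, tuple[float, float]] | None = None,
    config: SolverConfig | None = None,
    candidates: list[str] | None = None,
    objective_ids: list[str] | None = None,
    cardinality_equality: bool = True,
) -> ParetoFront:
    """ε-constraint sweep: fix the first objective at a grid of floors and
    maximize the second lexicographically. Finds unsupported nondominated
    points that the weighted-sum search cannot; resolution is ``grid_step``.
    """
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    config, candidates, objective_ids = _resolve_setup(
        model, config, candidates, objective_ids
    )
    if len(objective_ids) != 2:
        raise ValueError("ε-constraint sweep handles exactly two objectives")
    base = solve_bop(
        model, K, range_limits, config, candidates, objective_ids, cardinality_equality
    )
    if base.status != "ok" or not base.points:
        return base
    o1_values = [p.objectives[0] for p in base.points]
    lo, hi = min(o1_values), max(o1_values)
    points = list(base.points)
    eps = lo + grid_step
    obj1 = objective_ids[0]
    while eps < hi - 1e-12:
        limits = dict(range_limits or {})
        cur = limits.get(obj1, (None, None))
        limits[obj1] = (eps if cur[0] is None else max(cur[0], eps), cur[1])
        try:
            prob = KnockoutMilp(
                model, candidates, K, config,
                cardinality_equality=cardinality_equality, range_limits=limits,
            )
            values, kos, objectives = prob.solve_lexicographic(
                [objective_ids[1], objective_ids[0]], (1.0, 0.0)
            )
            objectives = (objectives[1], objectives[0])
            points.append(
                ParetoPoint(
                    objectives=objectives,
                    witness_flux=FluxVector(values=values, objective_value=objectives[0]),
                    witness_knockouts=KnockoutSet(frozenset(kos)),
                )
            )
        except InfeasibleProblem:
            pass
        eps += grid_step
    nondom = {
        tuple(round(x, 9) for x in t)
        for t in dominance_filter([p.objectives for p in points], config.objective_match_tol)
    }
    uniq: dict[tuple, ParetoPoint] = {}
    for p in points:
        k = tuple(round(x, 9) for x in p.objectives)
        if k in nondom and k not in uniq:
            uniq[k] = p
    front = sorted(uniq.values(), key=lambda p: (-p.objectives[0], -p.objectives[1]))
    spec = dict(base.problem_spec)
    spec["epsilon_grid_step"] = grid_step
    return ParetoFront(points=front, problem_spec=spec)
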