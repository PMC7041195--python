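"""Deterministic toy networks and brute-force oracles.

The generator builds branched uptake networks — one carbon uptake feeding a
hub metabolite that drains through parallel branches (the first is biomass,
the second the product, any extras by-products). Their Pareto fronts have
closed forms (capacities and the uptake bound are the only data), which
makes every MILP code path checkable against an independent oracle built
purely from single-objective LPs.

``toy_b`` is the 6-reaction, 3-metabolite worked example used throughout
the tests: uptake 10 into hub A, one biomass branch (R1: A→B, drained by
EX_bio) and a *duplicated* product branch (R2 and R2b: A→C, drained by
EX_prod). The duplication creates genuinely equivalent single deletions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog

from .lp import DEFAULT_CONFIG, FluxVector, SolverConfig
from .model import MetabolicModel, Metabolite, Reaction

__all__ = [
    "ToySpec",
    "make_branched_network",
    "toy_b",
    "random_branched_network",
    "brute_force_front",
    "brute_force_enumerate",
    "minimal_distance_sets",
]

BRUTE_FORCE_BUDGET = 10_000
SINK_BOUND = 1000.0


@dataclass(frozen=True)
class ToySpec:
    n_branches: int
    branch_capacities: tuple[float, ...]
    uptake_bound: float
    seed: int = 0
    duplicate_product: bool = False

    def __post_init__(self):
        if self.n_branches < 2:
            raise ValueError("need at least two branches (biomass + product)")
        if len(self.branch_capacities) != self.n_branches:
            raise ValueError("one capacity per branch required")
        if any(c <= 0 for c in self.branch_capacities):
            raise ValueError("capacities must be positive")
        if self.uptake_bound <= 0:
            raise ValueError("uptake bound must be positive")


def make_branched_network(spec: ToySpec) -> MetabolicModel:
    """Uptake → hub → parallel sinks; all reactions irreversible.

    Branch 1 drains to biomass (EX_bio), branch 2 to the product (EX_prod),
    extras to by-product exchanges. Exchange reactions are marked essential
    (never knockable); the internal branch reactions form J_I. With
    ``duplicate_product`` a parallel copy (R2b) of the product branch is
    added, as in the TOY-B worked example.
    """
    mets = [Metabolite("A", "hub", "c")]
    reactions = [Reaction("EX_glc", {"A": 1.0}, 0.0, float(spec.uptake_bound), "uptake")]
    sink_names = []
    for b in range(spec.n_branches):
        mid = chr(ord("B") + b)
        mets.append(Metabolite(mid, f"branch {b + 1} intermediate", "c"))
        cap = float(spec.branch_capacities[b])
        reactions.append(Reaction(f"R{b + 1}", {"A": -1.0, mid: 1.0}, 0.0, cap, ""))
        if b == 0:
            sink = ("EX_bio", "biomass drain")
        elif b == 1:
            sink = ("EX_prod", "product export")
        else:
            sink = (f"EX_by{b + 1}", "by-product export")
        sink_names.append((sink[0], mid))
        if spec.duplicate_product and b == 1:
            reactions.append(Reaction("R2b", {"A": -1.0, mid: 1.0}, 0.0, cap, ""))
    for sink_id, mid in sink_names:
        reactions.append(Reaction(sink_id, {mid: -1.0}, 0.0, SINK_BOUND, ""))
    essential = frozenset(["EX_glc"] + [s for s, _ in sink_names])
    return MetabolicModel(
        metabolites=mets,
        reactions=reactions,
        biomass_id="EX_bio",
        target_ids=("EX_prod",),
        essential_ids=essential,
    )


def toy_b() -> MetabolicModel:
    """The 6-reaction worked example (duplicated product branch, uptake 10)."""
    return make_branched_network(
        ToySpec(
            n_branches=2,
            branch_capacities=(SINK_BOUND, SINK_BOUND),
            uptake_bound=10.0,
            duplicate_product=True,
        )
    )


def random_branched_network(seed: int) -> MetabolicModel:
    """A seeded small branched network for property/oracle tests.

    3–5 branches, integer capacities in [2, 12], integer uptake in [6, 14];
    the product branch is duplicated for half of the seeds so equivalent
    deletion sets occur. Deterministic: same seed, same model bytes.
    """
    rng = np.random.default_rng(seed)
    n_branches = int(rng.integers(3, 6))
    caps = tuple(float(c) for c in rng.integers(2, 13, size=n_branches))
    uptake = float(rng.integers(6, 15))
    dup = bool(rng.integers(0, 2))
    return make_branched_network(
        ToySpec(
            n_branches=n_branches,
            branch_capacities=caps,
            uptake_bound=uptake,
            seed=seed,
            duplicate_product=dup,
        )
    )


# ---- oracle LPs (independent of the MILP path) --------------------------


def _oracle_lp(model, c, fixed_zero, flux_windows, config):
    """max c·v  s.t. Sv=0, bounds, knocked reactions pinned to 0, plus
    per-reaction [lo,hi] windows. Returns None when infeasible."""
    lb, ub = model.bounds_arrays()
    ridx = {r.id: i for i, r in enumerate(model.reactions)}
    for rid in fixed_zero:
        lb[ridx[rid]] = ub[ridx[rid]] = 0.0
    for rid, (lo, hi) in flux_windows.items():
        j = ridx[rid]
        if lo is not None:
            lb[j] = max(lb[j], lo)
        if hi is not None:
            ub[j] = min(ub[j], hi)
    if (lb > ub).any():
        return None
    res = linprog(
        -c,
        A_eq=model.stoichiometric_matrix(),
        b_eq=np.zeros(model.n_metabolites),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status == 2:
        return None
    if res.status != 0:
        raise RuntimeError(f"oracle LP failed: {res.message}")
    return res.x


def _oracle_lex_point(model, obj_idx, weights, fixed_zero, windows, config):
    """Weighted LP refined lexicographically (objective order) — the same
    deterministic tie-break the MILP path uses, built from plain LPs."""
    n = model.n_reactions
    slack = 1e-9
    c = np.zeros(n)
    for j, w in zip(obj_idx, weights):
        c[j] += w
    windows = dict(windows)
    x = _oracle_lp(model, c, fixed_zero, windows, config)
    if x is None:
        return None
    # encode the weighted-score floor as an extra metabolite-free row:
    # emulate by refining objectives one at a time with scalar windows only —
    # the score floor needs a general row, so solve with augmented A_ub.
    score = float(c @ x)
    lb, ub = model.bounds_arrays()
    ridx = {r.id: i for i, r in enumerate(model.reactions)}
    for rid in fixed_zero:
        lb[ridx[rid]] = ub[ridx[rid]] = 0.0
    for rid, (lo, hi) in windows.items():
        j = ridx[rid]
        if lo is not None:
            lb[j] = max(lb[j], lo)
        if hi is not None:
            ub[j] = min(ub[j], hi)
    A_ub = [-c]
    b_ub = [-(score - slack * (1 + abs(score)))]
    point = []
    for j in obj_idx:
        cj = np.zeros(n)
        cj[j] = 1.0
        res = linprog(
            -cj,
            A_eq=model.stoichiometric_matrix(),
            b_eq=np.zeros(model.n_metabolites),
            A_ub=np.array(A_ub),
            b_ub=np.array(b_ub),
            bounds=np.column_stack([lb, ub]),
            method="highs",
        )
        if res.status != 0:
            return None
        val = float(res.x[j])
        point.append(val)
        A_ub.append(-cj)
        b_ub.append(-(val - slack * (1 + abs(val))))
    return tuple(point)


def _upper_hull_vertices(points, tol=1e-6):
    """Vertices of the upper-right convex envelope of a 2-D nondominated,
    first-objective-descending point list.

    Points within ``tol`` (scaled) of the chord between their neighbours are
    dropped as collinear — the same resolution at which the dichotomic
    search stops probing a chord, so both code paths agree on which
    supported points count as extreme."""
    if len(points) <= 2:
        return list(points)
    pts = sorted(points, key=lambda t: (-t[0], -t[1]))
    hull = []
    for p in pts:
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            cross = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
            scale = 1.0 + abs(a[0]) + abs(a[1]) + abs(p[0]) + abs(p[1])
            if cross <= tol * scale:  # b on or below chord a–p: not a vertex
                hull.pop()
            else:
                break
        hull.append(p)
    return hull


def _check_budget(n_candidates: int, K: int) -> None:
    if math.comb(n_candidates, K) > BRUTE_FORCE_BUDGET:
        raise ValueError(
            f"brute force over C({n_candidates},{K}) subsets exceeds the "
            f"{BRUTE_FORCE_BUDGET}-subset budget"
        )


def _dominance(points, tol):
    from .pareto import dominance_filter

    return dominance_filter(points, tol)


def brute_force_front(
    model: MetabolicModel,
    K: int,
    J_I: list[str] | None = None,
    weight_grid_size: int = 101,
    range_limits: dict[str, tuple[float, float]] | None = None,
    objective_ids: list[str] | None = None,
    config: SolverConfig = DEFAULT_CONFIG,
) -> list[tuple[float, float]]:
    """Reference frontier by exhaustive K-subset × weighted-LP search.

    For every K-subset of J_I the knocked LP is scanned over a dense weight
    grid (plus both lexicographic anchors, which are the grid endpoints);
    each weighted optimum is refined lexicographically so ties resolve to
    face corners. The union is dominance-filtered and reduced to the
    vertices of its upper convex envelope — the extreme supported
    nondominated points that the dichotomic search is contracted to return.
    """
    if J_I is None:
        J_I = model.inessential_ids()
    if objective_ids is None:
        objective_ids = [model.target_ids[0], model.biomass_id]
    _check_budget(len(J_I), K)
    ridx = {r.id: i for i, r in enumerate(model.reactions)}
    obj_idx = [ridx[rid] for rid in objective_ids]
    windows = {rid: v for rid, v in (range_limits or {}).items()}
    recorded = []
    grid = np.linspace(0.0, 1.0, max(2, weight_grid_size))
    for subset in itertools.combinations(J_I, K):
        for w in grid:
            pt = _oracle_lex_point(
                model, obj_idx, (w, 1.0 - w), set(subset), windows, config
            )
            if pt is not None:
                recorded.append(pt)
    front = _dominance(recorded, config.objective_match_tol)
    return _upper_hull_vertices(front)


def brute_force_enumerate(
    model: MetabolicModel,
    point,
    K: int,
    J_I: list[str] | None = None,
    reference: FluxVector | None = None,
    objective_ids: list[str] | None = None,
    config: SolverConfig = DEFAULT_CONFIG,
):
    """Reference enumeration by exhaustive K-subset feasibility LPs.

    Tests every K-subset of J_I for a flux attaining the point's objective
    values (within ``objective_match_tol``). When a reference flux is given,
    the per-subset minimal L1 distance is computed with an LP over (v, z).

    Returns ``(sets, distances)``: the feasible subsets as frozensets (sorted
    canonically) and, when a reference was given, a dict subset → minimal
    distance (else None).
    """
    if J_I is None:
        J_I = model.inessential_ids()
    if objective_ids is None:
        objective_ids = [model.target_ids[0], model.biomass_id]
    objectives = point.objectives if hasattr(point, "objectives") else tuple(point)
    _check_budget(len(J_I), K)
    tol = config.objective_match_tol
    windows = {
        rid: (val - tol, val + tol) for rid, val in zip(objective_ids, objectives)
    }
    n = model.n_reactions
    S = model.stoichiometric_matrix()
    ridx = {r.id: i for i, r in enumerate(model.reactions)}
    ref_arr = (
        np.array([reference.values[r.id] for r in model.reactions])
        if reference is not None
        else None
    )
    feasible = []
    distances: dict[frozenset, float] = {}
    for subset in itertools.combinations(sorted(J_I), K):
        x = _oracle_lp(model, np.zeros(n), set(subset), windows, config)
        if x is None:
            continue
        feasible.append(frozenset(subset))
        if ref_arr is not None:
            distances[frozenset(subset)] = _oracle_min_l1(
                model, set(subset), windows, ref_arr
            )
    feasible.sort(key=lambda s: tuple(sorted(s)))
    return feasible, (distances if ref_arr is not None else None)


def minimal_distance_sets(
    distances: dict[frozenset, float], config: SolverConfig = DEFAULT_CONFIG
) -> list[frozenset]:
    """Distance-minimal subsets under the same tie rule the MILP path uses.

    Sets whose minimal L1 distance lies within ``MOMA_TIE_FACTOR ×
    objective_match_tol`` of the global minimum count as tied: pinning the
    objectives in a ±tol window perturbs each set's attainable distance by
    O(tol), so finer separation is not meaningful.
    """
    from ._milp import MOMA_TIE_FACTOR

    if not distances:
        return []
    f_min = min(distances.values())
    tie = MOMA_TIE_FACTOR * config.objective_match_tol
    return sorted(
        (s for s, d in distances.items() if d <= f_min + tie),
        key=lambda s: tuple(sorted(s)),
    )


def _oracle_min_l1(model, fixed_zero, windows, ref):
    """min sum_i |v_i - ref_i| over the knocked, objective-pinned LP."""
    n = model.n_reactions
    lb, ub = model.bounds_arrays()
    ridx = {r.id: i for i, r in enumerate(model.reactions)}
    for rid in fixed_zero:
        lb[ridx[rid]] = ub[ridx[rid]] = 0.0
    for rid, (lo, hi) in windows.items():
        j = ridx[rid]
        if lo is not None:
            lb[j] = max(lb[j], lo)
        if hi is not None:
            ub[j] = min(ub[j], hi)
    S = model.stoichiometric_matrix()
    from scipy import sparse

    A_eq = sparse.hstack([S, sparse.csr_matrix((model.n_metabolites, n))])
    # z_i >= v_i - ref_i   ->  v_i - z_i <= ref_i
    # z_i >= ref_i - v_i   -> -v_i - z_i <= -ref_i
    eye = sparse.eye(n)
    A_ub = sparse.vstack([sparse.hstack([eye, -eye]), sparse.hstack([-eye, -eye])])
    b_ub = np.concatenate([ref, -ref])
    big = 4.0 * (np.abs(lb).max() + np.abs(ub).max() + np.abs(ref).max() + 1.0)
    bounds = np.vstack([np.column_stack([lb, ub]), np.column_stack([np.zeros(n), np.full(n, big)])])
    c = np.concatenate([np.zeros(n), np.ones(n)])
    res = linprog(
        c, A_eq=A_eq, b_eq=np.zeros(model.n_metabolites),
        A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs",
    )
    if res.status != 0:
        raise RuntimeError(f"oracle L1 LP failed: {res.message}")
    return float(res.fun)
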