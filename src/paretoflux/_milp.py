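"""Internal MILP assembly for the bi-objective knockout program.

Variables are the fluxes v (one per reaction), binaries y (one per knockout
candidate in J_I), and, when an L1 flux-adjustment term is enabled, the
auxiliary deviations z (one per reaction). Constraints:

    S v = 0
    LB_j <= v_j <= UB_j                          j in J_E
    LB_j (1 - y_j) <= v_j <= UB_j (1 - y_j)      j in J_I
    sum_j y_j = K   (or <= K when relaxed)
    z_i >= +(v_i - ref_i),  z_i >= -(v_i - ref_i)    (MOMA mode)

The y-linked bound constraints are linear because LB/UB are constants:
v_j + LB_j y_j >= LB_j and v_j + UB_j y_j <= UB_j. They are exact for
bounds of any sign; no big-M reformulation is needed. Solved through the
HiGHS backend of :func:`scipy.optimize.milp`.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .lp import InfeasibleProblem, SolverConfig, UnboundedProblem
from .model import MetabolicModel

#: Distance ties in MOMA enumeration are resolved at this multiple of the
#: objective-pinning tolerance: pinning objectives inside a ±tol window
#: perturbs the attainable L1 distance of each deletion set by O(tol), so
#: sets tied at the exact point can separate by a few tol inside the window.
MOMA_TIE_FACTOR = 10.0


class KnockoutMilp:
    """Mutable knockout MILP: build once, re-solve under varying objectives."""

    def __init__(
        self,
        model: MetabolicModel,
        candidates: list[str],
        K: int,
        config: SolverConfig,
        cardinality_equality: bool = True,
        range_limits: dict[str, tuple[float, float]] | None = None,
    ):
        if K < 0:
            raise ValueError("K must be nonnegative")
        if K > len(candidates):
            raise InfeasibleProblem(
                f"K={K} exceeds the {len(candidates)} knockout candidates"
            )
        unknown = set(candidates) - set(model.reaction_ids)
        if unknown:
            raise KeyError(f"candidates not in the model: {sorted(unknown)}")
        self.model = model
        self.candidates = list(candidates)
        self.K = K
        self.config = config
        self.n = model.n_reactions
        self.q = len(candidates)
        self._ridx = {r.id: i for i, r in enumerate(model.reactions)}
        self._yidx = {rid: self.n + k for k, rid in enumerate(self.candidates)}
        self._nz = 0  # MOMA deviation variables, appended after y
        self._reference: np.ndarray | None = None

        lb, ub = model.bounds_arrays()
        if np.isinf(lb).any() or np.isinf(ub).any():
            raise UnboundedProblem(
                "model still has infinite bounds; apply cap_infinite_bounds first"
            )
        self._vlb = lb.copy()
        self._vub = ub.copy()
        cand_idx = np.array([self._ridx[rid] for rid in self.candidates], dtype=int)
        # A knockable reaction must be allowed to reach 0 flux.
        if len(cand_idx):
            self._vlb[cand_idx] = np.minimum(lb[cand_idx], 0.0)
            self._vub[cand_idx] = np.maximum(ub[cand_idx], 0.0)
        if range_limits:
            for rid, (lo, hi) in range_limits.items():
                j = self._ridx[rid]
                self._vlb[j] = max(self._vlb[j], -math.inf if lo is None else lo)
                self._vub[j] = min(self._vub[j], math.inf if hi is None else hi)

        # Static constraint rows as (coeff-dict over var index, lo, hi).
        self._rows: list[tuple[dict[int, float], float, float]] = []
        S = model.stoichiometric_matrix().tocoo()
        balance: dict[int, dict[int, float]] = {}
        for i, j, val in zip(S.row, S.col, S.data):
            balance.setdefault(int(i), {})[int(j)] = float(val)
        for i in range(model.n_metabolites):
            self._rows.append((balance.get(i, {}), 0.0, 0.0))
        for rid in self.candidates:
            j = self._ridx[rid]
            yj = self._yidx[rid]
            # v_j + LB_j y_j >= LB_j
            self._rows.append(({j: 1.0, yj: lb[j]}, lb[j], math.inf))
            # v_j + UB_j y_j <= UB_j
            self._rows.append(({j: 1.0, yj: ub[j]}, -math.inf, ub[j]))
        card_lo = float(K) if cardinality_equality else 0.0
        self._rows.append(({self._yidx[rid]: 1.0 for rid in self.candidates}, card_lo, float(K)))

    # ---- mutation ------------------------------------------------------

    def fix_flux(self, rid: str, value: float, tol: float | None = None) -> None:
        """Pin a reaction flux to ``value`` within ±tol via a constraint row."""
        tol = self.config.objective_match_tol if tol is None else tol
        self._rows.append(({self._ridx[rid]: 1.0}, value - tol, value + tol))

    def add_no_good_cut(self, members) -> None:
        """Exclude a found knockout set and all of its supersets."""
        members = sorted(members)
        if not members:
            raise ValueError(
                "no-good cut on the empty set: the unique K=0 solution has "
                "already been enumerated"
            )
        row = {self._yidx[rid]: 1.0 for rid in members}
        self._rows.append((row, -math.inf, float(len(members) - 1)))

    def add_score_floor(self, coeffs: dict[str, float], floor: float) -> None:
        """Require a weighted flux combination to stay at/above ``floor``."""
        row = {self._ridx[rid]: w for rid, w in coeffs.items()}
        self._rows.append((row, floor, math.inf))

    def pop_row(self) -> None:
        self._rows.pop()

    def enable_moma(self, reference: dict[str, float]) -> None:
        """Attach z_i >= |v_i - ref_i| deviation variables for all reactions."""
        missing = [r.id for r in self.model.reactions if r.id not in reference]
        if missing:
            raise ValueError(f"reference flux misses reactions: {missing[:5]}...")
        if self._nz:
            raise RuntimeError("MOMA deviations already enabled")
        self._nz = self.n
        self._reference = np.array(
            [reference[r.id] for r in self.model.reactions], dtype=float
        )
        z0 = self.n + self.q
        for i in range(self.n):
            ref = float(self._reference[i])
            # z_i - v_i >= -ref_i  and  z_i + v_i >= ref_i
            self._rows.append(({z0 + i: 1.0, i: -1.0}, -ref, math.inf))
            self._rows.append(({z0 + i: 1.0, i: 1.0}, ref, math.inf))

    def add_moma_cap(self, f_star: float, tol: float | None = None) -> None:
        """Constrain the total L1 deviation to the proven optimum f*.

        The default slack is ``MOMA_TIE_FACTOR × objective_match_tol`` so that
        deletion sets tied at the exact Pareto point are not separated by the
        window-induced O(tol) spread of their attainable distances.
        """
        if not self._nz:
            raise RuntimeError("enable_moma first")
        tol = MOMA_TIE_FACTOR * self.config.objective_match_tol if tol is None else tol
        z0 = self.n + self.q
        row = {z0 + i: 1.0 for i in range(self._nz)}
        self._rows.append((row, -math.inf, f_star + tol))

    # ---- solving -------------------------------------------------------

    @property
    def n_vars(self) -> int:
        return self.n + self.q + self._nz

    def _assemble(self):
        nv = self.n_vars
        ri, ci, data = [], [], []
        lo = np.empty(len(self._rows))
        hi = np.empty(len(self._rows))
        for r, (coeffs, l, h) in enumerate(self._rows):
            lo[r] = l
            hi[r] = h
            for c, val in coeffs.items():
                ri.append(r)
                ci.append(c)
                data.append(val)
        A = sparse.csr_matrix((data, (ri, ci)), shape=(len(self._rows), nv))
        var_lb = np.concatenate([self._vlb, np.zeros(self.q), np.zeros(self._nz)])
        big = 4.0 * (np.abs(self._vlb).max(initial=1.0) + np.abs(self._vub).max(initial=1.0))
        var_ub = np.concatenate([self._vub, np.ones(self.q), np.full(self._nz, big)])
        integrality = np.zeros(nv)
        integrality[self.n : self.n + self.q] = 1
        return A, lo, hi, var_lb, var_ub, integrality

    def solve(self, objective: dict[str, float] | str, sense: str = "max"):
        """Solve for a flux-weighted objective (or ``"moma"``: min sum z).

        Returns ``(values, knockouts, objective_value)`` where ``values`` maps
        reaction id to flux and ``knockouts`` is the frozenset of y=1 ids.
        """
        A, lo, hi, var_lb, var_ub, integrality = self._assemble()
        c = np.zeros(self.n_vars)
        if objective == "moma":
            if not self._nz:
                raise RuntimeError("enable_moma first")
            c[self.n + self.q :] = 1.0
            sign = 1.0  # always minimized
        else:
            for rid, w in objective.items():
                c[self._ridx[rid]] = w
            sign = -1.0 if sense == "max" else 1.0
            c *= sign
        # Exact optima matter here: equivalent-set tests compare objective
        # values at 1e-6 resolution, far below HiGHS's default MIP gap. The
        # MIP feasibility tolerance must also sit well below the ±1e-6
        # objective-pinning windows, which otherwise degenerate inside HiGHS.
        options = {
            "mip_rel_gap": 0.0,
            "mip_feasibility_tolerance": 1e-9,
            "primal_feasibility_tolerance": 1e-9,
        }
        if self.config.time_limit_s is not None:
            options["time_limit"] = self.config.time_limit_s
        with warnings.catch_warnings():
            # scipy warns that non-core options are forwarded to HiGHS verbatim
            warnings.simplefilter("ignore", RuntimeWarning)
            res = milp(
                c=c,
                constraints=[LinearConstraint(A, lo, hi)],
                integrality=integrality,
                bounds=Bounds(var_lb, var_ub),
                options=options,
            )
        if res.status == 2:
            raise InfeasibleProblem("knockout MILP is infeasible")
        if res.status == 3:  # pragma: no cover - bounds are finite by construction
            raise UnboundedProblem("knockout MILP is unbounded")
        if res.status != 0 or res.x is None:  # pragma: no cover
            raise RuntimeError(f"MILP solver failed: {res.message}")
        x = res.x
        values = {r.id: float(x[i]) for i, r in enumerate(self.model.reactions)}
        knockouts = frozenset(
            rid for rid in self.candidates if x[self._yidx[rid]] > 0.5
        )
        if objective == "moma":
            obj_val = float(x[self.n + self.q :].sum())
        else:
            obj_val = float(sum(values[rid] * w for rid, w in objective.items()))
        return values, knockouts, obj_val

    def solve_lexicographic(self, objective_ids: list[str], weights: tuple[float, ...]):
        """Weighted solve refined lexicographically over the listed objectives.

        First maximize the weighted sum, then, holding the score, re-optimize
        each objective in listed order. Deterministic tie-break for reporting.
        """
        slack = 1e-9
        pushed = 0
        try:
            wobj = {rid: w for rid, w in zip(objective_ids, weights) if w != 0.0}
            values, kos, score = self.solve(wobj, "max")
            self.add_score_floor(wobj, score - slack * (1.0 + abs(score)))
            pushed += 1
            for rid in objective_ids:
                values, kos, val = self.solve({rid: 1.0}, "max")
                self.add_score_floor({rid: 1.0}, val - slack * (1.0 + abs(val)))
                pushed += 1
        finally:
            for _ in range(pushed):
                self.pop_row()
        objectives = tuple(values[rid] for rid in objective_ids)
        return values, kos, objectives
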