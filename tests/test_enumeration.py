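import dataclasses
import math

import pytest

from paretoflux import (
    brute_force_enumerate,
    enumerate_equivalent,
    enumerate_moma,
    minimal_distance_sets,
    moma_distance_lp,
    no_good_cut,
    random_branched_network,
    solve_bop,
    solve_fba,
)
from paretoflux.pareto import KnockoutSet, ParetoPoint
from paretoflux.lp import FluxVector

from conftest import canon

F_TOL = 1e-5  # objective pinning at ±1e-6 shifts attainable distances by O(1e-6)


def point_at(objectives):
    """A bare Pareto point (user-fixed objective values)."""
    return ParetoPoint(
        objectives=tuple(objectives),
        witness_flux=FluxVector({}, objectives[0]),
        witness_knockouts=KnockoutSet(frozenset()),
    )


class TestNoGoodCut:
    def test_single_member(self):
        cut = no_good_cut(frozenset({"R2"}))
        assert cut.coeffs == {"R2": 1.0}
        assert cut.rhs == 0.0

    def test_pair(self):
        cut = no_good_cut(frozenset({"R1", "R2"}))
        assert cut.coeffs == {"R1": 1.0, "R2": 1.0}
        assert cut.rhs == 1.0

    def test_supersets_violate_the_cut(self):
        cut = no_good_cut(frozenset({"R1", "R2"}))
        y = {"R1": 1, "R2": 1, "R3": 1}  # superset of the found pair
        assert sum(cut.coeffs[r] * y[r] for r in cut.coeffs) > cut.rhs

    def test_empty_set_signalled(self):
        with pytest.raises(ValueError, match="empty"):
            no_good_cut(frozenset())


class TestEnumerateEquivalent:
    def test_growth_anchor_has_two_equivalent_sets(self, toy):
        res = enumerate_equivalent(toy, point_at((0.0, 10.0)), K=1)
        assert canon(ks.members for ks in res.knockout_sets) == (("R2",), ("R2b",))
        assert res.exhausted and res.status == "ok"

    def test_product_anchor_sets_match_bruteforce(self, toy):
        # with the product branch duplicated, any single deletion still
        # admits (prod=10, bio=0): biomass is free to be zero
        res = enumerate_equivalent(toy, point_at((10.0, 0.0)), K=1)
        oracle, _ = brute_force_enumerate(toy, (10.0, 0.0), K=1)
        assert canon(ks.members for ks in res.knockout_sets) == canon(oracle)
        assert canon(oracle) == (("R1",), ("R2",), ("R2b",))
        assert res.exhausted

    def test_budget_semantics(self, toy):
        res = enumerate_equivalent(toy, point_at((10.0, 0.0)), K=1, max_sets=0)
        assert res.knockout_sets == []
        assert not res.exhausted

    def test_truncation_below_total(self, toy):
        res = enumerate_equivalent(toy, point_at((10.0, 0.0)), K=1, max_sets=2)
        assert len(res.knockout_sets) == 2
        assert not res.exhausted

    def test_infeasible_point_flagged(self, toy):
        # uptake 10 cannot feed product and biomass at 10 each
        res = enumerate_equivalent(toy, point_at((10.0, 10.0)), K=1)
        assert res.knockout_sets == []
        assert res.exhausted
        assert res.status == "inconsistent-point"

    def test_k_zero_unique_empty_set(self, toy):
        res = enumerate_equivalent(toy, point_at((10.0, 0.0)), K=0, candidates=[])
        assert [ks.members for ks in res.knockout_sets] == [frozenset()]
        assert res.exhausted

    def test_set_count_bounded_by_combinations(self, toy):
        j_i = toy.inessential_ids()
        for K in (1, 2):
            front = solve_bop(toy, K)
            for p in front.points:
                res = enumerate_equivalent(toy, p, K)
                assert len(res.knockout_sets) <= math.comb(len(j_i), K)
                sizes = {ks.size for ks in res.knockout_sets}
                assert sizes <= {K}
                # pairwise distinct (no-good cuts make repeats impossible)
                members = [ks.members for ks in res.knockout_sets]
                assert len(set(members)) == len(members)


class TestMomaDistance:
    def test_growth_anchor_distance_zero(self, toy, toy_wt):
        f_star, _ = moma_distance_lp(toy, point_at((0.0, 10.0)), K=1, reference=toy_wt)
        assert f_star == pytest.approx(0.0, abs=F_TOL)

    def test_product_anchor_distance_forty(self, toy, toy_wt):
        # reroute of 10 units: R1 off (10), carbon through a product branch
        # (10), biomass export off (10), product export on (10)
        f_star, _ = moma_distance_lp(toy, point_at((10.0, 0.0)), K=1, reference=toy_wt)
        assert f_star == pytest.approx(40.0, abs=F_TOL)

    def test_self_distance_zero(self, toy):
        from paretoflux import simulate_knockout

        mutant = simulate_knockout(toy, {"R1"}, "EX_prod")
        f_star, ks = moma_distance_lp(
            toy, point_at((10.0, 0.0)), K=1, reference=mutant
        )
        assert f_star == pytest.approx(0.0, abs=F_TOL)
        assert ks.members == frozenset({"R1"})


class TestEnumerateMoma:
    def test_growth_anchor(self, toy, toy_wt):
        res = enumerate_moma(toy, point_at((0.0, 10.0)), K=1, reference=toy_wt)
        assert res.f_star == pytest.approx(0.0, abs=F_TOL)
        assert canon(ks.members for ks in res.knockout_sets) == (("R2",), ("R2b",))
        assert res.exhausted

    def test_product_anchor_all_singletons_tied(self, toy, toy_wt):
        # at (10, 0) every singleton deletion admits a flux at distance 40
        res = enumerate_moma(toy, point_at((10.0, 0.0)), K=1, reference=toy_wt)
        assert res.f_star == pytest.approx(40.0, abs=F_TOL)
        _, dists = brute_force_enumerate(toy, (10.0, 0.0), K=1, reference=toy_wt)
        assert canon(ks.members for ks in res.knockout_sets) == canon(
            minimal_distance_sets(dists)
        )

    def test_infeasible_point_flagged(self, toy, toy_wt):
        res = enumerate_moma(toy, point_at((10.0, 10.0)), K=1, reference=toy_wt)
        assert res.status == "inconsistent-point"
        assert res.knockout_sets == []

    def test_capped_duplicate_branch_variant(self, toy, toy_wt):
        # shrink R2b to capacity 5: the growth anchor still has both product
        # branch deletions at distance zero, while (10,0) loses {R2} (the
        # surviving R2b can only carry 5)
        reactions = [
            dataclasses.replace(r, upper_bound=5.0) if r.id == "R2b" else r
            for r in toy.reactions
        ]
        variant = dataclasses.replace(toy, reactions=reactions)
        wt = solve_fba(variant)
        res = enumerate_moma(variant, point_at((0.0, 10.0)), K=1, reference=wt)
        assert res.f_star == pytest.approx(0.0, abs=F_TOL)
        assert canon(ks.members for ks in res.knockout_sets) == (("R2",), ("R2b",))
        res10 = enumerate_equivalent(variant, point_at((10.0, 0.0)), K=1)
        oracle, _ = brute_force_enumerate(variant, (10.0, 0.0), K=1)
        assert canon(ks.members for ks in res10.knockout_sets) == canon(oracle)
        assert ("R2",) not in canon(oracle)

    @pytest.mark.parametrize("seed", [0, 2, 5])
    @pytest.mark.parametrize("K", [1, 2])
    def test_subset_law_and_distance_optimality(self, seed, K):
        model = random_branched_network(seed)
        wt = solve_fba(model)
        front = solve_bop(model, K)
        for p in front.points:
            full = enumerate_equivalent(model, p, K)
            restricted = enumerate_moma(model, p, K, reference=wt)
            full_sets = {ks.members for ks in full.knockout_sets}
            moma_sets = {ks.members for ks in restricted.knockout_sets}
            assert moma_sets <= full_sets
            # every enumerated-but-excluded set is strictly farther
            _, dists = brute_force_enumerate(model, p, K, reference=wt)
            tied = set(minimal_distance_sets(dists))
            assert moma_sets == tied
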