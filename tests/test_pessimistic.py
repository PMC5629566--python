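"""Pessimistic design MILPs, the inner dual block and big-M linearization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pessiknock as pk
from pessiknock.solver import MipBuilder, solve_lp


class TestToy7WorkedValues:
    def test_p_optknock_growth_couples_production(self, toy7):
        res = pk.solve_p_optknock(toy7, 3, 0.0)
        assert res.knocked == ["R1", "R3", "R5"]
        assert res.objective == pytest.approx(5.0, abs=1e-4)

    def test_p_optknock_guarantee_degrades_with_tolerance(self, toy7):
        res = pk.solve_p_optknock(toy7, 3, 0.5)
        assert res.objective == pytest.approx(2.5, abs=1e-4)

    def test_p_room_finds_the_same_robust_design(self, toy7, w_toy7):
        res = pk.solve_p_room(toy7, 3, 0.0, w_toy7)
        assert res.knocked == ["R1", "R3", "R5"]
        assert res.objective == pytest.approx(5.0, abs=1e-4)


class TestRoomInnerDual:
    def test_empty_design_needs_no_changes(self, toy7, w_toy7):
        dual = pk.build_room_inner_dual(toy7, w_toy7, pk.KnockoutDesign.empty())
        res = dual.solve()
        assert res.status == "optimal"
        assert res.objective == pytest.approx(0.0, abs=1e-7)

    @pytest.mark.parametrize("ids", [["R1"], ["R1", "R3", "R5"], ["R2", "R4"]])
    def test_strong_duality_against_primal(self, toy7, w_toy7, ids):
        design = pk.KnockoutDesign.of(ids)
        dual = pk.build_room_inner_dual(toy7, w_toy7, design)
        primal = pk.inner_optimum(toy7, design, "room", w_toy7)
        assert dual.solve().objective == pytest.approx(primal, abs=1e-5)

    def test_non_knockable_design_rejected(self, toy7, w_toy7):
        with pytest.raises(ValueError, match="UP"):
            pk.build_room_inner_dual(toy7, w_toy7, pk.KnockoutDesign.of(["UP"]))

    def test_named_dual_groups_cover_all_rows(self, toy7, w_toy7):
        dual = pk.build_room_inner_dual(toy7, w_toy7, pk.KnockoutDesign.of(["R1"]))
        res = dual.solve()
        groups = dual.named_duals(res)
        assert set(groups) <= {"mu_max", "mu_min", "mu_max2", "mu_min2", "a", "mu_biom"}
        for key in ("mu_max", "mu_min", "mu_max2", "mu_min2", "a"):
            assert set(groups[key]) == set(toy7.reaction_ids())
        assert all(v >= -1e-9 for g in groups.values() for v in g.values())


def _bilinear_brute_force(c1, c2, b, u):
    """max over z in {0,1}: c1 x + c2 (z x)  s.t.  x + z x <= u, |x| <= b."""
    best = -np.inf
    for z in (0, 1):
        res = solve_lp(
            np.array([c1 + c2 * z]),
            A_ub=np.array([[1.0 + z]]),
            b_ub=np.array([u]),
            bounds=[(-b, b)],
            sense="max",
        )
        if res.optimal:
            best = max(best, res.objective)
    return best


@settings(deadline=None, max_examples=40, derandomize=True)
@given(
    c1=st.floats(-5, 5),
    c2=st.floats(-5, 5),
    b=st.floats(0.5, 50),
    u=st.floats(-20, 20),
)
def test_linearized_products_match_brute_force(c1, c2, b, u):
    """The big-M linearization is exact for binary x bounded-continuous terms."""
    mb = MipBuilder()
    z = mb.add_var("z", 0, 1, integer=True)
    x = mb.add_var("x", -b, b)
    xi = mb.mark_product(z, x, M=b)
    mb.add_constr([(x, 1.0), (xi, 1.0)], ub=u)
    mb.set_objective([(x, c1), (xi, c2)], sense="max")
    pk.linearize_products(mb, pk.BigMConfig())
    res = mb.solve()
    brute = _bilinear_brute_force(c1, c2, b, u)
    if not np.isfinite(brute):
        assert res.status != "optimal"
    else:
        assert res.objective == pytest.approx(brute, abs=1e-6, rel=1e-6)


def test_product_collapses_at_fixed_binary():
    for z_fix, expect in ((0, 0.0), (1, 3.5)):
        mb = MipBuilder()
        z = mb.add_var("z", z_fix, z_fix, integer=True)
        x = mb.add_var("x", 3.5, 3.5)
        xi = mb.mark_product(z, x, M=10.0)
        mb.set_objective([(xi, 1.0)], sense="max")
        pk.linearize_products(mb, pk.BigMConfig())
        res = mb.solve()
        assert res.x[xi] == pytest.approx(expect, abs=1e-8)


def test_unbounded_product_factor_is_configuration_error():
    mb = MipBuilder()
    z = mb.add_var("z", 0, 1, integer=True)
    x = mb.add_var("x")
    mb.mark_product(z, x, M=None)
    mb.set_objective([(x, 1.0)], sense="max")
    with pytest.raises(ValueError, match="big-M"):
        pk.linearize_products(mb, pk.BigMConfig(M_dual=float("inf")))


class TestGridProperties:
    """Small sanity grid; the full oracle-equivalence grid runs in the
    acceptance suite."""

    @pytest.mark.parametrize("seed", [1, 4])
    def test_milp_matches_oracle(self, random_model, random_wildtype, seed):
        model, w = random_model(seed), random_wildtype(seed)
        for eps in (0.0, 0.5):
            oracle_room = pk.pessimistic_enumeration_oracle(model, 2, "room", eps, w)
            assert pk.solve_p_room(model, 2, eps, w).objective == pytest.approx(
                oracle_room.objective, abs=1e-4
            )
            oracle_bio = pk.pessimistic_enumeration_oracle(model, 2, "biomass", eps)
            assert pk.solve_p_optknock(model, 2, eps).objective == pytest.approx(
                oracle_bio.objective, abs=1e-4
            )

    def test_epsilon_monotone_nonincreasing(self, toy7, w_toy7):
        for solve in (
            lambda e: pk.solve_p_optknock(toy7, 3, e).objective,
            lambda e: pk.solve_p_room(toy7, 3, e, w_toy7).objective,
        ):
            objs = [solve(e) for e in (0.0, 0.25, 0.5, 1.0)]
            for a, b in zip(objs, objs[1:]):
                assert b <= a + 1e-6

    def test_budget_monotone_nondecreasing(self, toy7, w_toy7):
        objs = [pk.solve_p_optknock(toy7, K, 0.25).objective for K in (1, 2, 3)]
        for a, b in zip(objs, objs[1:]):
            assert b >= a - 1e-6

    def test_optimistic_upper_bounds_pessimistic(self, toy7, w_toy7):
        for K in (1, 2, 3):
            opt = pk.solve_optknock(toy7, K).objective
            room = pk.solve_room_design(toy7, K, w_toy7).objective
            for eps in (0.0, 0.5):
                assert pk.solve_p_optknock(toy7, K, eps).objective <= opt + 1e-6
                assert pk.solve_p_room(toy7, K, eps, w_toy7).objective <= room + 1e-6

    def test_invalid_epsilon_rejected(self, toy7, w_toy7):
        with pytest.raises(ValueError):
            pk.solve_p_optknock(toy7, 2, 1.5)
        with pytest.raises(ValueError):
            pk.solve_p_room(toy7, 2, -0.1, w_toy7)
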