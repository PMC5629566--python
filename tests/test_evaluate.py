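"""Worst-/best-case evaluation of fixed designs and the enumeration oracle."""

import pytest

import pessiknock as pk
from pessiknock.evaluate import EnumerationBudgetError, InfeasibleDesignError


class TestInnerOptimum:
    def test_biomass_inner_optimum_under_knockouts(self, toy7):
        assert pk.inner_optimum(toy7, pk.KnockoutDesign.of(["R1", "R3", "R5"]),
                                "biomass") == pytest.approx(5.0, abs=1e-6)

    def test_wildtype_needs_no_flux_changes(self, toy7, w_toy7):
        assert pk.inner_optimum(toy7, pk.KnockoutDesign.empty(), "room",
                                w_toy7) == pytest.approx(0.0, abs=1e-6)

    def test_biomass_impossible_design_raises(self, toy7):
        with pytest.raises(InfeasibleDesignError):
            pk.inner_optimum(toy7, pk.KnockoutDesign.of(["R1", "R4"]), "biomass")


class TestEpsilonExtremeFlux:
    def test_free_sink_splits_cooperative_and_worst_case(self, toy7):
        # {R1,R3}: at max biomass 5, the 5 units of C split freely between
        # the target exchange and the uncredited sink
        ev = pk.epsilon_extreme_flux(toy7, pk.KnockoutDesign.of(["R1", "R3"]), "biomass", 0.0)
        assert ev.worst_flux == pytest.approx(0.0, abs=1e-6)
        assert ev.best_flux == pytest.approx(5.0, abs=1e-6)
        assert ev.inner_optimum == pytest.approx(5.0, abs=1e-6)

    def test_growth_coupled_design_halves_with_tolerance(self, toy7):
        # {R1,R3,R5}: biomass may drop to 2.5, freeing half the substrate
        ev = pk.epsilon_extreme_flux(
            toy7, pk.KnockoutDesign.of(["R1", "R3", "R5"]), "biomass", 0.5
        )
        assert ev.worst_flux == pytest.approx(2.5, abs=1e-6)

    @pytest.mark.parametrize("eps_pair", [(0.0, 0.25), (0.25, 0.5), (0.5, 1.0)])
    def test_band_nesting_in_epsilon(self, toy7, w_toy7, eps_pair):
        lo_eps, hi_eps = eps_pair
        for inner, w in (("biomass", None), ("room", w_toy7)):
            for ids in (["R1"], ["R1", "R3"], ["R1", "R3", "R5"]):
                d = pk.KnockoutDesign.of(ids)
                lo = pk.epsilon_extreme_flux(toy7, d, inner, lo_eps, w)
                hi = pk.epsilon_extreme_flux(toy7, d, inner, hi_eps, w)
                assert hi.worst_flux <= lo.worst_flux + 1e-6
                assert hi.best_flux >= lo.best_flux - 1e-6
                assert lo.worst_flux <= lo.best_flux + 1e-6

    def test_full_tolerance_reduces_to_target_flux_variability(self, toy7, diamond):
        """At eps=1 the biomass band is vacuous above the viability threshold,
        so the extremes equal FVA of the target reaction under v_biom >= min."""
        for model, ids in ((toy7, ["R1", "R3"]), (toy7, []), (diamond, ["AB"])):
            d = pk.KnockoutDesign.of(ids)
            ev = pk.epsilon_extreme_flux(model, d, "biomass", 1.0)
            tgt = model.target_reaction.id
            fva_min = pk.solve_fba(model, tgt, sense="min", design=d).objective
            fva_max = pk.solve_fba(model, tgt, sense="max", design=d).objective
            assert ev.worst_flux == pytest.approx(fva_min, abs=1e-6)
            assert ev.best_flux == pytest.approx(fva_max, abs=1e-6)


class TestEnumerationOracle:
    def test_toy7_growth_coupling_needs_three_knockouts(self, toy7):
        o3 = pk.pessimistic_enumeration_oracle(toy7, 3, "biomass", 0.0)
        assert o3.knocked == ["R1", "R3", "R5"]
        assert o3.objective == pytest.approx(5.0, abs=1e-6)
        o2 = pk.pessimistic_enumeration_oracle(toy7, 2, "biomass", 0.0)
        assert o2.objective == pytest.approx(0.0, abs=1e-6)

    def test_infeasible_full_knockout_is_filtered(self, toy7):
        # knocking all 5 internal reactions strands the fixed uptake; the
        # oracle must fall back to the best feasible subset
        o = pk.pessimistic_enumeration_oracle(toy7, 5, "biomass", 0.0)
        assert o.status == "optimal"
        assert len(o.design.knocked) < 5
        assert o.objective == pytest.approx(5.0, abs=1e-6)

    def test_budget_refusal(self, toy7):
        with pytest.raises(EnumerationBudgetError, match="budget"):
            pk.pessimistic_enumeration_oracle(toy7, 3, "biomass", 0.0, max_designs=5)

    def test_table_consistent_with_single_calls(self, toy7, w_toy7):
        table = pk.pessimistic_enumeration_table(toy7, 2, "room", [0.0, 0.5], w_toy7)
        for (K, eps), res in table.items():
            single = pk.pessimistic_enumeration_oracle(toy7, K, "room", eps, w_toy7)
            assert res.objective == pytest.approx(single.objective, abs=1e-9)
            assert res.design.knocked == single.design.knocked
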