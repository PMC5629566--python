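"""Model containers, tabular/SBML I/O and fixture generation."""

import json

import pytest

import pessiknock as pk
from pessiknock.model import ModelConfigurationError, ModelIntegrityError


class TestToy7Structure:
    def test_counts(self, toy7):
        assert len(toy7.balanced_metabolite_ids()) == 4
        assert len(toy7.reactions) == 9
        assert sorted(toy7.knockable_ids()) == ["R1", "R2", "R3", "R4", "R5"]

    def test_unique_role_designations(self, toy7):
        assert toy7.uptake_reaction.id == "UP"
        assert toy7.biomass_reaction.id == "BIOM"
        assert toy7.target_reaction.id == "CHEM"

    def test_fixed_uptake_bounds(self, toy7):
        up = toy7.uptake_reaction
        assert up.lower_bound == up.upper_bound == toy7.uptake_rate == 10.0


@pytest.mark.parametrize("name,seed", [("toy7", 0), ("diamond", 0), ("random", 3), ("random", 11)])
def test_tabular_round_trip_identity(tmp_path, name, seed):
    model = pk.make_fixture(name, seed=seed)
    path = tmp_path / f"{name}.json"
    pk.save_model(model, path)
    assert pk.load_model(path) == model


def test_reversible_bounds_round_trip_sign_exact(tmp_path, toy7):
    model = toy7.copy()
    model.reaction("R3").lower_bound = -100.0
    path = tmp_path / "rev.json"
    pk.save_model(model, path)
    assert pk.load_model(path).reaction("R3").lower_bound == -100.0


def test_unknown_metabolite_is_integrity_error(tmp_path, toy7):
    pk.save_model(toy7, tmp_path / "bad.json")
    doc = json.loads((tmp_path / "bad.json").read_text())
    doc["reactions"][1]["stoichiometry"]["X"] = 1.0
    (tmp_path / "bad.json").write_text(json.dumps(doc))
    with pytest.raises(ModelIntegrityError, match="X"):
        pk.load_model(tmp_path / "bad.json")


def test_missing_role_is_configuration_error(tmp_path, toy7):
    pk.save_model(toy7, tmp_path / "m.json")
    doc = json.loads((tmp_path / "m.json").read_text())
    for r in doc["reactions"]:
        if r["role"] == "target":
            r["role"] = "exchange"
    doc["roles"]["target"] = []
    (tmp_path / "m.json").write_text(json.dumps(doc))
    with pytest.raises(ModelConfigurationError, match="target"):
        pk.load_model(tmp_path / "m.json")


def test_save_to_unwritable_location_raises(toy7, tmp_path):
    with pytest.raises(OSError):
        pk.save_model(toy7, tmp_path)  # a directory is not a writable file


class TestValidateModel:
    def test_toy7_is_clean(self, toy7):
        assert pk.validate_model(toy7) == []

    def test_unreachable_biomass_target_reported(self, toy7):
        model = toy7.copy()
        model.biomass_min = 50.0
        violations = pk.validate_model(model)
        assert any("exceeds achievable" in v for v in violations)

    def test_inverted_bounds_reported(self, toy7):
        model = toy7.copy()
        model.reaction("R1").lower_bound = 5.0
        model.reaction("R1").upper_bound = 1.0
        violations = pk.validate_model(model, check_feasibility=False)
        assert any("lower_bound" in v for v in violations)

    def test_knockable_role_policy(self, toy7):
        model = toy7.copy()
        model.reaction("BIOM").knockable = True
        violations = pk.validate_model(model, check_feasibility=False)
        assert any("not knockable by policy" in v for v in violations)


class TestFixtures:
    def test_random_fixture_is_seed_deterministic(self):
        assert pk.make_fixture("random", seed=7) == pk.make_fixture("random", seed=7)

    def test_unknown_fixture_name(self):
        with pytest.raises(ValueError, match="unknown fixture"):
            pk.make_fixture("nope")

    @pytest.mark.parametrize("seed", range(6))
    def test_random_fixtures_feasible_with_bounded_knockouts(self, random_model, seed):
        model = random_model(seed)
        assert len(model.knockable_ids()) <= 8
        assert pk.validate_model(model) == []
        sol = pk.solve_fba(model, model.biomass_reaction.id)
        assert sol.status == "optimal"
        assert sol.objective >= model.biomass_min


class TestKnockoutDesign:
    def test_budget_enforced(self, toy7):
        design = pk.KnockoutDesign(frozenset({"R1", "R2"}), budget=1)
        with pytest.raises(ValueError, match="budget"):
            design.validate_against(toy7)

    def test_non_knockable_rejected(self, toy7):
        with pytest.raises(ValueError, match="UP"):
            pk.KnockoutDesign.of(["UP"]).validate_against(toy7)


def test_sbml_round_trip_through_cobra(tmp_path, toy7):
    """An SBML/FBC export of toy7 reloads with identical stoichiometry and FBA optimum."""
    cobra = pytest.importorskip("cobra")
    cm = cobra.Model("toy7")
    mets = {m.id: cobra.Metabolite(m.id, compartment="c") for m in toy7.metabolites}
    for r in toy7.reactions:
        rx = cobra.Reaction(r.id)
        rx.lower_bound, rx.upper_bound = r.lower_bound, r.upper_bound
        cm.add_reactions([rx])
        rx.add_metabolites({mets[k]: v for k, v in r.stoichiometry.items()})
    cm.objective = "BIOM"
    path = tmp_path / "toy7.xml"
    cobra.io.write_sbml_model(cm, str(path))

    model = pk.load_model(
        path,
        format="sbml",
        roles={"uptake": "UP", "target": "CHEM"},
        uptake_rate=10.0,
        biomass_min=1.0,
        knockable=["R1", "R2", "R3", "R4", "R5"],
    )
    assert model.biomass_reaction.id == "BIOM"
    assert len(model.reactions) == 9
    assert model.reaction("R4").stoichiometry == {"A": -1.0, "B": 0.5, "C": 0.5}
    assert pk.solve_fba(model, "BIOM").objective == pytest.approx(10.0)
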