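import math

import pytest

from paretoflux import (
    BoundOverride,
    MetabolicModel,
    Metabolite,
    ModelFormatError,
    ModelValidationError,
    Reaction,
    apply_bound_overrides,
    cap_infinite_bounds,
    load_model,
    random_branched_network,
    read_bound_overrides,
    save_model,
)
from paretoflux.model import model_from_dict, model_to_dict

INF = math.inf


def two_reaction_model(lb=0.0, ub=10.0):
    return MetabolicModel(
        metabolites=[Metabolite("A", compartment="c")],
        reactions=[
            Reaction("in", {"A": 1.0}, lb, ub),
            Reaction("out", {"A": -1.0}, 0.0, 1000.0),
        ],
        biomass_id="out",
    )


class TestValidation:
    def test_toy_structure(self, toy):
        assert toy.n_reactions == 6
        assert toy.n_metabolites == 3
        assert toy.biomass_id == "EX_bio"
        assert toy.target_ids == ("EX_prod",)

    def test_unknown_metabolite_rejected(self):
        doc = model_to_dict(two_reaction_model())
        doc["reactions"][0]["stoich"] = {"X": 1.0}
        with pytest.raises(ModelValidationError, match="unknown metabolite 'X'"):
            model_from_dict(doc)

    def test_biomass_must_resolve(self):
        with pytest.raises(ModelValidationError, match="biomass"):
            MetabolicModel(
                metabolites=[Metabolite("A")],
                reactions=[Reaction("in", {"A": 1.0}, 0, 1)],
                biomass_id="nope",
            )

    @pytest.mark.parametrize(
        "mutate, message",
        [
            (lambda d: d["reactions"][0].update(lb=5, ub=1), "exceeds"),
            (lambda d: d["reactions"][0].update(stoich={}), "empty stoichiometry"),
            (lambda d: d["reactions"].append(dict(d["reactions"][0])), "duplicate"),
            (lambda d: d["reactions"][0]["stoich"].update(A=float("nan")), "non-finite"),
        ],
    )
    def test_invalid_models_rejected(self, mutate, message):
        doc = model_to_dict(two_reaction_model())
        mutate(doc)
        with pytest.raises(ModelValidationError, match=message):
            model_from_dict(doc)

    def test_missing_bounds_is_a_format_error(self):
        doc = model_to_dict(two_reaction_model())
        del doc["reactions"][0]["lb"]
        with pytest.raises(ModelFormatError, match="lb"):
            model_from_dict(doc)

    def test_exchange_detection(self, toy):
        assert toy.reaction("EX_glc").is_exchange
        assert toy.reaction("EX_prod").is_exchange
        assert not toy.reaction("R1").is_exchange


class TestJsonRoundTrip:
    @pytest.mark.parametrize("seed", [0, 3, 7])
    def test_round_trip_preserves_everything(self, tmp_path, seed):
        model = random_branched_network(seed)
        path = tmp_path / "m.json"
        save_model(model, path)
        back = load_model(path)
        assert back.reaction_ids == model.reaction_ids
        assert back.metabolite_ids == model.metabolite_ids
        assert back.biomass_id == model.biomass_id
        assert back.target_ids == model.target_ids
        assert back.essential_ids == model.essential_ids
        assert (back.stoichiometric_matrix() != model.stoichiometric_matrix()).nnz == 0
        for a, b in zip(model.reactions, back.reactions):
            assert (a.lower_bound, a.upper_bound) == (b.lower_bound, b.upper_bound)
        assert back.digest() == model.digest()

    def test_infinite_bounds_round_trip(self, tmp_path):
        model = two_reaction_model(lb=-INF, ub=INF)
        path = tmp_path / "inf.json"
        save_model(model, path)
        back = load_model(path)
        assert back.reactions[0].lower_bound == -INF
        assert back.reactions[0].upper_bound == INF

    def test_malformed_json_is_a_format_error(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text("{not json")
        with pytest.raises(ModelFormatError, match="invalid JSON"):
            load_model(path)


class TestBoundManipulation:
    def test_cap_replaces_only_infinite_bounds(self):
        model = two_reaction_model(lb=-INF, ub=INF)
        capped = cap_infinite_bounds(model, 1000.0)
        assert capped.reactions[0].lower_bound == -1000.0
        assert capped.reactions[0].upper_bound == 1000.0
        # finite bounds untouched
        assert capped.reactions[1].upper_bound == 1000.0
        assert capped.reactions[1].lower_bound == 0.0

    def test_cap_one_sided(self):
        model = two_reaction_model(lb=-INF, ub=10.0)
        capped = cap_infinite_bounds(model, 50.0)
        assert capped.reactions[0].lower_bound == -50.0
        assert capped.reactions[0].upper_bound == 10.0

    def test_cap_idempotent(self):
        model = two_reaction_model(lb=-INF, ub=INF)
        once = cap_infinite_bounds(model, 1000.0)
        twice = cap_infinite_bounds(once, 1000.0)
        assert once.digest() == twice.digest()

    def test_cap_requires_positive(self, toy):
        with pytest.raises(ValueError):
            cap_infinite_bounds(toy, -1.0)

    def test_overrides_applied_in_order(self, toy):
        out = apply_bound_overrides(
            toy,
            [
                BoundOverride("EX_glc", "lower", -10.0),
                BoundOverride("R2", "upper", 6.0),
            ],
        )
        assert out.reaction("EX_glc").lower_bound == -10.0
        assert out.reaction("R2").upper_bound == 6.0
        # original untouched
        assert toy.reaction("EX_glc").lower_bound == 0.0

    def test_override_unknown_reaction(self, toy):
        with pytest.raises(ModelValidationError, match="unknown reaction"):
            apply_bound_overrides(toy, [BoundOverride("rX", "lower", 0.0)])

    def test_override_crossing_bounds(self, toy):
        with pytest.raises(ModelValidationError, match="exceed"):
            apply_bound_overrides(toy, [BoundOverride("EX_glc", "lower", 99.0)])

    def test_override_raising_lower_within_upper_is_valid(self, toy):
        out = apply_bound_overrides(toy, [BoundOverride("R1", "lower", 5.0)])
        assert out.reaction("R1").lower_bound == 5.0
        assert out.reaction("R1").upper_bound == 1000.0

    def test_override_tsv_reader(self, tmp_path):
        path = tmp_path / "ov.tsv"
        path.write_text("# comment\nr_1714\tlower\t-10\nr_0438\tupper\t10\nr_1054\tupper\t6\n")
        ovs = read_bound_overrides(path)
        assert [(o.reaction_id, o.which, o.value) for o in ovs] == [
            ("r_1714", "lower", -10.0),
            ("r_0438", "upper", 10.0),
            ("r_1054", "upper", 6.0),
        ]


class TestSbml:
    def test_sbml_reader_matches_json(self, toy, tmp_path):
        cobra = pytest.importorskip("cobra")
        cmodel = cobra.Model("toy")
        mets = {m.id: cobra.Metabolite(m.id, compartment="c") for m in toy.metabolites}
        for rxn in toy.reactions:
            cr = cobra.Reaction(rxn.id)
            cr.lower_bound, cr.upper_bound = rxn.lower_bound, rxn.upper_bound
            cmodel.add_reactions([cr])
            cr.add_metabolites({mets[mid]: c for mid, c in rxn.stoichiometry.items()})
        cmodel.objective = "EX_bio"
        path = tmp_path / "toy.xml"
        cobra.io.write_sbml_model(cmodel, str(path))

        back = load_model(path, dialect="sbml", target_ids=("EX_prod",))
        assert set(back.reaction_ids) == set(toy.reaction_ids)
        assert back.biomass_id == "EX_bio"  # inferred from the FBC objective
        for rid in toy.reaction_ids:
            a, b = toy.reaction(rid), back.reaction(rid)
            assert a.lower_bound == b.lower_bound
            assert a.upper_bound == b.upper_bound
            assert a.stoichiometry == b.stoichiometry
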