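import json

import pytest

from crossfeed.model_core import (
    MetaboliteRef,
    MetabolicModel,
    ModelValidationError,
    NamespaceError,
    Reaction,
    harmonize,
    read_model,
    write_model,
)
from crossfeed.toyforge import ACSP_SPEC, FERM_SPEC, make_organism, make_suite


def _models_equal(a: MetabolicModel, b: MetabolicModel) -> bool:
    if a.model_id != b.model_id:
        return False
    if [(m.id, m.external) for m in a.metabolites] != [
        (m.id, m.external) for m in b.metabolites
    ]:
        return False
    if a.biomass_reaction_id != b.biomass_reaction_id:
        return False
    if a.atp_maintenance_reaction_id != b.atp_maintenance_reaction_id:
        return False
    for ra, rb in zip(a.reactions, b.reactions):
        if (ra.id, ra.lower_bound, ra.upper_bound, ra.is_exchange) != (
            rb.id,
            rb.lower_bound,
            rb.upper_bound,
            rb.is_exchange,
        ):
            return False
        if dict(ra.stoich) != dict(rb.stoich):
            return False
    return True


class TestToyJsonIO:
    def test_ferm_shape(self, ferm):
        assert len(ferm.exchange_reactions) == 6
        assert ferm.biomass_reaction_id == "BIOMASS"

    def test_round_trip(self, ferm, tmp_path):
        path = write_model(ferm, tmp_path / "ferm.json")
        again = read_model(path, format="toy_json")
        assert _models_equal(ferm, again)

    def test_round_trip_random_suite(self, tmp_path):
        models, _, _ = make_suite(4, 5, seed=11)
        for model in models:
            path = write_model(model, tmp_path / f"{model.model_id}.json")
            assert _models_equal(model, read_model(path))

    def test_missing_biomass_rejected(self, tmp_path):
        doc = {
            "id": "bad",
            "metabolites": [{"id": "x_e", "external": True}],
            "reactions": [{"id": "EX_x_e", "stoich": {"x_e": -1.0}, "lb": -10, "ub": 10}],
        }
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelValidationError, match="no biomass"):
            read_model(path)

    def test_parse_failure(self, tmp_path):
        path = tmp_path / "junk.json"
        path.write_text("{not json")
        with pytest.raises(ModelValidationError, match="parse"):
            read_model(path)

    def test_exchange_autodetected(self, tmp_path):
        doc = {
            "id": "auto",
            "metabolites": [
                {"id": "x_e", "external": True},
                {"id": "x_c", "external": False},
            ],
            "reactions": [
                {"id": "EX_x_e", "stoich": {"x_e": -1.0}, "lb": -10, "ub": 10},
                {"id": "t_x", "stoich": {"x_e": -1.0, "x_c": 1.0}, "lb": -10, "ub": 10},
                {"id": "BIOMASS", "stoich": {"x_c": -1.0}, "lb": 0, "ub": 10},
            ],
            "biomass": "BIOMASS",
        }
        path = tmp_path / "auto.json"
        path.write_text(json.dumps(doc))
        model = read_model(path)
        assert [r.id for r in model.exchange_reactions] == ["EX_x_e"]


class TestSbmlIO:
    @pytest.mark.parametrize("spec", [FERM_SPEC, ACSP_SPEC], ids=lambda s: s.organism_id)
    def test_round_trip(self, spec, tmp_path):
        model = make_organism(spec)
        path = write_model(model, tmp_path / f"{spec.organism_id}.xml", format="sbml")
        again = read_model(path, format="sbml")
        assert _models_equal(model, again)

    def test_cross_format(self, ferm, tmp_path):
        sbml = write_model(ferm, tmp_path / "ferm.xml", format="sbml")
        via_sbml = read_model(sbml, format="sbml")
        jsonp = write_model(via_sbml, tmp_path / "ferm.json", format="toy_json")
        assert _models_equal(ferm, read_model(jsonp))


class TestValidation:
    def test_zero_reactions(self):
        with pytest.raises(ModelValidationError, match="no reactions"):
            MetabolicModel(
                model_id="empty",
                metabolites=[],
                reactions=[],
                biomass_reaction_id="BIOMASS",
            )

    def test_undeclared_metabolite(self):
        with pytest.raises(ModelValidationError, match="undeclared"):
            MetabolicModel(
                model_id="m",
                metabolites=[MetaboliteRef("a_c")],
                reactions=[Reaction("r", {"b_c": 1.0}, 0, 10)],
                biomass_reaction_id="r",
            )

    def test_inverted_bounds(self):
        with pytest.raises(ModelValidationError, match="bound"):
            MetabolicModel(
                model_id="m",
                metabolites=[MetaboliteRef("a_c")],
                reactions=[Reaction("r", {"a_c": 1.0}, 5, -5)],
                biomass_reaction_id="r",
            )

    def test_exchange_convention_enforced(self):
        # coefficient +1 on the external metabolite violates the convention
        with pytest.raises(ModelValidationError, match="coefficient -1"):
            MetabolicModel(
                model_id="m",
                metabolites=[MetaboliteRef("x_e", external=True)],
                reactions=[
                    Reaction("EX_x_e", {"x_e": 1.0}, -10, 10, is_exchange=True),
                    Reaction("sink", {"x_e": -1.0}, 0, 10),
                ],
                biomass_reaction_id="sink",
            )

    def test_write_requires_valid_model(self, ferm, tmp_path):
        ferm.reactions = []
        with pytest.raises(ModelValidationError):
            write_model(ferm, tmp_path / "x.json")


class TestHarmonize:
    def _tiny(self, model_id, ext_id):
        return MetabolicModel(
            model_id=model_id,
            metabolites=[
                MetaboliteRef(ext_id, external=True),
                MetaboliteRef("x_c"),
            ],
            reactions=[
                Reaction(f"EX_{ext_id}", {ext_id: -1.0}, -10, 10, is_exchange=True),
                Reaction("t", {ext_id: -1.0, "x_c": 1.0}, -10, 10),
                Reaction("BIOMASS", {"x_c": -1.0}, 0, 10),
            ],
            biomass_reaction_id="BIOMASS",
        )

    def test_shared_canonical_id(self):
        a = self._tiny("A", "glc__D_e")
        b = self._tiny("B", "glc__D_e")
        out = harmonize([a, b], {"glc__D_e": "glc_e"})
        for model in out:
            assert model.exchange_reactions[0].exchanged_metabolite == "glc_e"
        shared = set(out[0].external_metabolites) & set(out[1].external_metabolites)
        assert shared == {"glc_e"}

    def test_strict_unmapped_errors(self):
        model = self._tiny("A", "ac_e")
        with pytest.raises(NamespaceError, match="ac_e"):
            harmonize([model], {}, strict=True)

    def test_nonstrict_passthrough(self, caplog):
        model = self._tiny("A", "ac_e")
        (out,) = harmonize([model], {}, strict=False)
        assert out.external_metabolites == ["ac_e"]

    def test_duplicate_canonical_rejected(self, ferm):
        collapse = {m: "same_e" for m in ferm.external_metabolites}
        with pytest.raises(NamespaceError, match="duplicate canonical"):
            harmonize([ferm], collapse)
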