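"""Model construction, validation, JSON/SBML I/O, and bound edits."""

import json
import math

import pytest

from rubiscoflux.model import (
    MetabolicModel,
    Metabolite,
    ModelParseError,
    ModelValidationError,
    Reaction,
    apply_knockouts,
    load_model,
    set_carbon_source,
    write_model,
)

MINIMAL_DOC = json.dumps(
    {
        "metabolites": [{"id": "A", "name": "met A", "compartment": "e"}],
        "reactions": [
            {
                "id": "EX_A",
                "stoichiometry": {"A": -1},
                "lower_bound": -10,
                "upper_bound": 1000,
                "is_exchange": True,
            }
        ],
        "objective": "EX_A",
    }
)


class TestValidation:
    def test_empty_metabolite_id_rejected(self):
        with pytest.raises(ModelValidationError):
            Metabolite("")

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ModelValidationError, match="lower_bound"):
            Reaction("r", {"A": -1}, 5.0, 1.0)

    def test_empty_stoichiometry_rejected(self):
        with pytest.raises(ModelValidationError, match="stoichiometry"):
            Reaction("r", {})

    def test_exchange_must_touch_one_metabolite(self):
        with pytest.raises(ModelValidationError, match="exactly one"):
            Reaction("EX_bad", {"A": -1, "B": 1}, is_exchange=True)

    def test_unknown_metabolite_reference_rejected(self):
        with pytest.raises(ModelValidationError, match="unknown metabolites"):
            MetabolicModel(
                (Metabolite("A"),),
                (Reaction("r", {"A": -1, "ghost": 1}),),
                "r",
            )

    def test_unknown_objective_rejected(self):
        with pytest.raises(ModelValidationError, match="objective"):
            MetabolicModel(
                (Metabolite("A"),), (Reaction("EX_A", {"A": -1}, is_exchange=True),),
                "nope",
            )


class TestJsonIO:
    def test_minimal_document(self):
        model = load_model(MINIMAL_DOC)
        assert len(model.reactions) == 1
        assert model.reaction("EX_A").is_exchange

    def test_round_trip_identity(self):
        model = load_model(MINIMAL_DOC)
        text = write_model(model)
        assert load_model(text) == model

    def test_serialization_deterministic(self, full_toy):
        assert write_model(full_toy) == write_model(full_toy)

    def test_toy_fixture_round_trips(self, full_toy):
        assert len(full_toy.reactions) == 9
        reloaded = load_model(write_model(full_toy))
        assert reloaded.reaction_ids == tuple(sorted(full_toy.reaction_ids))
        for rid in full_toy.reaction_ids:
            assert reloaded.reaction(rid).stoichiometry == (
                full_toy.reaction(rid).stoichiometry
            )

    def test_malformed_document_names_problem(self):
        with pytest.raises(ModelParseError, match="top-level"):
            load_model('{"metabolites": []}')
        with pytest.raises(ModelParseError, match="invalid JSON"):
            load_model("{not json\n")

    def test_omitted_bounds_get_irreversible_defaults(self):
        doc = json.dumps(
            {
                "metabolites": [{"id": "A"}],
                "reactions": [{"id": "EX_A", "stoichiometry": {"A": -1},
                               "is_exchange": True}],
                "objective": "EX_A",
            }
        )
        rxn = load_model(doc).reaction("EX_A")
        assert (rxn.lower_bound, rxn.upper_bound) == (0.0, 1000.0)

    def test_null_bounds_mean_unbounded(self):
        model = load_model(MINIMAL_DOC)
        rxn = model.reaction("EX_A").with_bounds(-math.inf, math.inf)
        reloaded = load_model(write_model(model.with_reaction(rxn)))
        assert reloaded.reaction("EX_A").lower_bound == -math.inf


SBML_DOC = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
      xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2"
      level="3" version="1" fbc:required="false">
  <model id="mini" fbc:strict="true">
    <listOfCompartments>
      <compartment id="c" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="c" constant="false"
               hasOnlySubstanceUnits="false" boundaryCondition="false"/>
      <species id="B" compartment="c" constant="false"
               hasOnlySubstanceUnits="false" boundaryCondition="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="lb_ex" value="-10" constant="true"/>
      <parameter id="zero" value="0" constant="true"/>
      <parameter id="ub" value="1000" constant="true"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="EX_A" reversible="true" fast="false"
                fbc:lowerFluxBound="lb_ex" fbc:upperFluxBound="ub">
        <listOfReactants>
          <speciesReference species="A" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
      <reaction id="T1" reversible="false" fast="false"
                fbc:lowerFluxBound="zero" fbc:upperFluxBound="ub">
        <listOfReactants>
          <speciesReference species="A" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="B" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="EX_B" reversible="false" fast="false"
                fbc:lowerFluxBound="zero" fbc:upperFluxBound="ub">
        <listOfReactants>
          <speciesReference species="B" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
    </listOfReactions>
    <fbc:listOfObjectives fbc:activeObjective="obj">
      <fbc:objective fbc:id="obj" fbc:type="maximize">
        <fbc:listOfFluxObjectives>
          <fbc:fluxObjective fbc:reaction="EX_B" fbc:coefficient="1"/>
        </fbc:listOfFluxObjectives>
      </fbc:objective>
    </fbc:listOfObjectives>
  </model>
</sbml>
"""


class TestSbmlImport:
    def test_species_reactions_bounds_objective(self):
        model = load_model(SBML_DOC, format="sbml")
        assert {m.id for m in model.metabolites} == {"A", "B"}
        assert model.objective_id == "EX_B"
        ex = model.reaction("EX_A")
        assert ex.is_exchange and ex.lower_bound == -10
        assert model.reaction("T1").stoichiometry == {"A": -1.0, "B": 1.0}

    def test_sbml_fba_agrees_with_json_route(self):
        from rubiscoflux.fba import fba

        model = load_model(SBML_DOC, format="sbml")
        assert fba(model).objective_value == pytest.approx(10.0)

    def test_garbage_rejected(self):
        with pytest.raises(ModelParseError):
            load_model("<sbml>nope", format="sbml")


class TestSetCarbonSource:
    def test_direct_bound_set(self, full_toy):
        out = set_carbon_source(full_toy, "EX_glyc", 10.0)
        assert out.reaction("EX_glyc").lower_bound == -10.0
        assert math.isinf(out.reaction("EX_glyc").upper_bound)

    def test_exclusivity(self):
        mets = (Metabolite("glc", compartment="e"), Metabolite("glyc", compartment="e"),
                Metabolite("co2", compartment="e"))
        rxns = (
            Reaction("EX_glc", {"glc": -1}, -5, 1000, is_exchange=True),
            Reaction("EX_glyc", {"glyc": -1}, -5, 1000, is_exchange=True),
            Reaction("EX_co2", {"co2": -1}, -1000, 1000, is_exchange=True),
        )
        model = MetabolicModel(mets, rxns, "EX_glc")
        glyc_first = set_carbon_source(model, "EX_glyc", 10.0)
        then_glc = set_carbon_source(glyc_first, "EX_glc", 10.0)
        assert then_glc.reaction("EX_glyc").lower_bound == 0.0
        assert then_glc.reaction("EX_glc").lower_bound == -10.0
        # inorganic CO2 exchange is never closed
        assert then_glc.reaction("EX_co2").lower_bound == -1000.0

    def test_nine_sources_yield_nine_distinct_configurations(self):
        sources = ["glc", "fru", "glcn", "rib", "succ", "xyl", "glyc3",
                   "ac", "glyc"]
        mets = tuple(Metabolite(s, compartment="e") for s in sources)
        rxns = tuple(
            Reaction(f"EX_{s}", {s: -1}, -10, 1000, is_exchange=True)
            for s in sources
        )
        model = MetabolicModel(mets, rxns, "EX_glc")
        configured = [set_carbon_source(model, f"EX_{s}", 10.0) for s in sources]
        assert len(configured) == 9
        for s, m in zip(sources, configured):
            open_uptakes = {r.id for r in m.exchanges if r.lower_bound < 0}
            assert open_uptakes == {f"EX_{s}"}

    def test_original_model_untouched(self, full_toy):
        before = write_model(full_toy)
        set_carbon_source(full_toy, "EX_glyc", 3.0)
        assert write_model(full_toy) == before

    def test_errors(self, full_toy):
        with pytest.raises(KeyError):
            set_carbon_source(full_toy, "EX_ghost", 10.0)
        with pytest.raises(ValueError, match="not an exchange"):
            set_carbon_source(full_toy, "T5_rpi", 10.0)


class TestApplyKnockouts:
    def test_empty_set_is_identity(self, full_toy):
        assert apply_knockouts(full_toy, set()) == full_toy

    def test_bounds_zeroed(self, full_toy):
        out = apply_knockouts(full_toy, {"T5_rpi"})
        rxn = out.reaction("T5_rpi")
        assert (rxn.lower_bound, rxn.upper_bound) == (0.0, 0.0)
        # original untouched
        assert full_toy.reaction("T5_rpi").upper_bound > 0

    def test_unknown_id_raises(self, full_toy):
        with pytest.raises(KeyError, match="ghost"):
            apply_knockouts(full_toy, {"ghost"})
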