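"""Model reading, writing, validation and flux-table output."""

import json

import pytest

from poflux import (
    ConfigurationError,
    MetabolicModel,
    Metabolite,
    ModelIOError,
    Reaction,
    build_core_fixture,
    fixture_role_map,
    models_equal,
    read_model,
    validate_model,
    write_flux_table,
    write_model_json,
)
from poflux.io import FLUX_TABLE_COLUMNS
from poflux.scan import POGrid, ScanRecord, ScanResult, ScanScenario

MINIMAL_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
      xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2"
      level="3" version="1" fbc:required="false">
  <model id="mini" fbc:strict="true">
    <listOfCompartments>
      <compartment id="e" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="M_A_e" compartment="e" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"/>
      <species id="M_bio_e" compartment="e" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="lb_m5" value="-5" constant="true"/>
      <parameter id="zero" value="0" constant="true"/>
      <parameter id="ub_1000" value="1000" constant="true"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="R_EX_A" reversible="true" fast="false"
                fbc:lowerFluxBound="lb_m5" fbc:upperFluxBound="zero">
        <listOfReactants>
          <speciesReference species="M_A_e" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
      <reaction id="R_biomass" reversible="false" fast="false"
                fbc:lowerFluxBound="zero" fbc:upperFluxBound="ub_1000">
        <listOfReactants>
          <speciesReference species="M_A_e" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="M_bio_e" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
    </listOfReactions>
    <fbc:listOfObjectives fbc:activeObjective="obj">
      <fbc:objective fbc:id="obj" fbc:type="maximize">
        <fbc:listOfFluxObjectives>
          <fbc:fluxObjective fbc:reaction="R_biomass" fbc:coefficient="1"/>
        </fbc:listOfFluxObjectives>
      </fbc:objective>
    </fbc:listOfObjectives>
  </model>
</sbml>
"""


class TestReadModel:
    def test_minimal_sbml_document(self, tmp_path):
        path = tmp_path / "mini.xml"
        path.write_text(MINIMAL_SBML)
        model = read_model(str(path))
        assert set(model.reactions) == {"EX_A", "biomass"}
        assert model.objective_id == "biomass"
        assert model.reactions["EX_A"].lower_bound == -5.0
        assert model.reactions["biomass"].stoich == {"A_e": -1.0, "bio_e": 1.0}

    def test_sbml_level2_rejected(self, tmp_path):
        doc = MINIMAL_SBML.replace('level="3"', 'level="2"')
        doc = doc.replace("level3", "level2").replace(' fbc:required="false"', "")
        path = tmp_path / "l2.xml"
        path.write_text(doc)
        with pytest.raises((ConfigurationError, ModelIOError)):
            read_model(str(path))

    def test_missing_file(self, tmp_path):
        with pytest.raises(ModelIOError, match="not found"):
            read_model(str(tmp_path / "nope.xml"))

    def test_unknown_format(self, tmp_path):
        path = tmp_path / "model.txt"
        path.write_text("{}")
        with pytest.raises(ConfigurationError):
            read_model(str(path))
        with pytest.raises(ConfigurationError):
            read_model(str(path), fmt="weird")

    def test_json_without_objective_rejected(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text(json.dumps({
            "metabolites": [{"id": "A_e"}],
            "reactions": [{"id": "EX_A", "metabolites": {"A_e": -1}}],
        }))
        with pytest.raises(ConfigurationError, match="objective"):
            read_model(str(path))

    def test_json_bounds_default_to_1000(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text(json.dumps({
            "metabolites": [{"id": "A_e"}],
            "reactions": [{"id": "EX_A", "metabolites": {"A_e": -1},
                           "objective_coefficient": 1}],
        }))
        model = read_model(str(path))
        assert model.reactions["EX_A"].lower_bound == -1000.0
        assert model.reactions["EX_A"].upper_bound == 1000.0

    def test_bracket_compartment_style_normalized(self, tmp_path):
        path = tmp_path / "m.json"
        path.write_text(json.dumps({
            "metabolites": [{"id": "h[c]"}, {"id": "h[p]"}],
            "reactions": [{"id": "PUMP", "metabolites": {"h[c]": -1, "h[p]": 1},
                           "objective_coefficient": 1}],
        }))
        model = read_model(str(path))
        assert set(model.metabolites) == {"h_c", "h_p"}
        assert model.reactions["PUMP"].stoich == {"h_c": -1.0, "h_p": 1.0}


class TestRoundTrip:
    def test_fixture_json_round_trip_is_identity(self, tmp_path):
        model = build_core_fixture()
        path = tmp_path / "fixture.json"
        write_model_json(model, str(path))
        back = read_model(str(path))
        assert models_equal(model, back)

    def test_double_round_trip(self, tmp_path):
        model = build_core_fixture()
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        write_model_json(model, str(p1))
        write_model_json(read_model(str(p1)), str(p2))
        assert p1.read_text() == p2.read_text()


class TestValidateModel:
    def test_fixture_roles_resolve(self):
        report = validate_model(build_core_fixture(), fixture_role_map())
        assert report.missing_mandatory == []
        # menaquinol/formate roles are absent-optional in the core network
        assert report.role_status["cytochrome_bd_menaquinol"] == {}
        assert report.role_status["formate_dehydrogenase"] == {}
        assert all(v is not None for v in report.exchange_status.values())

    def test_empty_model_everything_missing(self):
        report = validate_model(MetabolicModel(), fixture_role_map())
        assert set(report.missing_mandatory) == {
            "nadh_dehydrogenase_translocating", "cytochrome_bo",
            "cytochrome_bd_ubiquinol",
        }
        assert all(v is None for v in report.exchange_status.values())

    def test_validation_is_pure(self):
        model = build_core_fixture()
        before = model.copy()
        validate_model(model, fixture_role_map())
        assert models_equal(model, before)


def _toy_result(label, pos, status="optimal"):
    scen = ScanScenario(label, q_glc=-11.0, q_o2=-8.0)
    res = ScanResult(scenario=scen, grid=POGrid())
    for po in pos:
        if status == "optimal":
            res.records.append(ScanRecord(
                po=po, status="optimal", growth_rate=0.5, q_glc=-11.0,
                q_o2=-8.0, q_ac=1.0, q_co2=2.0, bo_flux=3.0, bd_flux=0.0))
        else:
            res.records.append(ScanRecord(po=po, status=status))
    return res


class TestFluxTable:
    def test_row_count_two_scenarios_three_points(self, tmp_path):
        results = [_toy_result("a", [1, 2, 3]), _toy_result("b", [1, 2, 3])]
        path = tmp_path / "t.tsv"
        write_flux_table(results, str(path))
        lines = path.read_text().splitlines()
        assert len(lines) == 1 + 6
        assert lines[0].split("\t") == list(FLUX_TABLE_COLUMNS)

    def test_infeasible_row_kept_with_empty_cells(self, tmp_path):
        res = _toy_result("a", [1.0], status="infeasible")
        path = tmp_path / "t.tsv"
        write_flux_table(res, str(path))
        row = path.read_text().splitlines()[1].split("\t")
        assert row[-1] == "infeasible"
        assert row[2:9] == [""] * 7

    def test_empty_result_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_flux_table([], str(tmp_path / "t.tsv"))
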