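"""Data model, validation, serialization and stoichiometric matrix."""

import json

import pytest

from holoflux.netcore import (MetabolicModel, Metabolite, ModelFormatError,
                              Reaction, build_stoichiometric_matrix,
                              export_sbml, import_sbml, load_model,
                              parse_formula, save_model, validate_model)

from conftest import make_chain_model


def minimal_model_dict():
    return {
        "organism_id": "mini",
        "metabolites": [
            {"id": "x_e", "name": "x", "compartment": "extracellular",
             "elemental_formula": None, "charge": None, "molar_mass": 10.0},
        ],
        "reactions": [
            {"id": "EX_x", "name": "", "stoichiometry": {"x_e": -1.0},
             "lower_bound": -10.0, "upper_bound": 10.0, "kind": "exchange",
             "pathway_tag": "", "evidence": ""},
            {"id": "BIO", "name": "", "stoichiometry": {"x_e": -1.0},
             "lower_bound": 0.0, "upper_bound": 10.0, "kind": "biomass",
             "pathway_tag": "", "evidence": ""},
        ],
        "biomass_reaction_id": "BIO",
        "biomass_composition": {"x_e": 1.0},
    }


class TestLoadSave:
    def test_minimal_model_loads_with_two_reactions(self, tmp_path):
        path = tmp_path / "mini.json"
        path.write_text(json.dumps(minimal_model_dict()))
        model = load_model(path)
        assert len(model.reactions) == 2
        assert validate_model(model).valid

    @pytest.mark.parametrize("dialect", ["native-json", "native-tsv"])
    def test_round_trip_is_identity(self, autotroph, tmp_path, dialect):
        suffix = "json" if dialect == "native-json" else "tsv"
        path = tmp_path / f"model.{suffix}"
        save_model(autotroph, path, dialect)
        back = load_model(path, dialect)
        assert back.to_dict() == autotroph.to_dict()

    def test_json_round_trip_bit_identical(self, heterotroph, tmp_path):
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_model(heterotroph, p1)
        save_model(load_model(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_bad_biomass_fraction_rejected(self, tmp_path):
        doc = minimal_model_dict()
        doc["biomass_composition"] = {"x_e": 0.9}
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError, match="sum to 0.9"):
            load_model(path)

    def test_duplicate_ids_rejected(self, tmp_path):
        doc = minimal_model_dict()
        doc["metabolites"].append(doc["metabolites"][0])
        path = tmp_path / "dup.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError, match="duplicate"):
            load_model(path)

    def test_parse_error_names_line(self, tmp_path):
        path = tmp_path / "broken.json"
        path.write_text('{"organism_id": "x",\n  broken')
        with pytest.raises(ModelFormatError, match="line"):
            load_model(path)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            load_model(tmp_path / "nope.json")


class TestValidation:
    def test_packaged_models_are_valid(self, autotroph, heterotroph):
        assert validate_model(autotroph).violations == []
        assert validate_model(heterotroph).violations == []

    def test_exchange_touching_two_metabolites_flagged(self, chain_model):
        bad = chain_model.copy()
        bad.reactions_by_id["EX_A"].stoichiometry["A"] = 1.0
        report = validate_model(bad)
        assert any("EX_A" in v for v in report.violations)

    def test_elemental_imbalance_flagged(self):
        model = MetabolicModel(
            "imb",
            [Metabolite("a", compartment="cytosol", elemental_formula="CH4"),
             Metabolite("b", compartment="cytosol", elemental_formula="CO2")],
            [Reaction("R", stoichiometry={"a": -1.0, "b": 1.0}, kind="internal"),
             Reaction("BIO", stoichiometry={"b": -1.0}, kind="biomass")],
            "BIO", {})
        report = validate_model(model)
        assert any("R" in v and "imbalance" in v for v in report.violations)

    def test_single_coefficient_mutation_flags_exactly_that_reaction(self, heterotroph):
        # TPA is fully specified and balanced; perturbing one coefficient
        # must flag it and nothing else
        clean = {v for v in validate_model(heterotroph).violations}
        mutant = heterotroph.copy()
        mutant.reactions_by_id["TPA"].stoichiometry["glu_c"] = 2.0
        flagged = [v for v in validate_model(mutant).violations if v not in clean]
        assert len(flagged) == 1 and "TPA" in flagged[0]

    def test_lumped_reactions_listed_unchecked(self, autotroph):
        report = validate_model(autotroph)
        assert "CFIX" in report.unchecked

    def test_formula_parser(self):
        assert parse_formula("C2H7NO3S") == {"C": 2, "H": 7, "N": 1, "O": 3, "S": 1}
        with pytest.raises(ValueError):
            parse_formula("2CH")


class TestStoichiometricMatrix:
    def test_chain_matrix_hand_checked(self, chain_model):
        mat = build_stoichiometric_matrix(chain_model)
        assert mat.shape == (2, 4)  # internal rows A, B only
        assert list(mat.columns) == ["EX_A", "T_A", "R1", "BIOMASS"]
        assert mat["EX_A"].tolist() == [0.0, 0.0]   # touches only A_e
        assert mat["T_A"].tolist() == [1.0, 0.0]
        assert mat["R1"].tolist() == [-1.0, 1.0]
        assert mat["BIOMASS"].tolist() == [0.0, -1.0]

    def test_packaged_models_have_no_orphan_rows(self, autotroph, heterotroph):
        for model in (autotroph, heterotroph):
            mat = build_stoichiometric_matrix(model)
            assert not (mat == 0).all(axis=1).any()

    def test_empty_model(self):
        mat = build_stoichiometric_matrix(MetabolicModel("void"))
        assert mat.shape == (0, 0)

    def test_invalid_model_rejected(self, chain_model):
        bad = chain_model.copy()
        bad.biomass_reaction_id = "nope"
        with pytest.raises(ValueError, match="invalid model"):
            build_stoichiometric_matrix(bad)


class TestSBML:
    def test_minimal_model_species_and_reactions(self, tmp_path):
        model = MetabolicModel.from_dict(minimal_model_dict())
        path = tmp_path / "mini.xml"
        export_sbml(model, path)
        back = import_sbml(path)
        assert len(back.metabolites) == 1
        assert len(back.reactions) == 2

    @pytest.mark.parametrize("builder", ["autotroph", "heterotroph"])
    def test_round_trip_preserves_stoichiometry_and_bounds(
            self, builder, autotroph, heterotroph, tmp_path):
        model = {"autotroph": autotroph, "heterotroph": heterotroph}[builder]
        path = tmp_path / f"{builder}.xml"
        export_sbml(model, path)
        back = import_sbml(path)
        orig = {r.id: r for r in model.reactions}
        assert set(r.id for r in back.reactions) == set(orig)
        for r in back.reactions:
            assert r.stoichiometry == orig[r.id].stoichiometry
            assert r.lower_bound == orig[r.id].lower_bound
            assert r.upper_bound == orig[r.id].upper_bound
            assert r.kind == orig[r.id].kind
        assert back.biomass_reaction_id == model.biomass_reaction_id

    def test_unicode_names_round_trip(self, tmp_path):
        model = make_chain_model()
        model.metabolites[1].name = "α-ketoglutaräte"
        path = tmp_path / "uni.xml"
        export_sbml(model, path)
        back = import_sbml(path)
        assert back.metabolites_by_id["A"].name == "α-ketoglutaräte"
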