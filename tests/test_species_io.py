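"""Species/TS schema validation, unit normalization and round-trips."""

import json
import logging

import pytest
from pydantic import ValidationError

from cdftkit.species_io import (AtomSite, FormingBond, OrbitalEnergies,
                                RecordValidationError, SchemaError,
                                SpeciesRecord, TSRecord, check_fukui_sums,
                                load_species, load_ts, write_species,
                                write_species_csv, write_ts)
from cdftkit.synthetic_data import SynthConfig, make_species, make_ts_set


def make_record(rid="sp", homo=-6.0, lumo=-2.0, atoms=(), **kw):
    return SpeciesRecord(id=rid,
                         orbitals=OrbitalEnergies(e_homo=homo, e_lumo=lumo),
                         atoms=list(atoms), **kw)


class TestOrbitalEnergies:
    def test_hartree_input_normalized_to_ev(self):
        orb = OrbitalEnergies.from_values(-0.21122, -0.05, units="hartree")
        assert orb.e_homo == pytest.approx(-5.7476, abs=1e-3)
        assert orb.source_units == "hartree"

    def test_ev_input_stored_unchanged(self):
        orb = OrbitalEnergies.from_values(-5.747, -1.973)
        assert (orb.e_homo, orb.e_lumo) == (-5.747, -1.973)

    def test_homo_above_lumo_rejected(self):
        with pytest.raises(ValidationError, match="strictly below"):
            OrbitalEnergies(e_homo=-1.0, e_lumo=-2.0)


class TestSpeciesValidation:
    def test_empty_id_rejected(self):
        with pytest.raises(ValidationError):
            make_record(rid="")

    def test_duplicate_atom_indices_rejected(self):
        atoms = [AtomSite(index=1, element="C"), AtomSite(index=1, element="N")]
        with pytest.raises(ValidationError, match="duplicate"):
            make_record(atoms=atoms)

    def test_fukui_sum_violation_flags_partial_site(self, caplog):
        atoms = [AtomSite(index=1, element="C", p_neutral=4.0,
                          p_anion=4.3, p_cation=3.9)]
        rec = make_record(atoms=atoms)
        with caplog.at_level(logging.WARNING):
            check_fukui_sums(rec)
        assert rec.partial_site
        assert "partial-site" in caplog.text

    def test_fukui_sum_violation_strict_raises(self):
        atoms = [AtomSite(index=1, element="C", p_neutral=4.0,
                          p_anion=4.3, p_cation=3.9)]
        with pytest.raises(RecordValidationError, match="fukui-sum"):
            check_fukui_sums(make_record(atoms=atoms), strict=True)

    def test_sum_rule_passes_within_tolerance(self):
        atoms = [AtomSite(index=1, element="C", p_neutral=4.0,
                          p_anion=4.99, p_cation=3.01)]
        rec = check_fukui_sums(make_record(atoms=atoms))
        assert not rec.partial_site


class TestSpeciesFiles:
    def test_json_round_trip_is_identity(self, tmp_path):
        records = make_species(SynthConfig(seed=3, n_species=4, n_atoms=3))
        path = write_species(records, tmp_path / "species.json")
        reloaded = load_species(path)
        assert [r.id for r in reloaded] == [r.id for r in records]
        for a, b in zip(records, reloaded):
            assert b.orbitals.e_homo == pytest.approx(
                a.orbitals.e_homo, abs=1e-12)
            for x, y in zip(a.atoms, b.atoms):
                assert y.p_anion == pytest.approx(x.p_anion, abs=1e-12)
                assert y.asd_cation == pytest.approx(x.asd_cation, abs=1e-12)

    def test_csv_round_trip_is_identity(self, tmp_path):
        records = make_species(SynthConfig(seed=5, n_species=2, n_atoms=4))
        path = write_species_csv(records, tmp_path / "species.csv")
        reloaded = load_species(path)
        for a, b in zip(records, reloaded):
            assert b.id == a.id and len(b.atoms) == len(a.atoms)
            for x, y in zip(a.atoms, b.atoms):
                assert y.p_cation == pytest.approx(x.p_cation, abs=1e-9)

    def test_empty_list_round_trips(self, tmp_path):
        path = write_species([], tmp_path / "empty.json")
        assert load_species(path) == []

    def test_loading_ev_file_is_idempotent(self, tmp_path):
        records = make_species(SynthConfig(seed=1, n_species=2, n_atoms=2))
        p1 = write_species(records, tmp_path / "a.json")
        p2 = write_species(load_species(p1), tmp_path / "b.json")
        assert (tmp_path / "a.json").read_text() == \
            (tmp_path / "b.json").read_text()

    def test_units_override_converts(self, tmp_path):
        path = tmp_path / "h.json"
        path.write_text(json.dumps([{
            "id": "x", "orbitals": {"homo": -0.21122, "lumo": -0.05}}]))
        (rec,) = load_species(path, units_override="hartree")
        assert rec.orbitals.e_homo == pytest.approx(-5.7476, abs=1e-3)

    def test_charges_convention_gives_same_fukui(self, tmp_path):
        # f+ = q(N) - q(N+1) with charges must equal p(N+1) - p(N) with
        # populations; a file of q = -p loaded with charges=True matches.
        from cdftkit.local_indices import fukui
        records = make_species(SynthConfig(seed=2, n_species=1, n_atoms=3))
        objs = [{
            "id": "q", "orbitals": {"homo": -6.0, "lumo": -2.0},
            "atoms": [{"index": a.index, "element": a.element,
                       "p_neutral": -a.p_neutral, "p_anion": -a.p_anion,
                       "p_cation": -a.p_cation}
                      for a in records[0].atoms]}]
        path = tmp_path / "charges.json"
        path.write_text(json.dumps(objs))
        (rec,) = load_species(path, charges=True)
        for orig, conv in zip(records[0].atoms, rec.atoms):
            assert fukui(conv) == pytest.approx(fukui(orig), abs=1e-12)

    def test_duplicate_species_id_rejected(self, tmp_path):
        path = tmp_path / "dup.json"
        obj = {"id": "x", "orbitals": {"homo": -6.0, "lumo": -2.0}}
        path.write_text(json.dumps([obj, obj]))
        with pytest.raises(RecordValidationError, match="unique-id"):
            load_species(path)

    def test_malformed_json_names_location(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("[{\n  broken\n")
        with pytest.raises(SchemaError, match="line"):
            load_species(path)

    def test_csv_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(SchemaError, match="species_id"):
            load_species(path)


MINIMAL_TS = {
    "id": "ts1",
    "atom_charges": {"1": 0.1, "2": 0.22, "3": -0.2, "4": -0.12},
    "fragment_of": {"1": "f1", "2": "f1", "3": "f2", "4": "f2"},
    "forming_bonds": [{"atoms": [1, 3], "length": 2.2},
                      {"atoms": [2, 4], "length": 2.5}],
}


class TestTSFiles:
    def test_minimal_record_loads(self, tmp_path):
        path = tmp_path / "ts.json"
        path.write_text(json.dumps([MINIMAL_TS]))
        (ts,) = load_ts(path)
        assert ts.fragment_charge("f1") == pytest.approx(0.32)

    def test_atom_missing_from_fragment_map_rejected(self, tmp_path):
        obj = dict(MINIMAL_TS, fragment_of={"1": "f1", "2": "f1", "3": "f2"})
        path = tmp_path / "ts.json"
        path.write_text(json.dumps([obj]))
        with pytest.raises(RecordValidationError, match="fragment"):
            load_ts(path)

    def test_wrong_bond_count_rejected(self, tmp_path):
        obj = dict(MINIMAL_TS)
        obj["forming_bonds"] = obj["forming_bonds"] + [
            {"atoms": [1, 4], "length": 3.0}]
        path = tmp_path / "ts.json"
        path.write_text(json.dumps([obj]))
        with pytest.raises(RecordValidationError, match="two forming bonds"):
            load_ts(path)

    def test_empty_fragment_rejected(self):
        with pytest.raises(ValidationError, match="non-empty"):
            TSRecord(id="t", atom_charges={1: 0.1, 2: -0.1},
                     fragment_of={1: "f1", 2: "f1"},
                     forming_bonds=[FormingBond(atoms=(1, 2), length=2.0),
                                    FormingBond(atoms=(1, 2), length=2.1)])

    def test_nonpositive_bond_length_rejected(self):
        with pytest.raises(ValidationError):
            FormingBond(atoms=(1, 2), length=0.0)

    def test_ts_round_trip(self, tmp_path):
        records = make_ts_set(SynthConfig(seed=4, n_ts=3))
        path = write_ts(records, tmp_path / "ts.json")
        reloaded = load_ts(path)
        for a, b in zip(records, reloaded):
            assert b.atom_charges == pytest.approx(a.atom_charges)
            assert b.thermo.G == pytest.approx(a.thermo.G, abs=1e-12)
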