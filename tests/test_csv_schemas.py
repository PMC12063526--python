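"""Parsing, validation and round-trip behaviour of the four CSV schemas."""

import pytest

from otplan import csv_schemas as cs
from otplan.fixtures import FixtureSpec, generate_fixture

from conftest import LABWARE_CSV, PARAMS_CSV, PIPETTES_CSV, STOCK_CSV


def issues_of(exc_info):
    return [(i.row, i.column, i.message) for i in exc_info.value.issues]


class TestLabwareInventory:
    def test_direct_field_mapping(self):
        recs = cs.parse_labware_inventory(
            "Name,Labware,Slot,Working Volume,Source,Mixing,Final\n"
            "plate1,corning_96_wellplate_360ul_flat,1,200,N,N,Y\n"
        )
        (r,) = recs
        assert r.name == "plate1"
        assert r.labware_def == "corning_96_wellplate_360ul_flat"
        assert r.slot == 1 and r.working_volume == 200
        assert (r.is_source, r.is_mixing, r.is_final) == (False, False, True)

    def test_tip_rack_zero_working_volume_accepted(self):
        recs = cs.parse_labware_inventory(
            "Name,Labware,Slot,Working Volume,Source,Mixing,Final\n"
            "tips,opentrons_96_tiprack_300ul,4,0,N,N,N\n"
        )
        assert recs[0].working_volume == 0

    @pytest.mark.parametrize("slot", [0, 12, -3, 99])
    def test_slot_outside_deck_rejected(self, slot):
        with pytest.raises(cs.SchemaError) as e:
            cs.parse_labware_inventory(
                "Name,Labware,Slot,Working Volume,Source,Mixing,Final\n"
                f"p,corning_96_wellplate_360ul_flat,{slot},200,N,N,Y\n"
            )
        (row, column, message), = issues_of(e)
        assert (row, column) == (2, "Slot") and "1..11" in message

    @pytest.mark.parametrize("dup_col,row3", [
        ("Name", "p1,corning_96_wellplate_360ul_flat,2,200,N,N,Y"),
        ("Slot", "p2,corning_96_wellplate_360ul_flat,1,200,N,N,Y"),
    ])
    def test_duplicate_name_or_slot_rejected(self, dup_col, row3):
        with pytest.raises(cs.SchemaError) as e:
            cs.parse_labware_inventory(
                "Name,Labware,Slot,Working Volume,Source,Mixing,Final\n"
                "p1,corning_96_wellplate_360ul_flat,1,200,N,N,Y\n" + row3 + "\n"
            )
        assert any(col == dup_col and "duplicate" in msg for _, col, msg in issues_of(e))

    @pytest.mark.parametrize("bad", ["yes", "1", "true", ""])
    def test_flag_cells_accept_only_yn(self, bad):
        with pytest.raises(cs.SchemaError):
            cs.parse_labware_inventory(
                "Name,Labware,Slot,Working Volume,Source,Mixing,Final\n"
                f"p,corning_96_wellplate_360ul_flat,1,200,{bad},N,Y\n"
            )

    @pytest.mark.parametrize("header", [
        "Name,Labware,Slot,Working Volume,Source,Mixing",              # missing column
        "Name,Labware,Slot,Working Volume,Source,Mixing,Final,Extra",  # extra column
        "Labware,Name,Slot,Working Volume,Source,Mixing,Final",        # reordered
    ])
    def test_header_must_match_exactly_seven_columns(self, header):
        with pytest.raises(cs.SchemaError):
            cs.parse_labware_inventory(header + "\np,x,1,200,N,N,Y\n")

    def test_header_case_and_whitespace_insensitive(self):
        recs = cs.parse_labware_inventory(
            " name , LABWARE ,Slot, working volume ,source,MIXING,Final\n"
            "p,x_96_wellplate,1,200,N,N,Y\n"
        )
        assert recs[0].name == "p"


class TestStockInventory:
    def test_component_fill_down(self):
        recs = cs.parse_stock_inventory(
            "Component,Sample,Well Location,Volume,Concentration,Target Volume,"
            "Speed,Transfer Volume,Dilutant,Diluent\n"
            "DNA,0,tubes:A1,100,10 ng/ul,100,,,N,N\n"
            ",1,tubes:A2,100,10 ng/ul,100,,,N,N\n"
        )
        assert [r.component for r in recs] == ["DNA", "DNA"]

    def test_first_row_blank_component_rejected(self):
        with pytest.raises(cs.SchemaError) as e:
            cs.parse_stock_inventory(
                "Component,Sample,Well Location,Volume,Concentration,Target Volume,"
                "Speed,Transfer Volume,Dilutant,Diluent\n"
                ",0,tubes:A1,100,10,100,,,N,N\n"
            )
        assert "nothing to inherit" in str(e.value)

    def test_blank_speed_and_override_become_absent(self):
        (r,) = cs.parse_stock_inventory(STOCK_CSV)[:1]
        assert r.speed is None and r.transfer_volume_override is None

    @pytest.mark.parametrize("cell,value,unit", [
        ("10 %", 10.0, "%"),
        ("10%", 10.0, "%"),
        ("250 ng/ul", 250.0, "ng/ul"),
        ("1.5 mM", 1.5, "mm"),
        ("3 uM", 3.0, "um"),
        ("2 M", 2.0, "m"),
        ("42", 42.0, ""),
    ])
    def test_concentration_unit_suffixes(self, cell, value, unit):
        (r,) = cs.parse_stock_inventory(
            "Component,Sample,Well Location,Volume,Concentration,Target Volume,"
            "Speed,Transfer Volume,Dilutant,Diluent\n"
            f"X,0,tubes:A1,100,{cell},100,,,N,N\n"
        )
        assert (r.stock_concentration, r.concentration_unit) == (value, unit)

    def test_unit_conflict_within_component_rejected(self):
        with pytest.raises(cs.SchemaError) as e:
            cs.parse_stock_inventory(
                "Component,Sample,Well Location,Volume,Concentration,Target Volume,"
                "Speed,Transfer Volume,Dilutant,Diluent\n"
                "X,0,tubes:A1,100,10 ng/ul,100,,,N,N\n"
                "X,1,tubes:A2,100,10 mM,100,,,N,N\n"
            )
        assert "conflicts" in str(e.value)

    def test_sample_index_must_strictly_increase_within_component(self):
        with pytest.raises(cs.SchemaError) as e:
            cs.parse_stock_inventory(
                "Component,Sample,Well Location,Volume,Concentration,Target Volume,"
                "Speed,Transfer Volume,Dilutant,Diluent\n"
                "X,2,tubes:A1,100,10,100,,,N,N\n"
                ",1,tubes:A2,100,10,100,,,N,N\n"
            )
        assert "strictly increasing" in str(e.value)

    def test_zero_concentration_requires_dilutant_flag(self):
        with pytest.raises(cs.SchemaError):
            cs.parse_stock_inventory(
                "Component,Sample,Well Location,Volume,Concentration,Target Volume,"
                "Speed,Transfer Volume,Dilutant,Diluent\n"
                "X,0,tubes:A1,100,0,100,,,N,N\n"
            )


class TestExperimentalParameters:
    def test_first_data_row_is_sample_zero(self):
        d = cs.parse_experimental_parameters("A,B\n1,2\n3,4\n5,6\n")
        assert d.n_samples == 3
        assert d.targets[0] == (1.0, 2.0)  # row 2 of the file is Sample 0
        assert sorted(range(d.n_samples)) == [0, 1, 2]

    def test_all_zero_row_is_valid(self):
        d = cs.parse_experimental_parameters("A,B\n0,0\n")
        assert d.targets == ((0.0, 0.0),)

    def test_non_numeric_cell_located(self):
        with pytest.raises(cs.SchemaError) as e:
            cs.parse_experimental_parameters("A,B\n1,abc\n")
        (i,) = e.value.issues
        assert (i.row, i.column) == (2, "B")

    @pytest.mark.parametrize("text", ["", "A,B\n", "A,B\n1\n"])
    def test_empty_or_ragged_rejected(self, text):
        with pytest.raises(cs.SchemaError):
            cs.parse_experimental_parameters(text)


class TestPipetteSettings:
    def test_single_pipette_column(self):
        (c,) = cs.parse_pipette_settings(
            "Pipette,P300\nMount,right\nAspirate Rate,150\nDispense Rate,300\n"
            "Tip Rack,tips300\nTrash Container,trash\n"
        )
        assert c.model == "p300_single_gen2" and c.mount == "right"
        assert (c.min_volume, c.max_volume) == (20.0, 300.0)

    def test_two_pipettes_returned_left_first(self):
        configs = cs.parse_pipette_settings(PIPETTES_CSV)
        assert [c.mount for c in configs] == ["left", "right"]

    def test_duplicate_mount_rejected(self):
        with pytest.raises(cs.SchemaError) as e:
            cs.parse_pipette_settings(
                "Pipette,P300,P20\nMount,left,left\nAspirate Rate,150,7\n"
                "Dispense Rate,300,7\nTip Rack,t3,t2\nTrash Container,tr,tr\n"
            )
        assert "duplicate mount" in str(e.value)

    def test_three_pipette_columns_rejected(self):
        with pytest.raises(cs.SchemaError) as e:
            cs.parse_pipette_settings(
                "Pipette,P300,P20,P10\nMount,left,right,left\nAspirate Rate,1,1,1\n"
                "Dispense Rate,1,1,1\nTip Rack,a,b,c\nTrash Container,t,t,t\n"
            )
        assert "at most 2" in str(e.value)

    def test_unknown_model_rejected(self):
        with pytest.raises(cs.SchemaError) as e:
            cs.parse_pipette_settings(
                "Pipette,P9000\nMount,left\nAspirate Rate,1\nDispense Rate,1\n"
                "Tip Rack,a\nTrash Container,t\n"
            )
        assert "unknown pipette model" in str(e.value)


class TestCrossFileValidation:
    def parse_all(self, labware=LABWARE_CSV, stock=STOCK_CSV, params=PARAMS_CSV,
                  pipettes=PIPETTES_CSV):
        return (
            cs.parse_labware_inventory(labware),
            cs.parse_stock_inventory(stock),
            cs.parse_experimental_parameters(params),
            cs.parse_pipette_settings(pipettes),
        )

    def test_clean_inputs_pass(self):
        report = cs.validate_cross_file(*self.parse_all())
        assert report.ok and report.errors == []

    def test_stock_rows_beyond_design_rejected(self):
        stock = STOCK_CSV + "DNA,3,tubes:B1,100,100 ng/ul,100,,,N,N\n"
        report = cs.validate_cross_file(*self.parse_all(stock=stock))
        assert any("sample index 3" in i.message for i in report.errors)

    def test_design_reagent_without_stock_named(self):
        report = cs.validate_cross_file(*self.parse_all(params="DNA,Mg2\n10,5\n"))
        assert any("Mg2" in i.message for i in report.errors)

    def test_missing_tip_rack_reference(self):
        pip = PIPETTES_CSV.replace("tips20", "tips_nope")
        report = cs.validate_cross_file(*self.parse_all(pipettes=pip))
        assert any("tips_nope" in i.message for i in report.errors)

    def test_stock_on_non_source_labware(self):
        stock = STOCK_CSV.replace("tubes:A1", "plate1:A1")
        report = cs.validate_cross_file(*self.parse_all(stock=stock))
        assert any("not flagged as Source" in i.message for i in report.errors)

    def test_predilution_without_dilutant(self):
        stock = (
            "Component,Sample,Well Location,Volume,Concentration,Target Volume,"
            "Speed,Transfer Volume,Dilutant,Diluent\n"
            "DNA,0,tubes:A1,1000,100 ng/ul,100,,,N,Y\n"
            "Mg,0,tubes:A2,1000,50 mM,100,,,N,N\n"
        )
        report = cs.validate_cross_file(*self.parse_all(stock=stock))
        assert any("no Dilutant reagent" in i.message for i in report.errors)

    def test_no_final_labware(self):
        labware = LABWARE_CSV.replace("N,N,Y", "N,N,N")
        report = cs.validate_cross_file(*self.parse_all(labware=labware))
        assert any("Final" in i.column for i in report.errors)

    def test_findings_carry_resolvable_locations(self):
        stock = STOCK_CSV + "DNA,3,tubes:B1,100,100 ng/ul,100,,,N,N\n"
        report = cs.validate_cross_file(*self.parse_all(stock=stock))
        for i in report.errors:
            assert i.file and i.row >= 0 and i.column
            assert i.row <= stock.count("\n") + 1


class TestRoundTrip:
    @pytest.mark.parametrize("seed", range(5))
    def test_fixture_files_round_trip(self, seed):
        fx = generate_fixture(FixtureSpec(seed=seed, n_samples=3, n_reagents=3,
                                          predilute=bool(seed % 2)))
        lab = cs.parse_labware_inventory(fx.labware_inventory)
        assert cs.parse_labware_inventory(cs.write_labware_inventory(lab)) == lab
        stock = cs.parse_stock_inventory(fx.stock_inventory)
        assert cs.parse_stock_inventory(cs.write_stock_inventory(stock)) == stock
        design = cs.parse_experimental_parameters(fx.experimental_parameters)
        assert cs.parse_experimental_parameters(cs.write_experimental_parameters(design)) == design
        pips = cs.parse_pipette_settings(fx.pipette_settings)
        assert cs.parse_pipette_settings(cs.write_pipette_settings(pips)) == pips

    def test_fill_down_idempotent(self):
        text = (
            "Component,Sample,Well Location,Volume,Concentration,Target Volume,"
            "Speed,Transfer Volume,Dilutant,Diluent\n"
            "DNA,0,tubes:A1,100,10 ng/ul,100,,,N,N\n"
            ",1,tubes:A2,100,10 ng/ul,100,,,N,N\n"
        )
        once = cs.parse_stock_inventory(text)
        twice = cs.parse_stock_inventory(cs.write_stock_inventory(once))
        assert once == twice

    def test_writers_use_lf_and_no_trailing_delimiter(self):
        lab = cs.parse_labware_inventory(LABWARE_CSV)
        out = cs.write_labware_inventory(lab)
        assert "\r" not in out
        assert all(not line.endswith(",") for line in out.splitlines())
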