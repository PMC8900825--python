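"""Fishing definitions, result merging and the collection sheet."""

from datetime import timedelta

import pandas as pd
import pytest

from fragflow.errors import FragflowError, FragmentNotFoundError, ReconciliationError
from fragflow.harvest import (
    build_fishing_definition,
    export_collection_sheet,
    merge_fishing_results,
    write_fishing_definition,
)
from fragflow.plates import parse_crystal_well
from fragflow.soak import DropTarget, SoakRecord

from conftest import BASE_TIME


def _soak(well, fragment_id, status="dispensed", plate="XT-1"):
    return SoakRecord(
        target=DropTarget(plate, parse_crystal_well(well)),
        fragment_id=fragment_id,
        transfer_nl=25.0,
        status=status,
        soak_start=BASE_TIME,
        soak_stop=BASE_TIME + timedelta(minutes=30) if status != "planned" else None,
    )


@pytest.fixture
def soaks():
    return [
        _soak("C3b", "F03"),
        _soak("A1a", "F01"),
        _soak("B2c", "F02"),
        _soak("D4a", "F04", status="failed"),
    ]


def test_fishing_definition_orders_by_plate_then_well(soaks):
    rows = build_fishing_definition(soaks)
    assert [r["well"] for r in rows] == ["A1a", "B2c", "C3b"]
    assert [r["fragment_id"] for r in rows] == ["F01", "F02", "F03"]


def test_fishing_definition_excludes_failed(soaks):
    rows = build_fishing_definition(soaks)
    assert all(r["fragment_id"] != "F04" for r in rows)


def test_fishing_definition_all_failed_is_error():
    with pytest.raises(FragflowError, match="no dispensed"):
        build_fishing_definition([_soak("A1a", "F01", status="failed")])


def test_fishing_definition_csv_roundtrip(tmp_path, soaks):
    rows = build_fishing_definition(soaks)
    path = write_fishing_definition(rows, tmp_path / "fish.csv")
    import csv

    with open(path, newline="") as fh:
        assert list(csv.DictReader(fh)) == rows


def _shifter(well, status, plate="XT-1", **kw):
    row = {
        "plate_barcode": plate,
        "well": well,
        "status": status,
        "timestamp": BASE_TIME.isoformat(),
        "comment": "",
    }
    row.update(kw)
    return row


def test_merge_assigns_pucks_in_order(soaks):
    shifter = [_shifter("A1a", "fished"), _shifter("B2c", "fished")]
    scans = [
        {"sequence": 1, "puck": "PK-01", "pin": 1},
        {"sequence": 2, "puck": "PK-01", "pin": 2},
    ]
    records, warnings = merge_fishing_results(soaks, shifter, scans)
    assert warnings == []
    assert [(r.puck, r.pin) for r in records] == [("PK-01", 1), ("PK-01", 2)]
    assert [r.fragment_id for r in records] == ["F01", "F02"]


def test_merge_count_mismatch_reports_both_counts(soaks):
    shifter = [
        _shifter("A1a", "fished"),
        _shifter("B2c", "fished"),
        _shifter("C3b", "fished"),
    ]
    scans = [
        {"sequence": 1, "puck": "PK-01", "pin": 1},
        {"sequence": 2, "puck": "PK-01", "pin": 2},
    ]
    with pytest.raises(ReconciliationError, match="3 vs 2"):
        merge_fishing_results(soaks, shifter, scans)


def test_merge_skipped_row_consumes_no_scan(soaks):
    """Manual-pairing oracle: with a skip between two fished rows, the
    second fished row must take scan sequence 2, not 3."""
    shifter = [
        _shifter("A1a", "fished"),
        _shifter("B2c", "skipped", comment="no crystal"),
        _shifter("C3b", "fished"),
    ]
    scans = [
        {"sequence": 1, "puck": "PK-01", "pin": 1},
        {"sequence": 2, "puck": "PK-01", "pin": 2},
    ]
    records, _ = merge_fishing_results(soaks, shifter, scans)
    by_well = {str(r.target.well): r for r in records}
    assert (by_well["A1a"].puck, by_well["A1a"].pin) == ("PK-01", 1)
    assert (by_well["C3b"].puck, by_well["C3b"].pin) == ("PK-01", 2)
    assert by_well["B2c"].puck is None and by_well["B2c"].status == "skipped"


def test_merge_is_bijective_when_counts_agree(soaks):
    shifter = [_shifter(w, "fished") for w in ("A1a", "B2c", "C3b")]
    scans = [{"sequence": k + 1, "puck": "PK-01", "pin": k + 1} for k in range(3)]
    records, _ = merge_fishing_results(soaks, shifter, scans)
    fished = [r for r in records if r.status == "fished"]
    assert len({(r.puck, r.pin) for r in fished}) == len(fished) == len(scans)


def test_merge_flags_pin_barcode_mismatch(soaks):
    shifter = [_shifter("A1a", "fished", pin_barcode="PIN-AAA")]
    scans = [{"sequence": 1, "puck": "PK-01", "pin": 1, "pin_barcode": "PIN-BBB"}]
    records, warnings = merge_fishing_results(soaks, shifter, scans)
    assert len(warnings) == 1 and "mismatch" in warnings[0]
    assert records[0].pin_barcode == "PIN-BBB"


def test_merge_unknown_well_is_error(soaks):
    shifter = [_shifter("H12c", "fished")]
    scans = [{"sequence": 1, "puck": "PK-01", "pin": 1}]
    with pytest.raises(ReconciliationError, match="unknown drop"):
        merge_fishing_results(soaks, shifter, scans)


# -- collection sheet -------------------------------------------------------


@pytest.fixture
def fished_records(soaks, five_library):
    shifter = [
        _shifter("A1a", "fished"),
        _shifter("B2c", "skipped"),
        _shifter("C3b", "fished"),
    ]
    scans = [
        {"sequence": 1, "puck": "PK-01", "pin": 2},
        {"sequence": 2, "puck": "PK-01", "pin": 1},
    ]
    records, _ = merge_fishing_results(soaks, shifter, scans)
    return records


def test_collection_sheet_contents(fished_records, five_library):
    sheet = export_collection_sheet(
        fished_records, five_library, "gopy", "model.pdb", campaign="camp1"
    )
    assert len(sheet) == 2  # skipped record omitted
    assert list(sheet["pin"]) == [1, 2]  # sorted by puck then pin
    assert sheet.loc[sheet["pin"] == 2, "sample_name"].item() == "camp1-XT-1-A1a"
    assert set(sheet["fragment_smiles"]) == {
        five_library["F01"].smiles,
        five_library["F03"].smiles,
    }


def test_collection_sheet_row_count_matches_fished(fished_records, five_library):
    sheet = export_collection_sheet(
        fished_records, five_library, "xia2dials", "m.pdb", campaign="c"
    )
    assert len(sheet) == sum(
        1 for r in fished_records if r.status == "fished" and r.puck is not None
    )


def test_collection_sheet_unknown_fragment(fished_records):
    from conftest import build_library

    tiny = build_library({"ZZZ": "CCO"})
    with pytest.raises(FragmentNotFoundError, match="F01"):
        export_collection_sheet(fished_records, tiny, "gopy", "m.pdb", campaign="c")


def test_collection_sheet_unknown_pipeline(fished_records, five_library):
    with pytest.raises(FragflowError, match="pipeline"):
        export_collection_sheet(
            fished_records, five_library, "hkl2000", "m.pdb", campaign="c"
        )


def test_collection_sheet_csv_xlsx_identical(tmp_path, fished_records, five_library):
    csv_path = tmp_path / "sheet.csv"
    xlsx_path = tmp_path / "sheet.xlsx"
    sheet = export_collection_sheet(
        fished_records,
        five_library,
        "gopy",
        "model.pdb",
        campaign="camp1",
        csv_path=csv_path,
        xlsx_path=xlsx_path,
    )
    from_csv = pd.read_csv(csv_path)
    from_xlsx = pd.read_excel(xlsx_path)
    pd.testing.assert_frame_equal(from_csv, from_xlsx)
    pd.testing.assert_frame_equal(from_csv, sheet)
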