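"""Soak planning: offsets, transfer lists, DMSO, timers, reports."""

import random
from datetime import datetime, timedelta

import pytest
from hypothesis import given, strategies as hst

from fragflow.config import CRYSTAL_PLATE, DROPLET_QUANTUM_NL
from fragflow.errors import (
    CapacityError,
    FragflowError,
    FragmentNotFoundError,
    TransferError,
)
from fragflow.plates import parse_crystal_well
from fragflow.soak import (
    DropTarget,
    SoakRecord,
    TransferList,
    build_transfer_list,
    dmso_percent,
    ingest_dispense_report,
    pixel_to_offset,
    plan_redissolve,
    soak_elapsed,
)

from conftest import BASE_TIME


CAL = {"well_centre_px": (100.0, 100.0), "mm_per_px": 0.01}


def test_pixel_at_centre_is_zero_offset():
    assert pixel_to_offset((100, 100), CAL) == (0.0, 0.0, False)


def test_pixel_to_offset_linear():
    x, y, clamped = pixel_to_offset((150, 80), CAL)
    assert (x, y) == pytest.approx((0.5, -0.2))
    assert not clamped


def test_pixel_far_outside_is_clamped_and_flagged():
    half = CRYSTAL_PLATE.drop_half_extent_mm
    x, y, clamped = pixel_to_offset((10000, -10000), CAL)
    assert clamped
    assert (x, y) == (half, -half)


def test_offset_beyond_half_extent_rejected_on_target():
    with pytest.raises(TransferError, match="half-extent"):
        DropTarget("XT-1", parse_crystal_well("A1a"), offset=(5.0, 0.0))


def test_build_transfer_list_single_row(five_library, drop_target):
    tl = build_transfer_list([(drop_target, "F01", 25.0)], five_library)
    (row,) = tl.rows
    assert row.source_barcode == "LIB-001"
    assert row.source_well == str(five_library["F01"].source_well)
    assert (row.dest_barcode, row.dest_well) == ("XTAL-001", "B2")
    assert row.transfer_nl == 25.0
    # subwell a centre offset added to the click offset
    dx, dy = CRYSTAL_PLATE.drop_centre_offsets_mm[0]
    assert (row.dest_x_offset_mm, row.dest_y_offset_mm) == (
        pytest.approx(0.3 + dx),
        pytest.approx(-0.2 + dy),
    )


def test_build_transfer_list_rejects_off_quantum_volume(five_library, drop_target):
    with pytest.raises(TransferError, match="quantum"):
        build_transfer_list([(drop_target, "F01", 26.0)], five_library)


def test_build_transfer_list_rejects_unknown_fragment(five_library, drop_target):
    with pytest.raises(FragmentNotFoundError):
        build_transfer_list([(drop_target, "NOPE", 25.0)], five_library)


def test_build_transfer_list_rejects_duplicate_drop(five_library, drop_target):
    soaks = [(drop_target, "F01", 25.0), (drop_target, "F02", 25.0)]
    with pytest.raises(TransferError, match="duplicate destination"):
        build_transfer_list(soaks, five_library)


def test_transfer_volume_conservation_random_plans(five_library):
    """Total volume drawn per source well equals quantum x droplet count,
    across many random plans (conservation, no rounding drift)."""
    rng = random.Random(42)
    drops = [
        parse_crystal_well(f"{r}{c}{d}")
        for r in "ABCDEFGH"
        for c in range(1, 13)
        for d in "abc"
    ]
    ids = five_library.ids()
    for _ in range(1000):
        n = rng.randint(1, 30)
        soaks = [
            (
                DropTarget("XT-1", well),
                rng.choice(ids),
                DROPLET_QUANTUM_NL * rng.randint(1, 40),
            )
            for well in rng.sample(drops, n)
        ]
        tl = build_transfer_list(soaks, five_library)
        assert len(tl) == n
        for (plate, well), total in tl.total_volume_per_source().items():
            droplets = total / DROPLET_QUANTUM_NL
            assert droplets == pytest.approx(round(droplets))
        expected = sum(v for _, _, v in soaks)
        assert sum(r.transfer_nl for r in tl) == pytest.approx(expected)


def test_transfer_list_csv_roundtrip(tmp_path, five_library):
    wells = [parse_crystal_well(w) for w in ("A1a", "A1b", "C7c")]
    soaks = [
        (DropTarget("XT-1", w, offset=(0.123, -0.456)), fid, 25.0)
        for w, fid in zip(wells, ("F01", "F02", "F03"))
    ]
    tl = build_transfer_list(soaks, five_library)
    path = tl.to_csv(tmp_path / "transfers.csv")
    assert TransferList.from_csv(path).rows == tl.rows


@pytest.mark.parametrize(
    "drop, transfer, expected",
    [(475.0, 25.0, 5.0), (100.0, 100.0, 50.0), (900.0, 100.0, 10.0)],
)
def test_dmso_percent(drop, transfer, expected):
    assert dmso_percent(drop, transfer) == pytest.approx(expected)


def test_dmso_percent_rejects_nonpositive():
    with pytest.raises(FragflowError):
        dmso_percent(0.0, 25.0)
    with pytest.raises(FragflowError):
        dmso_percent(500.0, -1.0)


@given(
    drop=hst.floats(1.0, 1e6),
    t1=hst.floats(0.1, 1e6),
    t2=hst.floats(0.1, 1e6),
)
def test_dmso_percent_monotone_and_bounded(drop, t1, t2):
    lo, hi = sorted((t1, t2))
    a, b = dmso_percent(drop, lo), dmso_percent(drop, hi)
    assert 0.0 < a < 100.0 and 0.0 < b < 100.0
    if hi > lo:
        assert b > a


def _record(**kw):
    target = DropTarget("XT-1", parse_crystal_well("B2a"))
    defaults = dict(target=target, fragment_id="F01", transfer_nl=25.0)
    defaults.update(kw)
    return SoakRecord(**defaults)


def test_soak_elapsed_running_timer():
    rec = _record(soak_start=BASE_TIME)
    assert soak_elapsed(rec, BASE_TIME + timedelta(minutes=45)) == 45
    # floored to whole minutes
    assert soak_elapsed(rec, BASE_TIME + timedelta(minutes=45, seconds=59)) == 45


def test_soak_elapsed_frozen_at_stop():
    rec = _record(
        soak_start=datetime(2024, 1, 15, 10, 0),
        soak_stop=datetime(2024, 1, 15, 11, 30),
        status="dispensed",
    )
    assert soak_elapsed(rec, datetime(2024, 1, 15, 12, 0)) == 90


def test_soak_elapsed_errors():
    with pytest.raises(FragflowError, match="never started"):
        soak_elapsed(_record(), BASE_TIME)
    with pytest.raises(FragflowError, match="precedes"):
        soak_elapsed(_record(soak_start=BASE_TIME), BASE_TIME - timedelta(minutes=1))


def test_ingest_dispense_report_all_ok():
    records = [
        _record(soak_start=BASE_TIME),
        SoakRecord(
            target=DropTarget("XT-1", parse_crystal_well("B3b")),
            fragment_id="F02",
            transfer_nl=25.0,
            soak_start=BASE_TIME,
        ),
    ]
    rows = [
        {"dest_barcode": "XT-1", "dest_well": "B2a", "status": "OK", "message": ""},
        {"dest_barcode": "XT-1", "dest_well": "B3b", "status": "ok", "message": ""},
    ]
    stop = BASE_TIME + timedelta(minutes=30)
    updated, discrepancies = ingest_dispense_report(records, rows, stop)
    assert discrepancies == []
    assert all(r.status == "dispensed" and r.soak_stop == stop for r in updated)


def test_ingest_dispense_report_failure_keeps_message():
    records = [_record(soak_start=BASE_TIME)]
    rows = [
        {
            "dest_barcode": "XT-1",
            "dest_well": "B2a",
            "status": "failed: no source volume",
            "message": "",
        }
    ]
    updated, _ = ingest_dispense_report(records, rows, BASE_TIME)
    assert updated[0].status == "failed"
    assert "no source volume" in updated[0].error_msg


def test_ingest_dispense_report_unplanned_row_is_discrepancy():
    records = [_record(soak_start=BASE_TIME)]
    rows = [
        {"dest_barcode": "XT-1", "dest_well": "B2a", "status": "OK", "message": ""},
        {"dest_barcode": "XT-9", "dest_well": "A1a", "status": "OK", "message": ""},
    ]
    updated, discrepancies = ingest_dispense_report(records, rows, BASE_TIME)
    assert updated[0].status == "dispensed"
    assert len(discrepancies) == 1 and discrepancies[0]["dest_barcode"] == "XT-9"


def test_plan_redissolve_row_major_fill(five_library):
    transfers, sheet = plan_redissolve(["F01", "F02", "F03"], "RD-1", five_library, 25.0)
    assert len(transfers) == 3 and len(sheet) == 3
    assert [s["well"] for s in sheet] == ["A1a", "A1b", "A1c"]
    assert all(
        s[step] == "pending" for s in sheet for step in ("dispensed", "dried", "redissolved")
    )


def test_plan_redissolve_capacity(five_library):
    too_many = [f"F{i % 5 + 1:02d}" for i in range(289)]
    with pytest.raises(CapacityError):
        plan_redissolve(too_many, "RD-1", five_library, 25.0)


def test_plan_redissolve_empty(five_library):
    transfers, sheet = plan_redissolve([], "RD-1", five_library, 25.0)
    assert len(transfers) == 0 and sheet == []
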