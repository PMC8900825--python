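"""Targeted soak planning for an acoustic liquid handler.

Selected crystallization drops (with a click-selected in-drop dispense
offset) are paired with fragments from a source plate to produce a
cherry-pick transfer list the dispenser consumes. Transfer volumes must be
exact multiples of the droplet quantum (2.5 nL by default). The destination
well in the CSV is the 96-well address; the subwell (a/b/c) is encoded by
adding its configured centre offset to the user's in-drop offset.

The module also tracks soak timing (a per-record timer, stopped when the
dispense report arrives), computes the DMSO concentration a soak imposes on
a drop, ingests dispense status reports, and plans the DMSO-free
"redissolve" variant where fragment stock is dispensed onto an empty plate,
air-dried and redissolved in crystallization buffer before crystals are
added.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from . import config
from .errors import TransferError, CapacityError, FragflowError
from .library import FragmentLibrary
from .plates import CrystalWellAddress, iter_crystal_drops, parse_crystal_well

__all__ = [
    "DropTarget",
    "SoakRecord",
    "TransferRow",
    "TransferList",
    "OffsetResult",
    "pixel_to_offset",
    "build_transfer_list",
    "dmso_percent",
    "soak_elapsed",
    "ingest_dispense_report",
    "plan_redissolve",
]


@dataclass(frozen=True)
class DropTarget:
    """A crystallization drop selected for soaking, with the dispense
    offset (mm, image convention: +x right, +y down) relative to the
    subwell centre."""

    plate_barcode: str
    well: CrystalWellAddress
    offset: tuple[float, float] = (0.0, 0.0)
    image: str | None = None
    selected_at: datetime | None = None

    def __post_init__(self) -> None:
        half = config.CRYSTAL_PLATE.drop_half_extent_mm
        x, y = self.offset
        if abs(x) > half or abs(y) > half:
            raise TransferError(
                f"dispense offset ({x}, {y}) mm outside the ±{half} mm drop "
                f"half-extent for {self.plate_barcode} {self.well}"
            )


@dataclass
class SoakRecord:
    """One fragment-into-drop soak with its dispense status and timer."""

    target: DropTarget
    fragment_id: str
    transfer_nl: float
    status: str = "planned"  # planned | dispensed | failed
    soak_start: datetime | None = None
    soak_stop: datetime | None = None
    error_msg: str | None = None

    def __post_init__(self) -> None:
        _check_quantum(self.transfer_nl)
        if self.status not in ("planned", "dispensed", "failed"):
            raise FragflowError(f"unknown soak status {self.status!r}")
        if (
            self.soak_start is not None
            and self.soak_stop is not None
            and self.soak_stop < self.soak_start
        ):
            raise FragflowError("soak_stop precedes soak_start")


class TransferRow(NamedTuple):
    source_barcode: str
    source_well: str
    dest_barcode: str
    dest_well: str
    transfer_nl: float
    dest_x_offset_mm: float
    dest_y_offset_mm: float


@dataclass
class TransferList:
    """Ordered cherry-pick rows for the acoustic dispenser."""

    rows: list[TransferRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def total_volume_per_source(self) -> dict[tuple[str, str], float]:
        """Total nL drawn from each (source plate, source well)."""
        totals: dict[tuple[str, str], float] = {}
        for row in self.rows:
            key = (row.source_barcode, row.source_well)
            totals[key] = totals.get(key, 0.0) + row.transfer_nl
        return totals

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(config.TRANSFER_CSV_COLUMNS)
            for r in self.rows:
                writer.writerow(
                    [
                        r.source_barcode,
                        r.source_well,
                        r.dest_barcode,
                        r.dest_well,
                        f"{r.transfer_nl:.1f}",
                        f"{r.dest_x_offset_mm:.3f}",
                        f"{r.dest_y_offset_mm:.3f}",
                    ]
                )
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "TransferList":
        rows = []
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader)
            if tuple(header) != config.TRANSFER_CSV_COLUMNS:
                raise TransferError(f"unexpected transfer-list header {header}")
            for rec in reader:
                rows.append(
                    TransferRow(
                        source_barcode=rec[0],
                        source_well=rec[1],
                        dest_barcode=rec[2],
                        dest_well=rec[3],
                        transfer_nl=float(rec[4]),
                        dest_x_offset_mm=float(rec[5]),
                        dest_y_offset_mm=float(rec[6]),
                    )
                )
        return cls(rows=rows)


class OffsetResult(NamedTuple):
    x_mm: float
    y_mm: float
    clamped: bool


def _check_quantum(transfer_nl: float) -> None:
    q = config.DROPLET_QUANTUM_NL
    if transfer_nl <= 0:
        raise TransferError(f"transfer volume must be positive, got {transfer_nl} nL")
    droplets = transfer_nl / q
    if abs(droplets - round(droplets)) > 1e-9:
        raise TransferError(
            f"transfer volume {transfer_nl} nL is not a multiple of the "
            f"{q} nL droplet quantum"
        )


def pixel_to_offset(
    pixel: tuple[float, float],
    calibration: dict,
    half_extent_mm: float | None = None,
) -> OffsetResult:
    """Convert a clicked image pixel to a dispense offset in mm.

    ``calibration`` holds ``well_centre_px`` (cx, cy) and ``mm_per_px``.
    Image convention: +x right, +y down. Results outside the drop-well
    half-extent are clamped and flagged.
    """
    cx, cy = calibration["well_centre_px"]
    scale = calibration["mm_per_px"]
    if scale <= 0:
        raise FragflowError(f"mm_per_px must be positive, got {scale}")
    half = (
        half_extent_mm
        if half_extent_mm is not None
        else config.CRYSTAL_PLATE.drop_half_extent_mm
    )
    x = (pixel[0] - cx) * scale
    y = (pixel[1] - cy) * scale
    clamped = abs(x) > half or abs(y) > half
    x = min(max(x, -half), half)
    y = min(max(y, -half), half)
    return OffsetResult(x_mm=x, y_mm=y, clamped=clamped)


def _dest_offsets(target: DropTarget) -> tuple[float, float]:
    dx, dy = config.CRYSTAL_PLATE.drop_centre_offsets_mm[target.well.drop]
    return (round(target.offset[0] + dx, 3), round(target.offset[1] + dy, 3))


def build_transfer_list(
    soaks: Sequence[tuple[DropTarget, str, float]],
    library: FragmentLibrary,
) -> TransferList:
    """One transfer row per (drop, fragment, volume) soak request.

    The source well is looked up from the library's fragment map; row order
    follows input order. Unknown fragments, off-quantum volumes and two
    soaks into the same drop are refused.
    """
    rows: list[TransferRow] = []
    seen: set[tuple[str, str]] = set()
    for target, fragment_id, transfer_nl in soaks:
        frag = library[fragment_id]  # raises FragmentNotFoundError
        _check_quantum(transfer_nl)
        dest_key = (target.plate_barcode, str(target.well))
        if dest_key in seen:
            raise TransferError(
                f"duplicate destination drop {target.well} on plate "
                f"{target.plate_barcode!r}"
            )
        seen.add(dest_key)
        x, y = _dest_offsets(target)
        rows.append(
            TransferRow(
                source_barcode=frag.source_plate,
                source_well=str(frag.source_well),
                dest_barcode=target.plate_barcode,
                dest_well=target.well.well_name,
                transfer_nl=float(transfer_nl),
                dest_x_offset_mm=x,
                dest_y_offset_mm=y,
            )
        )
    return TransferList(rows=rows)


def dmso_percent(drop_nl: float, transfer_nl: float) -> float:
    """Final DMSO concentration (%) after dispensing ``transfer_nl`` of
    DMSO stock into a ``drop_nl`` aqueous drop: 100·t/(d+t)."""
    if drop_nl <= 0 or transfer_nl <= 0:
        raise FragflowError(
            f"volumes must be positive (drop {drop_nl} nL, transfer {transfer_nl} nL)"
        )
    return 100.0 * transfer_nl / (drop_nl + transfer_nl)


def soak_elapsed(record: SoakRecord, now: datetime) -> int:
    """Whole minutes a soak has run: from soak_start to soak_stop if the
    timer was stopped, else to ``now``; floored to the display granularity
    of one minute."""
    if record.soak_start is None:
        raise FragflowError("soak timer was never started (soak_start unset)")
    end = record.soak_stop if record.soak_stop is not None else now
    seconds = (end - record.soak_start).total_seconds()
    if seconds < 0:
        raise FragflowError("current time precedes soak_start")
    return math.floor(seconds / 60.0)


def ingest_dispense_report(
    records: Sequence[SoakRecord],
    report_rows: Iterable[dict],
    stop_time: datetime,
) -> tuple[list[SoakRecord], list[dict]]:
    """Apply a dispenser status report to planned soaks.

    ``report_rows`` are dicts with keys dest_barcode, dest_well (well+drop,
    e.g. "B7c"), status and message. Matching key is (dest_barcode,
    well+drop); first match wins. Matched records become dispensed (status
    begins with "ok") or failed (message retained) and their soak timer is
    stopped at ``stop_time``. Rows matching no planned soak, and duplicate
    rows for an already-matched soak, come back as discrepancies.
    """
    updated = list(records)
    index: dict[tuple[str, str], int] = {}
    for i, rec in enumerate(updated):
        index.setdefault((rec.target.plate_barcode, str(rec.target.well)), i)
    matched: set[int] = set()
    discrepancies: list[dict] = []
    for row in report_rows:
        key = (row["dest_barcode"], str(parse_crystal_well(row["dest_well"])))
        i = index.get(key)
        if i is None or i in matched:
            discrepancies.append(dict(row))
            continue
        matched.add(i)
        ok = str(row.get("status", "")).strip().lower().startswith("ok")
        rec = updated[i]
        updated[i] = replace(
            rec,
            status="dispensed" if ok else "failed",
            soak_stop=stop_time,
            error_msg=None if ok else (row.get("message") or row.get("status")),
        )
    return updated, discrepancies


def plan_redissolve(
    fragments: Sequence[str],
    dest_plate: str,
    library: FragmentLibrary,
    transfer_nl: float,
) -> tuple[TransferList, list[dict]]:
    """Plan a DMSO-free soak: dispense each fragment's stock into its own
    subwell of an empty plate (row-major A1a, A1b, A1c, A2a, ...), to be
    air-dried and redissolved in crystallization buffer.

    Returns the transfer list plus a tracking sheet with per-well steps
    {dispensed, dried, redissolved}, all initially pending.
    """
    capacity = config.CRYSTAL_PLATE.capacity
    if len(fragments) > capacity:
        raise CapacityError(
            f"{len(fragments)} fragments exceed the {capacity} drop positions "
            f"of one crystallization plate"
        )
    soaks = [
        (DropTarget(plate_barcode=dest_plate, well=well), fid, transfer_nl)
        for well, fid in zip(iter_crystal_drops(), fragments)
    ]
    transfers = build_transfer_list(soaks, library)
    sheet = [
        {
            "well": str(t.well),
            "fragment_id": fid,
            "dispensed": "pending",
            "dried": "pending",
            "redissolved": "pending",
        }
        for (t, fid, _) in soaks
    ]
    return transfers, sheet


def write_redissolve_sheet(sheet: Sequence[dict], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(
            fh, fieldnames=["well", "fragment_id", "dispensed", "dried", "redissolved"]
        )
        writer.writeheader()
        writer.writerows(sheet)
    return path
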