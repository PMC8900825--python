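"""Crystal harvesting: fishing definitions, result merging, sample sheets.

After soaking, crystals are fished from their drops at a semi-automated
harvesting station and mounted on pins stored in cryo-pucks (16 pins per
puck). The station reports per-drop outcomes; a separate barcode-reading
station scans the pucks afterwards, producing a sequence-numbered list of
(puck, pin) positions. The k-th successfully fished crystal is joined to
the k-th scanned position — there is no shared key, so the join is by
order, with optional pin barcodes cross-checked when present.

The merged records feed a data-collection sample spreadsheet (CSV and XLSX
with identical cells) whose sample names are campaign-plate-welldrop.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from . import config
from .errors import FragflowError, ReconciliationError
from .library import FragmentLibrary, lookup_smiles
from .soak import DropTarget, SoakRecord

__all__ = [
    "FishRecord",
    "build_fishing_definition",
    "write_fishing_definition",
    "merge_fishing_results",
    "export_collection_sheet",
]

FISHING_DEFINITION_COLUMNS = ("plate_barcode", "well", "fragment_id", "soak_start")


@dataclass
class FishRecord:
    """One drop visited at the harvesting station."""

    target: DropTarget
    fragment_id: str
    status: str  # fished | skipped | failed
    fished_at: datetime | None = None
    puck: str | None = None
    pin: int | None = None
    pin_barcode: str | None = None
    comment: str | None = None

    def __post_init__(self) -> None:
        if self.status not in ("fished", "skipped", "failed"):
            raise FragflowError(f"unknown fishing status {self.status!r}")
        if self.pin is not None and not 1 <= self.pin <= config.PUCK_CAPACITY:
            raise FragflowError(
                f"pin position {self.pin} outside 1-{config.PUCK_CAPACITY}"
            )


def build_fishing_definition(soaks: Sequence[SoakRecord]) -> list[dict]:
    """Rows for the harvesting station: one per dispensed soak, ordered by
    plate then well. Failed/planned soaks are excluded; an empty result is
    an error (nothing to fish)."""
    dispensed = [s for s in soaks if s.status == "dispensed"]
    if not dispensed:
        raise FragflowError("no dispensed soaks: fishing definition would be empty")
    dispensed.sort(key=lambda s: (s.target.plate_barcode, s.target.well))
    return [
        {
            "plate_barcode": s.target.plate_barcode,
            "well": str(s.target.well),
            "fragment_id": s.fragment_id,
            "soak_start": s.soak_start.isoformat() if s.soak_start else "",
        }
        for s in dispensed
    ]


def write_fishing_definition(rows: Sequence[dict], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=FISHING_DEFINITION_COLUMNS)
        writer.writeheader()
        writer.writerows(rows)
    return path


def merge_fishing_results(
    soaks: Sequence[SoakRecord],
    shifter_rows: Iterable[dict],
    puck_scan_rows: Iterable[dict],
) -> tuple[list[FishRecord], list[str]]:
    """Join harvesting-station results with the puck-scan list.

    ``shifter_rows``: dicts with plate_barcode, well (well+drop), status,
    timestamp, comment — one per visited drop, in fishing order.
    ``puck_scan_rows``: dicts with sequence (1-based), puck, pin and
    optionally pin_barcode.

    The k-th *fished* shifter row is joined to the scan row with sequence
    k; skipped/failed rows consume no scan. A fished/scanned count mismatch
    is a reconciliation error reporting both counts. Pin-barcode
    disagreements (same sequence, different barcode recorded by the
    station) are flagged as warnings, not errors.

    Returns (records, warnings).
    """
    by_dest = {
        (s.target.plate_barcode, str(s.target.well)): s
        for s in soaks
    }
    shifter = list(shifter_rows)
    scans = sorted(puck_scan_rows, key=lambda r: int(r["sequence"]))
    n_fished = sum(1 for r in shifter if r["status"] == "fished")
    if n_fished != len(scans):
        raise ReconciliationError(
            f"fished-crystal count does not match puck-scan count: "
            f"{n_fished} vs {len(scans)}"
        )
    records: list[FishRecord] = []
    warnings: list[str] = []
    k = 0
    for row in shifter:
        key = (row["plate_barcode"], row["well"])
        soak = by_dest.get(key)
        if soak is None:
            raise ReconciliationError(
                f"harvest result for unknown drop {row['well']} on plate "
                f"{row['plate_barcode']!r}"
            )
        status = row["status"]
        puck = pin = pin_barcode = None
        if status == "fished":
            scan = scans[k]
            k += 1
            puck = str(scan["puck"])
            pin = int(scan["pin"])
            pin_barcode = scan.get("pin_barcode") or None
            station_pin_bc = row.get("pin_barcode") or None
            if station_pin_bc and pin_barcode and station_pin_bc != pin_barcode:
                warnings.append(
                    f"pin-barcode mismatch for {row['well']}: station recorded "
                    f"{station_pin_bc!r}, scan read {pin_barcode!r}"
                )
        ts = row.get("timestamp")
        records.append(
            FishRecord(
                target=soak.target,
                fragment_id=soak.fragment_id,
                status=status,
                fished_at=datetime.fromisoformat(ts) if ts else None,
                puck=puck,
                pin=pin,
                pin_barcode=pin_barcode,
                comment=row.get("comment") or None,
            )
        )
    seen: set[tuple[str, int]] = set()
    for rec in records:
        if rec.status == "fished":
            if (rec.puck, rec.pin) in seen:
                raise ReconciliationError(
                    f"puck position {rec.puck}/{rec.pin} assigned twice"
                )
            seen.add((rec.puck, rec.pin))
    return records, warnings


def export_collection_sheet(
    records: Sequence[FishRecord],
    library: FragmentLibrary,
    pipeline: str,
    mr_model: str,
    campaign: str,
    csv_path: str | Path | None = None,
    xlsx_path: str | Path | None = None,
) -> pd.DataFrame:
    """Data-collection sample sheet: one row per fished crystal, sorted by
    puck then pin, sample names ``campaign-plate-welldrop``, SMILES resolved
    from the library. Written as CSV and/or XLSX with identical cells when
    paths are given."""
    if pipeline not in config.PROCESSING_PIPELINES:
        raise FragflowError(
            f"unknown processing pipeline {pipeline!r} "
            f"(choose from {config.PROCESSING_PIPELINES})"
        )
    rows = []
    for rec in records:
        if rec.status != "fished":
            continue
        if rec.puck is None or rec.pin is None:
            raise FragflowError(
                f"fished record for {rec.target.well} lacks a puck/pin assignment"
            )
        rows.append(
            {
                "puck": rec.puck,
                "pin": rec.pin,
                "sample_name": f"{campaign}-{rec.target.plate_barcode}-{rec.target.well}",
                "fragment_id": rec.fragment_id,
                "fragment_smiles": lookup_smiles(library, rec.fragment_id),
                "processing_pipeline": pipeline,
                "mr_model": mr_model,
            }
        )
    sheet = pd.DataFrame(rows, columns=list(config.COLLECTION_SHEET_COLUMNS))
    sheet = sheet.sort_values(["puck", "pin"], kind="stable").reset_index(drop=True)
    if sheet["sample_name"].duplicated().any():
        dup = sheet.loc[sheet["sample_name"].duplicated(), "sample_name"].iloc[0]
        raise FragflowError(f"duplicate sample name {dup!r} in collection sheet")
    if csv_path is not None:
        sheet.to_csv(csv_path, index=False)
    if xlsx_path is not None:
        sheet.to_excel(xlsx_path, index=False)
    return sheet
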