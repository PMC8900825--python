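"""Instrument and plate-geometry configuration.

All tunable constants live here so that another plate type, dispenser or
fingerprint flavour can be added without touching the workflow code.
Internally every index is 0-based; display strings use 1-based columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class CrystalPlateGeometry:
    """Sitting-drop crystallization plate (MRC-3 style by default).

    ``drop_centre_offsets_mm`` places each subwell's centre relative to the
    well footprint centre; the acoustic transfer list addresses the 96-well
    position and encodes the subwell through these offsets.
    """

    rows: int = 8
    cols: int = 12
    drops_per_well: int = 3
    # half-extent of one drop well: in-drop dispense offsets are clamped here
    drop_half_extent_mm: float = 1.5
    # subwell centres a/b/c laid out in a triangle around the well centre
    drop_centre_offsets_mm: tuple[tuple[float, float], ...] = (
        (0.0, -2.4),
        (-2.1, 1.2),
        (2.1, 1.2),
    )

    @property
    def capacity(self) -> int:
        return self.rows * self.cols * self.drops_per_well


@dataclass(frozen=True)
class SourcePlateGeometry:
    """Acoustic-dispenser source plate (384- or 1536-well)."""

    rows: int
    cols: int

    @property
    def capacity(self) -> int:
        return self.rows * self.cols


#: Supported library source-plate formats, keyed by well count.
SOURCE_PLATE_FORMATS: dict[int, SourcePlateGeometry] = {
    384: SourcePlateGeometry(rows=16, cols=24),
    1536: SourcePlateGeometry(rows=32, cols=48),
}

CRYSTAL_PLATE = CrystalPlateGeometry()

#: Smallest droplet an acoustic dispenser ejects; every transfer volume must
#: be an exact multiple of this quantum.
DROPLET_QUANTUM_NL: float = 2.5

#: Structural fingerprint used for diversity selection (a generic circular
#: fingerprint; the descriptor family, not a specific product, is the point).
FINGERPRINT_KIND: str = "morgan"
FINGERPRINT_RADIUS: int = 2
FINGERPRINT_NBITS: int = 1024

#: Cryo-puck capacity (SPINE/Unipuck convention).
PUCK_CAPACITY: int = 16

#: Transfer-list CSV header (cherry-pick convention; volumes in nL, offsets
#: in mm with 3 decimals).
TRANSFER_CSV_COLUMNS: tuple[str, ...] = (
    "Source Plate Barcode",
    "Source Well",
    "Destination Plate Barcode",
    "Destination Well",
    "Transfer Volume",
    "Destination Well X Offset",
    "Destination Well Y Offset",
)

#: Data-collection sample-sheet column template.
COLLECTION_SHEET_COLUMNS: tuple[str, ...] = (
    "puck",
    "pin",
    "sample_name",
    "fragment_id",
    "fragment_smiles",
    "processing_pipeline",
    "mr_model",
)

#: Downstream processing pipelines a sample sheet may request.
PROCESSING_PIPELINES: tuple[str, ...] = ("gopy", "autoPROC", "xia2dials")


@dataclass
class StoreSchema:
    """Required keys (and their Python types) for one store collection."""

    required: dict[str, type] = field(default_factory=dict)


#: Document-store collections and their validators. The store is schema-less
#: beyond these required keys: extra keys always pass.
COLLECTION_SCHEMAS: dict[str, StoreSchema] = {
    "Plates": StoreSchema({"barcode": str, "kind": str, "campaign": str}),
    "Wells": StoreSchema({"plate_barcode": str, "well": str, "campaign": str}),
    "Libraries": StoreSchema({"name": str, "plate_format": int}),
}
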