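"""Plate geometry and well addressing.

Crystallization plates are 96-well sitting-drop plates with three drop
positions (subwells) per well, addressed like ``"B7c"``: upper-case row
letter A-H, 1-based column 1-12, lower-case drop letter a-c. Library
source plates are 384-well (A1-P24) or 1536-well (A1-AF48); 1536 rows run
A-Z then AA-AF, Excel-style. All indices are 0-based internally; display
strings use 1-based columns.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterator, Literal

from .config import CRYSTAL_PLATE, SOURCE_PLATE_FORMATS
from .errors import AddressError

__all__ = [
    "PlateFormat",
    "CrystalWellAddress",
    "LibraryWellAddress",
    "PlateRecord",
    "parse_crystal_well",
    "parse_library_well",
    "enumerate_wells",
    "row_letters",
    "row_index",
]

_ADDRESS_RE = re.compile(r"^([A-Za-z]+)(\d+)([A-Za-z])?$")


class PlateFormat(int, Enum):
    """Source-plate format, named by its well count."""

    F384 = 384
    F1536 = 1536


def row_letters(index: int) -> str:
    """0-based row index -> letters (0 -> ``"A"``, 25 -> ``"Z"``, 26 -> ``"AA"``)."""
    if index < 0:
        raise AddressError(f"row index must be non-negative, got {index}")
    letters = ""
    index += 1  # bijective base-26
    while index:
        index, rem = divmod(index - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return letters


def row_index(letters: str) -> int:
    """Letters -> 0-based row index (inverse of :func:`row_letters`)."""
    if not letters.isalpha():
        raise AddressError(f"malformed row letters {letters!r}")
    index = 0
    for ch in letters.upper():
        index = index * 26 + (ord(ch) - ord("A") + 1)
    return index - 1


@dataclass(frozen=True, order=True)
class CrystalWellAddress:
    """One drop position on a 96-well, 3-subwell crystallization plate."""

    row: int
    col: int
    drop: int

    def __post_init__(self) -> None:
        g = CRYSTAL_PLATE
        if not 0 <= self.row < g.rows:
            raise AddressError(
                f"crystal-plate row index {self.row} out of range 0-{g.rows - 1}"
            )
        if not 0 <= self.col < g.cols:
            raise AddressError(
                f"crystal-plate column index {self.col} out of range 0-{g.cols - 1}"
            )
        if not 0 <= self.drop < g.drops_per_well:
            raise AddressError(
                f"drop index {self.drop} out of range 0-{g.drops_per_well - 1}"
            )

    @property
    def well_name(self) -> str:
        """96-well address without the drop letter, e.g. ``"B7"``."""
        return f"{row_letters(self.row)}{self.col + 1}"

    def __str__(self) -> str:
        return f"{self.well_name}{chr(ord('a') + self.drop)}"


@dataclass(frozen=True, order=True)
class LibraryWellAddress:
    """One well on a 384- or 1536-well library source plate."""

    row: int
    col: int
    format: PlateFormat = PlateFormat.F384

    def __post_init__(self) -> None:
        geom = SOURCE_PLATE_FORMATS[int(self.format)]
        if not 0 <= self.row < geom.rows:
            raise AddressError(
                f"row index {self.row} out of range 0-{geom.rows - 1} "
                f"for {int(self.format)}-well format"
            )
        if not 0 <= self.col < geom.cols:
            raise AddressError(
                f"column index {self.col} out of range 0-{geom.cols - 1} "
                f"for {int(self.format)}-well format"
            )

    def __str__(self) -> str:
        return f"{row_letters(self.row)}{self.col + 1}"


@dataclass(frozen=True)
class PlateRecord:
    """A barcoded plate registered to a campaign."""

    barcode: str
    kind: Literal["crystal", "library"]
    campaign: str
    temperature: Literal["4C", "RT"] = "RT"

    def __post_init__(self) -> None:
        if not self.barcode:
            raise ValueError("plate barcode must be non-empty")
        if self.kind not in ("crystal", "library"):
            raise ValueError(f"unknown plate kind {self.kind!r}")
        if self.temperature not in ("4C", "RT"):
            raise ValueError(f"unknown storage temperature {self.temperature!r}")


def parse_crystal_well(text: str) -> CrystalWellAddress:
    """Parse a crystallization drop address like ``"B7c"``.

    Parsing is case-insensitive; formatting back through ``str()`` yields
    the canonical upper-case-row / lower-case-drop form.
    """
    if not text:
        raise AddressError("empty crystal-well address")
    m = _ADDRESS_RE.match(text.strip())
    if m is None or m.group(3) is None:
        raise AddressError(
            f"malformed crystal-well address {text!r} (expected e.g. 'B7c')"
        )
    row_part, col_part, drop_part = m.groups()
    row = row_index(row_part)
    col = int(col_part) - 1
    drop = ord(drop_part.lower()) - ord("a")
    g = CRYSTAL_PLATE
    if row >= g.rows:
        raise AddressError(
            f"row {row_part.upper()!r} beyond last row "
            f"{row_letters(g.rows - 1)!r} in address {text!r}"
        )
    if not 0 <= col < g.cols:
        raise AddressError(f"column {col_part!r} beyond {g.cols} in address {text!r}")
    if drop >= g.drops_per_well:
        raise AddressError(
            f"drop letter {drop_part!r} beyond "
            f"{chr(ord('a') + g.drops_per_well - 1)!r} in address {text!r}"
        )
    return CrystalWellAddress(row=row, col=col, drop=drop)


def parse_library_well(text: str, format: PlateFormat | int) -> LibraryWellAddress:
    """Parse a source-plate address like ``"P24"`` (384) or ``"AF48"`` (1536)."""
    fmt = PlateFormat(int(format))
    if not text:
        raise AddressError("empty library-well address")
    m = _ADDRESS_RE.match(text.strip())
    if m is None or m.group(3) is not None:
        raise AddressError(
            f"malformed library-well address {text!r} (expected e.g. 'P24')"
        )
    row_part, col_part, _ = m.groups()
    geom = SOURCE_PLATE_FORMATS[int(fmt)]
    row = row_index(row_part)
    col = int(col_part) - 1
    if row >= geom.rows:
        raise AddressError(
            f"row {row_part.upper()!r} beyond last row "
            f"{row_letters(geom.rows - 1)!r} for {int(fmt)}-well format"
        )
    if not 0 <= col < geom.cols:
        raise AddressError(
            f"column {col_part!r} out of range 1-{geom.cols} "
            f"for {int(fmt)}-well format"
        )
    return LibraryWellAddress(row=row, col=col, format=fmt)


def enumerate_wells(format: PlateFormat | int) -> list[LibraryWellAddress]:
    """All wells of a source-plate format in row-major order (A1, A2, ...)."""
    try:
        fmt = PlateFormat(int(format))
    except ValueError:
        raise AddressError(
            f"unsupported source-plate format {format!r} "
            f"(supported: {sorted(SOURCE_PLATE_FORMATS)})"
        ) from None
    geom = SOURCE_PLATE_FORMATS[int(fmt)]
    return [
        LibraryWellAddress(row=r, col=c, format=fmt)
        for r in range(geom.rows)
        for c in range(geom.cols)
    ]


def iter_crystal_drops() -> Iterator[CrystalWellAddress]:
    """All 288 drop positions of a crystallization plate, row-major,
    subwells a-c within each well."""
    g = CRYSTAL_PLATE
    for r in range(g.rows):
        for c in range(g.cols):
            for d in range(g.drops_per_well):
                yield CrystalWellAddress(row=r, col=c, drop=d)
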