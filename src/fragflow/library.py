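"""Fragment-library handling.

A fragment library is a set of small molecules stored in DMSO in a barcoded
384- or 1536-well acoustic source plate. The library file of record is an
SDF whose per-record properties carry the catalogue code and the source
well; this module ingests that file, keeps the fragment <-> source-well map,
exports canonical SMILES for downstream restraint generation, and selects
maximally diverse subsets for screening.

Diversity selection is greedy MaxMin over binary structural fingerprints
with Tanimoto distance: starting from a seeded pick, each step adds the
candidate whose minimum distance to the already-selected set is largest.
The fingerprint kind and size are configuration (a generic circular
fingerprint by default); selection quality, not a specific descriptor
product, is the contract.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from rdkit import Chem, RDLogger
from rdkit.Chem import DataStructs, rdFingerprintGenerator

from . import config
from .errors import FragmentNotFoundError, LibraryError
from .plates import LibraryWellAddress, PlateFormat, parse_library_well

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Fragment",
    "FragmentLibrary",
    "read_library_sdf",
    "write_library_sdf",
    "lookup_smiles",
    "select_diverse",
    "export_library_csv",
]


@dataclass(frozen=True)
class Fragment:
    """One library member.

    Parameters
    ----------
    fragment_id : str
        Library catalogue code, e.g. ``"BTB00030"``. Case-sensitive and
        unique within a library.
    smiles : str
        Canonical SMILES (canonicalized at ingest so lookups are stable).
    source_plate : str
        Barcode of the acoustic source plate holding the stock.
    source_well : LibraryWellAddress
        Well of the stock solution on the source plate.
    stock_conc_mm : float, optional
        Stock concentration in mM DMSO; carried through, never defaulted.
    name : str, optional
        Free-text compound name.
    """

    fragment_id: str
    smiles: str
    source_plate: str
    source_well: LibraryWellAddress
    stock_conc_mm: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.fragment_id:
            raise LibraryError("fragment_id must be non-empty")
        if not self.smiles:
            raise LibraryError(f"fragment {self.fragment_id}: empty SMILES")


@dataclass
class FragmentLibrary:
    """A named fragment collection mapped onto one source-plate format."""

    name: str
    plate_format: PlateFormat = PlateFormat.F384
    fragments: dict[str, Fragment] = field(default_factory=dict)

    def add(self, fragment: Fragment) -> None:
        if fragment.fragment_id in self.fragments:
            raise LibraryError(f"duplicate fragment_id {fragment.fragment_id!r}")
        key = (fragment.source_plate, fragment.source_well)
        for other in self.fragments.values():
            if (other.source_plate, other.source_well) == key:
                raise LibraryError(
                    f"duplicate source well {fragment.source_well} on plate "
                    f"{fragment.source_plate!r} (fragments "
                    f"{other.fragment_id!r} and {fragment.fragment_id!r})"
                )
        self.fragments[fragment.fragment_id] = fragment

    def __len__(self) -> int:
        return len(self.fragments)

    def __contains__(self, fragment_id: str) -> bool:
        return fragment_id in self.fragments

    def __getitem__(self, fragment_id: str) -> Fragment:
        try:
            return self.fragments[fragment_id]
        except KeyError:
            raise FragmentNotFoundError(
                f"fragment {fragment_id!r} not in library {self.name!r}"
            ) from None

    def ids(self) -> list[str]:
        return list(self.fragments)


def _canonical_smiles(smiles: str, context: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise LibraryError(f"{context}: unparseable SMILES {smiles!r}")
    return Chem.MolToSmiles(mol)


def read_library_sdf(
    path: str | Path,
    id_field: str = "ID",
    well_field: str = "Well",
    *,
    plate_field: str = "Plate",
    conc_field: str = "Concentration_mM",
    name_field: str = "Name",
    plate_format: PlateFormat | int = PlateFormat.F384,
    library_name: str | None = None,
) -> FragmentLibrary:
    """Read a fragment library from an SDF (V2000) file.

    Each record must carry ``id_field`` and ``well_field`` properties.
    SMILES are taken from a ``SMILES`` property when present, otherwise
    derived from the connection table; either way they are canonicalized.
    ``plate_field``, ``conc_field`` and ``name_field`` are optional
    per-record properties.
    """
    path = Path(path)
    if not path.exists():
        raise LibraryError(f"SDF file not found: {path}")
    fmt = PlateFormat(int(plate_format))
    library = FragmentLibrary(
        name=library_name or path.stem, plate_format=fmt
    )
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=False)
    for i, mol in enumerate(supplier):
        if mol is None:
            raise LibraryError(f"record {i}: unreadable SDF molecule block")
        if not mol.HasProp(id_field):
            raise LibraryError(f"record {i}: missing property {id_field!r}")
        if not mol.HasProp(well_field):
            raise LibraryError(f"record {i}: missing property {well_field!r}")
        fragment_id = mol.GetProp(id_field).strip()
        well = parse_library_well(mol.GetProp(well_field).strip(), fmt)
        if mol.HasProp("SMILES"):
            smiles = _canonical_smiles(
                mol.GetProp("SMILES").strip(), f"record {i} ({fragment_id})"
            )
        else:
            smiles = Chem.MolToSmiles(mol)
        plate = mol.GetProp(plate_field).strip() if mol.HasProp(plate_field) else ""
        conc = float(mol.GetProp(conc_field)) if mol.HasProp(conc_field) else None
        name = mol.GetProp(name_field).strip() if mol.HasProp(name_field) else None
        library.add(
            Fragment(
                fragment_id=fragment_id,
                smiles=smiles,
                source_plate=plate,
                source_well=well,
                stock_conc_mm=conc,
                name=name,
            )
        )
    return library


def write_library_sdf(library: FragmentLibrary, path: str | Path) -> Path:
    """Write a library back to SDF with the same property fields
    :func:`read_library_sdf` consumes (round-trip safe)."""
    path = Path(path)
    writer = Chem.SDWriter(str(path))
    try:
        for frag in library.fragments.values():
            mol = Chem.MolFromSmiles(frag.smiles)
            if mol is None:  # cannot happen for canonical SMILES
                raise LibraryError(
                    f"fragment {frag.fragment_id}: unparseable SMILES {frag.smiles!r}"
                )
            mol.SetProp("_Name", frag.fragment_id)
            mol.SetProp("ID", frag.fragment_id)
            mol.SetProp("Well", str(frag.source_well))
            mol.SetProp("SMILES", frag.smiles)
            if frag.source_plate:
                mol.SetProp("Plate", frag.source_plate)
            if frag.stock_conc_mm is not None:
                mol.SetProp("Concentration_mM", repr(frag.stock_conc_mm))
            if frag.name is not None:
                mol.SetProp("Name", frag.name)
            writer.write(mol)
    finally:
        writer.close()
    return path


def lookup_smiles(library: FragmentLibrary, fragment_id: str) -> str:
    """Canonical SMILES for a fragment, ready for an external restraint
    generator. IDs are case-sensitive."""
    return library[fragment_id].smiles


def _fingerprints(library: FragmentLibrary, ids: Sequence[str]):
    gen = rdFingerprintGenerator.GetMorganGenerator(
        radius=config.FINGERPRINT_RADIUS, fpSize=config.FINGERPRINT_NBITS
    )
    fps = {}
    for fid in ids:
        mol = Chem.MolFromSmiles(library[fid].smiles)
        if mol is None:
            raise LibraryError(f"fragment {fid}: unparseable SMILES")
        fps[fid] = gen.GetFingerprint(mol)
    return fps


def tanimoto_distance_matrix(
    library: FragmentLibrary, ids: Sequence[str] | None = None
) -> dict[tuple[str, str], float]:
    """Pairwise Tanimoto distances (1 - similarity) keyed by id pair."""
    ids = list(ids if ids is not None else sorted(library.ids()))
    fps = _fingerprints(library, ids)
    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            d = 1.0 - DataStructs.TanimotoSimilarity(fps[a], fps[b])
            dist[(a, b)] = dist[(b, a)] = d
    return dist


def select_diverse(
    library: FragmentLibrary,
    n: int,
    seed: int = 0,
    *,
    first_id: str | None = None,
) -> list[str]:
    """Greedy MaxMin selection of ``n`` structurally diverse fragments.

    Deterministic given ``seed``: seed 0 starts from the lexicographically
    smallest fragment_id, any other seed from a seeded uniform choice, and
    ties in the minimum-distance criterion are broken by fragment_id order.
    ``first_id`` overrides the seeded start. The result for ``n = k`` is
    always a prefix of the result for ``n = k + 1`` under the same seed.
    """
    ids = sorted(library.ids())
    if not 1 <= n <= len(ids):
        raise LibraryError(
            f"cannot select {n} fragments from a library of {len(ids)}"
        )
    fps = _fingerprints(library, ids)

    if first_id is not None:
        if first_id not in library:
            raise FragmentNotFoundError(
                f"fragment {first_id!r} not in library {library.name!r}"
            )
        start = first_id
    elif seed == 0:
        start = ids[0]
    else:
        start = random.Random(seed).choice(ids)

    selected = [start]
    # min distance from each remaining candidate to the selected set
    min_dist = {
        fid: 1.0 - DataStructs.TanimotoSimilarity(fps[fid], fps[start])
        for fid in ids
        if fid != start
    }
    while len(selected) < n:
        # max of min-distance; ties broken by id order (ids iterated sorted)
        best_id, best_d = None, -1.0
        for fid in ids:
            d = min_dist.get(fid)
            if d is not None and d > best_d:
                best_id, best_d = fid, d
        assert best_id is not None
        selected.append(best_id)
        del min_dist[best_id]
        for fid in min_dist:
            d = 1.0 - DataStructs.TanimotoSimilarity(fps[fid], fps[best_id])
            if d < min_dist[fid]:
                min_dist[fid] = d
    return selected


def export_library_csv(library: FragmentLibrary, path: str | Path) -> Path:
    """Record-keeping export: fragment_id, smiles, source_plate, source_well,
    stock_conc_mm, one row per fragment in id order."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["fragment_id", "smiles", "source_plate", "source_well", "stock_conc_mm"]
        )
        for fid in sorted(library.ids()):
            frag = library[fid]
            writer.writerow(
                [
                    frag.fragment_id,
                    frag.smiles,
                    frag.source_plate,
                    str(frag.source_well),
                    "" if frag.stock_conc_mm is None else frag.stock_conc_mm,
                ]
            )
    return path
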