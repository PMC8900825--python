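from __future__ import annotations

from datetime import datetime

import pytest
from hypothesis import settings

from fragflow.library import Fragment, FragmentLibrary
from fragflow.plates import enumerate_wells, parse_crystal_well
from fragflow.soak import DropTarget

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")

BASE_TIME = datetime(2024, 1, 15, 9, 0, 0)

# five structurally distinct fragments for diversity tests
FIVE_SMILES = {
    "F01": "Cc1ccccc1",  # toluene
    "F02": "OC(=O)c1ccccc1",  # benzoic acid
    "F03": "C1CNCCN1",  # piperazine
    "F04": "c1ccc2[nH]ccc2c1",  # indole
    "F05": "NS(=O)(=O)c1ccccc1",  # benzenesulfonamide
}


def build_library(smiles_by_id: dict[str, str], plate: str = "LIB-001") -> FragmentLibrary:
    from rdkit import Chem

    wells = enumerate_wells(384)
    lib = FragmentLibrary(name="test")
    for i, (fid, smi) in enumerate(sorted(smiles_by_id.items())):
        lib.add(
            Fragment(
                fragment_id=fid,
                smiles=Chem.CanonSmiles(smi),
                source_plate=plate,
                source_well=wells[i],
                stock_conc_mm=100.0,
            )
        )
    return lib


@pytest.fixture
def five_library() -> FragmentLibrary:
    return build_library(FIVE_SMILES)


@pytest.fixture
def drop_target() -> DropTarget:
    return DropTarget(
        plate_barcode="XTAL-001",
        well=parse_crystal_well("B2a"),
        offset=(0.3, -0.2),
        selected_at=BASE_TIME,
    )
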