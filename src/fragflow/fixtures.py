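"""Deterministic synthetic campaign data.

Every file the workflow consumes — library SDF, drop-target list, dispense
report, harvesting results, puck scans, per-dataset results — can be
generated from a seed, so the whole pipeline is testable with no external
data. The generator emulates the statistical shape of a real screening
campaign: a few hundred targeted drops, a small dispense-failure rate, a
small fishing-skip rate, a narrow unimodal resolution distribution
(truncated normal, nothing better than 0.9 Angstrom), an RSCC pass rate of
a few percent among diffracting datasets, and verification of most passers.
Default rates mirror a production campaign of ~560 soaked crystals with a
~7% RSCC pass rate and ~85% of passers verified.

Datasets diffracting worse than the resolution cutoff get no RSCC (ligand
density is not evaluated at low resolution), which keeps the outcome funnel
monotone by construction.
"""

from __future__ import annotations

import csv
import random
from dataclasses import dataclass
from datetime import datetime, timedelta
from pathlib import Path

from . import config
from .errors import CapacityError, FragflowError
from .harvest import (
    build_fishing_definition,
    merge_fishing_results,
    write_fishing_definition,
)
from .library import (
    Fragment,
    FragmentLibrary,
    read_library_sdf,
    write_library_sdf,
)
from .plates import PlateFormat, enumerate_wells, iter_crystal_drops, parse_crystal_well
from .soak import (
    DropTarget,
    SoakRecord,
    build_transfer_list,
    ingest_dispense_report,
)
from .stats import CampaignSummary, read_results_csv, summarize_campaign
from .store import CampaignStore

__all__ = ["FixtureSpec", "FRAGMENT_CATALOGUE", "make_library", "simulate_campaign", "run_pipeline"]

#: Built-in catalogue of small, rule-of-3-sized fragment SMILES. Cycled when
#: more fragments are requested than the catalogue holds (ids stay unique).
FRAGMENT_CATALOGUE: tuple[str, ...] = (
    "Cc1ccccc1",
    "Oc1ccccc1",
    "Nc1ccccc1",
    "OC(=O)c1ccccc1",
    "NC(=O)c1ccccc1",
    "COc1ccccc1",
    "Clc1ccccc1",
    "Fc1ccccc1",
    "Brc1ccccc1",
    "Cc1ccccc1O",
    "Nc1ccc(O)cc1",
    "Oc1ccc(Cl)cc1",
    "c1ccncc1",
    "Cc1ccncc1",
    "Nc1ccncc1",
    "OC(=O)c1ccncc1",
    "c1ccnnc1",
    "c1cnccn1",
    "c1ccc2[nH]ccc2c1",
    "c1ccc2occc2c1",
    "c1ccc2sccc2c1",
    "c1ccc2ncccc2c1",
    "c1cc[nH]c1",
    "c1ccoc1",
    "c1ccsc1",
    "c1cn[nH]c1",
    "c1cnc[nH]1",
    "Nc1nccs1",
    "NS(=O)(=O)c1ccccc1",
    "CC(=O)Nc1ccccc1",
    "O=C1CCCCC1",
    "OC1CCCCC1",
    "NC1CCCCC1",
    "C1CCNCC1",
    "C1CNCCN1",
    "C1COCCN1",
    "O=C1CCCO1",
    "O=C1CCCN1",
    "CC(=O)c1ccccc1",
    "OCc1ccccc1",
    "NCc1ccccc1",
    "OC(=O)C1CCCCC1",
    "Cn1ccnc1",
    "c1nc[nH]n1",
    "Nc1ncccn1",
    "Oc1ccncc1",
    "FC(F)(F)c1ccccc1",
    "N#Cc1ccccc1",
    "O=Cc1ccccc1",
    "CSc1ccccc1",
    "CC(=O)Nc1c(F)cccc1F",
    "CC1CCC(=O)O1",
)

_BASE_TIME = datetime(2024, 1, 15, 9, 0, 0)


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of a simulated campaign.

    Probabilities are per-event Bernoulli rates; resolutions are drawn from
    a normal distribution truncated below at 0.9 Angstrom; the RSCC pass
    rate applies to datasets at or better than the resolution cutoff.
    """

    seed: int = 0
    n_fragments: int = 48
    n_plates: int = 2
    drops_per_plate: int = 288
    dispense_fail_rate: float = 0.03
    fish_skip_rate: float = 0.03
    resolution_mean: float = 1.7
    resolution_sd: float = 0.2
    rscc_pass_rate: float = 0.075
    verify_given_pass_rate: float = 0.85
    transfer_nl: float = 25.0
    res_cutoff: float = 2.5
    rscc_threshold: float = 0.7

    def __post_init__(self) -> None:
        for name in (
            "dispense_fail_rate",
            "fish_skip_rate",
            "rscc_pass_rate",
            "verify_given_pass_rate",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise FragflowError(f"{name} must be in [0, 1], got {p}")
        for name in ("n_fragments", "n_plates", "drops_per_plate"):
            if getattr(self, name) <= 0:
                raise FragflowError(f"{name} must be positive")
        if self.drops_per_plate > config.CRYSTAL_PLATE.capacity:
            raise CapacityError(
                f"drops_per_plate {self.drops_per_plate} exceeds plate capacity "
                f"{config.CRYSTAL_PLATE.capacity}"
            )
        if self.resolution_sd <= 0:
            raise FragflowError("resolution_sd must be positive")


def make_library(
    spec: FixtureSpec, path: str | Path, plate_format: PlateFormat = PlateFormat.F384
) -> tuple[Path, FragmentLibrary]:
    """Write a deterministic library SDF: catalogue SMILES assigned to
    source wells row-major. The same spec always yields identical bytes."""
    wells = enumerate_wells(plate_format)
    if spec.n_fragments > len(wells):
        raise CapacityError(
            f"{spec.n_fragments} fragments exceed the {len(wells)}-well "
            f"source-plate capacity"
        )
    library = FragmentLibrary(name="synthetic", plate_format=plate_format)
    for i in range(spec.n_fragments):
        library.add(
            Fragment(
                fragment_id=f"FRAG{i + 1:04d}",
                smiles=FRAGMENT_CATALOGUE[i % len(FRAGMENT_CATALOGUE)],
                source_plate="LIB-001",
                source_well=wells[i],
                stock_conc_mm=100.0,
            )
        )
    out = write_library_sdf(library, path)
    # re-read so stored SMILES are the ingest-canonical ones
    return out, read_library_sdf(out, plate_format=plate_format, library_name="synthetic")


def _draw_resolution(rng: random.Random, spec: FixtureSpec) -> float:
    while True:  # truncation at 0.9 A: nothing diffracts better
        r = rng.gauss(spec.resolution_mean, spec.resolution_sd)
        if r > 0.9:
            return round(r, 2)


def simulate_campaign(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate the full consistent file set for one simulated campaign.

    Files: library.sdf, targets.csv, transfer_list.csv, dispense_report.csv,
    fishing_definition.csv, shifter_results.csv, puck_scan.csv,
    dataset_results.csv. All randomness comes from ``spec.seed``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)
    campaign = f"SIM{spec.seed}"

    sdf_path, library = make_library(spec, outdir / "library.sdf")
    frag_ids = sorted(library.ids())

    # drop targets with click offsets, fragments cycled over the library
    targets: list[tuple[DropTarget, str, float]] = []
    for p in range(spec.n_plates):
        barcode = f"XTAL-{p + 1:03d}"
        for well in list(iter_crystal_drops())[: spec.drops_per_plate]:
            offset = (round(rng.uniform(-0.5, 0.5), 3), round(rng.uniform(-0.5, 0.5), 3))
            fid = frag_ids[len(targets) % len(frag_ids)]
            targets.append(
                (DropTarget(plate_barcode=barcode, well=well, offset=offset), fid, spec.transfer_nl)
            )
    targets_path = outdir / "targets.csv"
    with open(targets_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["plate_barcode", "well", "x_offset_mm", "y_offset_mm", "fragment_id", "transfer_nl"])
        for t, fid, vol in targets:
            writer.writerow([t.plate_barcode, str(t.well), t.offset[0], t.offset[1], fid, vol])

    transfers = build_transfer_list(targets, library)
    transfers.to_csv(outdir / "transfer_list.csv")

    # dispense report: Bernoulli failures
    report_rows = []
    for t, fid, vol in targets:
        failed = rng.random() < spec.dispense_fail_rate
        report_rows.append(
            {
                "dest_barcode": t.plate_barcode,
                "dest_well": str(t.well),
                "status": "failed" if failed else "OK",
                "message": "no source volume" if failed else "",
            }
        )
    report_path = outdir / "dispense_report.csv"
    with open(report_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["dest_barcode", "dest_well", "status", "message"])
        writer.writeheader()
        writer.writerows(report_rows)

    # apply the report so downstream files reference dispensed soaks only
    planned = [
        SoakRecord(target=t, fragment_id=fid, transfer_nl=vol, soak_start=_BASE_TIME)
        for t, fid, vol in targets
    ]
    soaked, _ = ingest_dispense_report(planned, report_rows, _BASE_TIME + timedelta(minutes=30))
    fishing_rows = build_fishing_definition(soaked)
    write_fishing_definition(fishing_rows, outdir / "fishing_definition.csv")

    # harvesting: visit drops in fishing order, skip some
    shifter_rows = []
    t_fish = _BASE_TIME + timedelta(hours=2)
    n_fished = 0
    for row in fishing_rows:
        skipped = rng.random() < spec.fish_skip_rate
        shifter_rows.append(
            {
                "plate_barcode": row["plate_barcode"],
                "well": row["well"],
                "status": "skipped" if skipped else "fished",
                "timestamp": t_fish.isoformat(),
                "comment": "no crystal" if skipped else "",
            }
        )
        t_fish += timedelta(minutes=1)
        n_fished += 0 if skipped else 1
    with open(outdir / "shifter_results.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["plate_barcode", "well", "status", "timestamp", "comment"])
        writer.writeheader()
        writer.writerows(shifter_rows)

    # puck scans: one per fished crystal, 16 pins per puck
    scan_rows = []
    for k in range(n_fished):
        scan_rows.append(
            {
                "sequence": k + 1,
                "puck": f"PUCK-{k // config.PUCK_CAPACITY + 1:02d}",
                "pin": k % config.PUCK_CAPACITY + 1,
                "pin_barcode": "",
            }
        )
    with open(outdir / "puck_scan.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["sequence", "puck", "pin", "pin_barcode"])
        writer.writeheader()
        writer.writerows(scan_rows)

    # dataset results for every mounted crystal
    results_path = outdir / "dataset_results.csv"
    with open(results_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_name", "resolution", "rscc", "verified"])
        for row in shifter_rows:
            if row["status"] != "fished":
                continue
            sample = f"{campaign}-{row['plate_barcode']}-{row['well']}"
            res = _draw_resolution(rng, spec)
            if res <= spec.res_cutoff:
                if rng.random() < spec.rscc_pass_rate:
                    rscc = round(rng.uniform(spec.rscc_threshold, 0.95), 3)
                    verified = rng.random() < spec.verify_given_pass_rate
                else:
                    rscc = round(rng.uniform(0.2, spec.rscc_threshold - 0.01), 3)
                    verified = False
                writer.writerow([sample, res, rscc, "true" if verified else "false"])
            else:
                writer.writerow([sample, res, "", "false"])

    return {
        "library": sdf_path,
        "targets": targets_path,
        "transfer_list": outdir / "transfer_list.csv",
        "dispense_report": report_path,
        "fishing_definition": outdir / "fishing_definition.csv",
        "shifter_results": outdir / "shifter_results.csv",
        "puck_scan": outdir / "puck_scan.csv",
        "dataset_results": results_path,
    }


def _read_csv_dicts(path: Path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def run_pipeline(spec: FixtureSpec, workdir: str | Path) -> CampaignSummary:
    """End-to-end exercise of the whole workflow from one seed.

    Generates the synthetic file set, then consumes it exclusively through
    the public module interfaces: campaign bookkeeping, soak planning,
    dispense-report ingest, fishing, result merging, sample-sheet export
    and the final funnel summary.
    """
    workdir = Path(workdir)
    files = simulate_campaign(spec, workdir / "files")
    campaign = f"SIM{spec.seed}"

    store = CampaignStore(workdir / "store.jsonl", account="demo")
    store.create_campaign(campaign)
    for p in range(spec.n_plates):
        store.register_plate(campaign, f"XTAL-{p + 1:03d}")
    store.advance_stage(campaign, "Plates", "done")
    store.advance_stage(campaign, "Cryo", "skipped")
    store.advance_stage(campaign, "Soaking", "in_progress")

    library = read_library_sdf(files["library"], library_name="synthetic")
    planned = [
        SoakRecord(
            target=DropTarget(
                plate_barcode=row["plate_barcode"],
                well=parse_crystal_well(row["well"]),
                offset=(float(row["x_offset_mm"]), float(row["y_offset_mm"])),
            ),
            fragment_id=row["fragment_id"],
            transfer_nl=float(row["transfer_nl"]),
            soak_start=_BASE_TIME,
        )
        for row in _read_csv_dicts(files["targets"])
    ]
    build_transfer_list(
        [(s.target, s.fragment_id, s.transfer_nl) for s in planned], library
    )
    soaked, discrepancies = ingest_dispense_report(
        planned, _read_csv_dicts(files["dispense_report"]), _BASE_TIME + timedelta(minutes=30)
    )
    if discrepancies:
        raise FragflowError(f"{len(discrepancies)} unexplained dispense-report rows")
    store.advance_stage(campaign, "Soaking", "done")
    store.advance_stage(campaign, "Redissolve", "skipped")
    store.advance_stage(campaign, "Fishing", "in_progress")

    records, _warnings = merge_fishing_results(
        soaked,
        _read_csv_dicts(files["shifter_results"]),
        _read_csv_dicts(files["puck_scan"]),
    )
    from .harvest import export_collection_sheet

    export_collection_sheet(
        records,
        library,
        pipeline="gopy",
        mr_model="model.pdb",
        campaign=campaign,
        csv_path=workdir / "collection_sheet.csv",
    )
    store.advance_stage(campaign, "Fishing", "done")

    n_soaked = sum(1 for s in soaked if s.status == "dispensed")
    mounted = [r for r in records if r.status == "fished"]
    results = read_results_csv(files["dataset_results"])
    return summarize_campaign(
        n_soaked,
        mounted,
        results,
        res_cutoff=spec.res_cutoff,
        rscc_threshold=spec.rscc_threshold,
    )
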