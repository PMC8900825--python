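"""Campaign outcome statistics.

A screening campaign is summarized as a funnel:

    soaked >= mounted >= diffracting (res <= cutoff)
           >= RSCC-pass (rscc >= threshold) >= verified

with every percentage relative to the number of crystals soaked.
Crystal-level percentages (mounted, diffracting) are printed as whole
percent, dataset-level ones (RSCC pass, verified) to one decimal, both
rounded half away from zero. The real-space correlation coefficient (RSCC)
between a fitted ligand and its electron density comes from external
fitting software; the triage threshold is inclusive (rscc >= 0.7 passes).
Verification of a protein-fragment complex is a human judgement and enters
as an input flag.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

from .errors import FragflowError

__all__ = [
    "DatasetResult",
    "CampaignSummary",
    "summarize_campaign",
    "rscc_filter",
    "resolution_histogram",
    "read_results_csv",
]


@dataclass(frozen=True)
class DatasetResult:
    """Outcome of one collected and processed dataset."""

    sample_name: str
    resolution: float | None = None  # high-resolution cutoff, Angstrom
    rscc: float | None = None
    verified: bool = False

    def __post_init__(self) -> None:
        if self.resolution is not None and self.resolution <= 0:
            raise FragflowError(
                f"{self.sample_name}: resolution must be positive, "
                f"got {self.resolution}"
            )
        if self.rscc is not None and not -1.0 <= self.rscc <= 1.0:
            raise FragflowError(
                f"{self.sample_name}: RSCC {self.rscc} outside [-1, 1]"
            )


def _pct(numerator: int, denominator: int, decimals: int) -> float | int:
    """Percentage rounded half away from zero to ``decimals`` places.

    Exact decimal arithmetic: 100*num/den is quantized, never a float
    intermediate, so printed-precision agreement is reproducible.
    """
    q = Decimal(1).scaleb(-decimals)
    value = (Decimal(100 * numerator) / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP
    )
    return int(value) if decimals == 0 else float(value)


@dataclass(frozen=True)
class CampaignSummary:
    """Funnel counts and the percentages as they would be printed."""

    n_soaked: int
    n_mounted: int
    n_diffracting: int
    n_rscc_pass: int
    n_verified: int
    pct_mounted: int
    pct_diffracting: int
    pct_rscc_pass: float
    pct_verified: float
    res_cutoff: float = 2.5
    rscc_threshold: float = 0.7

    @classmethod
    def from_counts(
        cls,
        n_soaked: int,
        n_mounted: int,
        n_diffracting: int,
        n_rscc_pass: int,
        n_verified: int,
        res_cutoff: float = 2.5,
        rscc_threshold: float = 0.7,
    ) -> "CampaignSummary":
        if n_soaked <= 0:
            raise FragflowError("n_soaked must be positive")
        counts = (n_soaked, n_mounted, n_diffracting, n_rscc_pass, n_verified)
        names = ("soaked", "mounted", "diffracting", "RSCC-pass", "verified")
        for (a, an), (b, bn) in zip(zip(counts, names), zip(counts[1:], names[1:])):
            if b > a:
                raise FragflowError(
                    f"funnel not monotone: {bn} count {b} exceeds {an} count {a}"
                )
        if any(c < 0 for c in counts):
            raise FragflowError("funnel counts must be non-negative")
        return cls(
            n_soaked=n_soaked,
            n_mounted=n_mounted,
            n_diffracting=n_diffracting,
            n_rscc_pass=n_rscc_pass,
            n_verified=n_verified,
            pct_mounted=_pct(n_mounted, n_soaked, 0),
            pct_diffracting=_pct(n_diffracting, n_soaked, 0),
            pct_rscc_pass=_pct(n_rscc_pass, n_soaked, 1),
            pct_verified=_pct(n_verified, n_soaked, 1),
            res_cutoff=res_cutoff,
            rscc_threshold=rscc_threshold,
        )

    def as_rows(self) -> list[tuple[str, int, str]]:
        return [
            ("crystals soaked", self.n_soaked, "100%"),
            ("crystals mounted", self.n_mounted, f"{self.pct_mounted}%"),
            (
                f"diffracting to <={self.res_cutoff} A",
                self.n_diffracting,
                f"{self.pct_diffracting}%",
            ),
            (
                f"datasets with RSCC >= {self.rscc_threshold}",
                self.n_rscc_pass,
                f"{self.pct_rscc_pass}%",
            ),
            ("verified complexes", self.n_verified, f"{self.pct_verified}%"),
        ]

    def to_markdown(self) -> str:
        lines = ["| stage | count | % of soaked |", "| --- | --- | --- |"]
        lines += [f"| {s} | {c} | {p} |" for s, c, p in self.as_rows()]
        return "\n".join(lines)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["stage", "count", "pct_of_soaked"])
            writer.writerows(self.as_rows())
        return path


def rscc_filter(
    results: Sequence[DatasetResult], threshold: float = 0.7
) -> list[DatasetResult]:
    """Datasets passing the RSCC triage: rscc >= threshold, inclusive;
    datasets without an RSCC value are excluded."""
    if not 0.0 <= threshold <= 1.0:
        raise FragflowError(f"RSCC threshold {threshold} outside [0, 1]")
    return [r for r in results if r.rscc is not None and r.rscc >= threshold]


def summarize_campaign(
    n_soaked: int,
    mounted: Sequence,
    results: Sequence[DatasetResult],
    res_cutoff: float = 2.5,
    rscc_threshold: float = 0.7,
) -> CampaignSummary:
    """Build the campaign funnel from raw per-sample results.

    ``mounted`` is the list of mounted crystals (only its length is used);
    ``results`` the processed datasets. Diffracting counts datasets with
    resolution <= ``res_cutoff``; RSCC pass and verified are counted over
    all datasets and must respect the funnel order, otherwise the inputs
    are inconsistent and an error is raised.
    """
    if n_soaked <= 0:
        raise FragflowError("n_soaked must be positive")
    if not n_soaked >= len(mounted) >= len(results):
        raise FragflowError(
            f"funnel not monotone: soaked {n_soaked}, mounted {len(mounted)}, "
            f"datasets {len(results)}"
        )
    n_diffracting = sum(
        1 for r in results if r.resolution is not None and r.resolution <= res_cutoff
    )
    passing = rscc_filter(results, rscc_threshold)
    n_verified = sum(1 for r in passing if r.verified)
    return CampaignSummary.from_counts(
        n_soaked=n_soaked,
        n_mounted=len(mounted),
        n_diffracting=n_diffracting,
        n_rscc_pass=len(passing),
        n_verified=n_verified,
        res_cutoff=res_cutoff,
        rscc_threshold=rscc_threshold,
    )


def resolution_histogram(
    resolutions: Sequence[float], bin_width: float = 0.1
) -> list[tuple[float, int]]:
    """Histogram of dataset resolutions in half-open bins [lo, lo + w).

    Bin edges are multiples of the bin width; interior empty bins are kept,
    leading/trailing ones never appear. Counts sum to the input length.
    """
    if bin_width <= 0:
        raise FragflowError(f"bin width must be positive, got {bin_width}")
    if not resolutions:
        return []
    for r in resolutions:
        if r <= 0:
            raise FragflowError(f"resolution must be positive, got {r}")
    # round before floor so values sitting on an edge (1.5/0.1) bin right
    indices = [math.floor(round(r / bin_width, 9)) for r in resolutions]
    counts: dict[int, int] = {}
    for i in indices:
        counts[i] = counts.get(i, 0) + 1
    lo, hi = min(counts), max(counts)
    return [(round(i * bin_width, 9), counts.get(i, 0)) for i in range(lo, hi + 1)]


def write_histogram_csv(
    bins: Sequence[tuple[float, int]], path: str | Path, bin_width: float = 0.1
) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["bin_lower_A", "bin_upper_A", "count"])
        for lo, count in bins:
            writer.writerow([lo, round(lo + bin_width, 9), count])
    return path


def read_results_csv(path: str | Path) -> list[DatasetResult]:
    """Read a per-sample results table (sample_name, resolution, rscc,
    verified); empty cells become missing values."""
    results = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            results.append(
                DatasetResult(
                    sample_name=row["sample_name"],
                    resolution=float(row["resolution"]) if row.get("resolution") else None,
                    rscc=float(row["rscc"]) if row.get("rscc") else None,
                    verified=str(row.get("verified", "")).strip().lower()
                    in ("1", "true", "yes"),
                )
            )
    return results
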