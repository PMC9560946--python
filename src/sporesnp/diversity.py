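"""Intra-spore diversity statistics.

SNP counts partitioned by repeat/coding masks and the SNPs-per-kilobase
density over the non-repeat portion of the assembly. The density
denominator is exact interval arithmetic on the repeat mask, never a
rounded megabase figure.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .intervals import IntervalSet
from .model import ReferenceModel, Site

__all__ = [
    "DiversityReport",
    "count_outside_intervals",
    "count_inside_intervals",
    "compute_density",
    "round_half_up",
    "build_report",
]

REPORT_ROWS = (
    ("Total number of SNPs", "n_snps_total"),
    ("Number of SNPs non-rep", "n_snps_nonrepeat"),
    ("Number of SNPs coding region", "n_snps_coding"),
    ("Density SNP/kb", "density_rounded"),
)


@dataclass(frozen=True)
class DiversityReport:
    n_snps_total: int
    n_snps_nonrepeat: int
    n_snps_coding: int
    nonrepeat_size_bp: int
    density_snp_per_kb: float
    density_rounded: float

    def __post_init__(self) -> None:
        if self.n_snps_nonrepeat > self.n_snps_total:
            raise ValueError("non-repeat SNPs cannot exceed total SNPs")

    def to_tsv(self) -> str:
        lines = ["statistic\tvalue"]
        for label, attr in REPORT_ROWS:
            value = getattr(self, attr)
            lines.append(f"{label}\t{value}")
        return "\n".join(lines) + "\n"


def _group_positions(sites: Sequence[Site]) -> dict[str, np.ndarray]:
    grouped: dict[str, list[int]] = {}
    for s in sites:
        grouped.setdefault(s.contig, []).append(s.pos - 1)  # to 0-based
    return {c: np.asarray(p, dtype=np.int64) for c, p in grouped.items()}


def count_inside_intervals(snp_sites: Sequence[Site], intervals: IntervalSet) -> int:
    """Number of sites whose 0-based position falls inside the interval set."""
    total = 0
    for contig, pos0 in _group_positions(snp_sites).items():
        total += int(intervals.contains(contig, pos0).sum())
    return total


def count_outside_intervals(snp_sites: Sequence[Site], intervals: IntervalSet) -> int:
    """Complement of :func:`count_inside_intervals`; inside + outside = total."""
    return len(snp_sites) - count_inside_intervals(snp_sites, intervals)


def compute_density(n_snps_nonrepeat: int, nonrepeat_size_bp: int) -> float:
    """SNPs per kilobase of non-repeat sequence: 1000 * n / size."""
    if nonrepeat_size_bp <= 0:
        raise ValueError("nonrepeat_size_bp must be positive")
    if n_snps_nonrepeat < 0:
        raise ValueError("n_snps_nonrepeat must be non-negative")
    return 1000.0 * n_snps_nonrepeat / nonrepeat_size_bp


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round-half-up for display; binary-float half-even would misreport
    borderline densities."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def build_report(snp_sites: Sequence[Site], ref: ReferenceModel) -> DiversityReport:
    """Assemble the full diversity summary for one spore."""
    n_total = len(snp_sites)
    n_nonrep = count_outside_intervals(snp_sites, ref.repeat_intervals)
    n_coding = count_inside_intervals(snp_sites, ref.coding_intervals)
    if ref.nonrepeat_size_bp > 0:
        density = compute_density(n_nonrep, ref.nonrepeat_size_bp)
    else:
        density = 0.0
    return DiversityReport(
        n_snps_total=n_total,
        n_snps_nonrepeat=n_nonrep,
        n_snps_coding=n_coding,
        nonrepeat_size_bp=ref.nonrepeat_size_bp,
        density_snp_per_kb=density,
        density_rounded=round_half_up(density, 2),
    )
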