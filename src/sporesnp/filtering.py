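"""SNP post-processing chain for single-nucleus data.

Stage order is fixed: site-level hard filtering on quality annotations,
per-nucleus haploid genotype calling, masking of unreliable cells
(low depth and/or ambiguous allele fraction), cross-nucleus missingness
filtering, and finally SNP-site extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ALT, MISSING, REF, GenotypeMatrix, ObservationMatrix, Site, SiteAnnotations

__all__ = [
    "HardFilterThresholds",
    "NucleusMaskRule",
    "FilterReport",
    "DataError",
    "apply_site_hard_filters",
    "call_haploid_genotype",
    "call_genotypes",
    "mask_unreliable_cells",
    "filter_by_missingness",
    "extract_snp_sites",
    "run_filter_chain",
    "run_filter_chain_details",
    "ChainResult",
]


class DataError(ValueError):
    """Raised when mandatory input data are absent or malformed."""


@dataclass(frozen=True)
class HardFilterThresholds:
    """Hard-filter thresholds; all comparisons are strict, so a site whose
    annotation sits exactly on a threshold passes."""

    qd_min: float = 2.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0
    qual_min: float = 30.0
    sor_max: float = 3.0


@dataclass(frozen=True)
class NucleusMaskRule:
    """Cell-masking rule: low depth and/or ambiguous allele fraction.

    ``combine="AND"`` masks a cell only when both conditions hold (the
    literal reading of the filtering rule); ``"OR"`` masks on either.
    """

    min_depth: int = 5
    af_low: float = 0.1
    af_high: float = 0.9
    combine: str = "AND"

    def __post_init__(self) -> None:
        if not 0 <= self.af_low < self.af_high <= 1:
            raise ValueError("require 0 <= af_low < af_high <= 1")
        if self.combine not in ("AND", "OR"):
            raise ValueError(f"combine must be 'AND' or 'OR', got {self.combine!r}")


@dataclass
class FilterReport:
    """Per-stage accounting for one filter-chain run."""

    n_sites_input: int = 0
    n_failed_hard_filters: int = 0
    n_cells_masked: int = 0
    n_sites_removed_missingness: int = 0
    n_snp_sites: int = 0
    n_all_alt_sites: int = 0  # SNPs where every non-missing call is ALT

    def __post_init__(self) -> None:
        for name, value in vars(self).items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_snp_sites > self.n_sites_input:
            raise ValueError("n_snp_sites cannot exceed n_sites_input")


def apply_site_hard_filters(
    ann: SiteAnnotations, thr: HardFilterThresholds | None = None
) -> np.ndarray:
    """Return a per-site boolean pass flag.

    A site fails iff any annotation strictly violates its threshold.
    Missing rank-sum annotations never fail their test, matching how
    absent annotations behave in standard hard-filtering tools.
    """
    thr = thr or HardFilterThresholds()
    for name in ("qd", "fs", "mq", "qual", "sor"):
        if np.any(~np.isfinite(getattr(ann, name))):
            raise DataError(f"mandatory annotation {name.upper()} missing for some sites")

    fail = (
        (ann.qd < thr.qd_min)
        | (ann.fs > thr.fs_max)
        | (ann.mq < thr.mq_min)
        | (ann.qual < thr.qual_min)
        | (ann.sor > thr.sor_max)
    )
    mqrs_ok = ann.mq_rank_sum_missing
    fail |= ~mqrs_ok & (np.nan_to_num(ann.mq_rank_sum, nan=0.0) < thr.mqranksum_min)
    rprs_ok = ann.read_pos_rank_sum_missing
    fail |= ~rprs_ok & (
        np.nan_to_num(ann.read_pos_rank_sum, nan=0.0) < thr.readposranksum_min
    )
    return ~fail


def call_haploid_genotype(depth: int, ref_count: int, alt_count: int) -> int:
    """Majority-rule haploid call for one cell.

    Zero depth gives MISSING; an exact ref/alt tie with coverage also
    gives MISSING (a haploid call is indefensible at a 50/50 split).
    """
    if depth < 0 or ref_count < 0 or alt_count < 0:
        raise ValueError("counts must be non-negative")
    if ref_count + alt_count > depth:
        raise ValueError("ref_count + alt_count exceeds depth")
    if depth == 0:
        return MISSING
    if ref_count > alt_count:
        return REF
    if alt_count > ref_count:
        return ALT
    return MISSING


def call_genotypes(obs: ObservationMatrix) -> GenotypeMatrix:
    """Vectorized :func:`call_haploid_genotype` over a whole matrix."""
    calls = np.full(obs.depth.shape, MISSING, dtype=np.int8)
    calls[obs.ref_count > obs.alt_count] = REF
    calls[obs.alt_count > obs.ref_count] = ALT
    calls[obs.depth == 0] = MISSING
    return GenotypeMatrix(list(obs.sites), calls)


def mask_unreliable_cells(
    gt: GenotypeMatrix,
    obs: ObservationMatrix,
    rule: NucleusMaskRule | None = None,
) -> GenotypeMatrix:
    """Set unreliable cells to MISSING; never resurrects a masked cell.

    Allele fraction is alt/(ref+alt); with zero informative reads the
    ambiguity condition is false so depth alone governs. Band bounds are
    strict: AF exactly at ``af_low`` or ``af_high`` is not ambiguous.
    """
    rule = rule or NucleusMaskRule()
    if gt.calls.shape != obs.depth.shape:
        raise ValueError("genotype and observation matrices disagree on shape")

    informative = obs.ref_count + obs.alt_count
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(informative > 0, obs.alt_count / np.maximum(informative, 1), np.nan)
    low_depth = obs.depth < rule.min_depth
    ambiguous = (informative > 0) & (af > rule.af_low) & (af < rule.af_high)
    if rule.combine == "AND":
        mask = low_depth & ambiguous
    else:
        mask = low_depth | ambiguous
    out = gt.copy()
    out.calls[mask] = MISSING
    return out


def filter_by_missingness(
    gt: GenotypeMatrix,
    max_missing_fraction: float = 1 / 3,
    n_nuclei: int | None = None,
) -> tuple[np.ndarray, FilterReport]:
    """Drop sites whose missing fraction strictly exceeds the threshold.

    The denominator is all sequenced nuclei. The comparison is strict:
    exactly 3 missing of 9 nuclei survives the default 1/3 threshold.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    if n_nuclei is None:
        n_nuclei = gt.n_nuclei
    elif n_nuclei != gt.n_nuclei:
        raise ValueError(
            f"n_nuclei={n_nuclei} does not match matrix width {gt.n_nuclei}"
        )
    missing_frac = (gt.calls == MISSING).sum(axis=1) / n_nuclei
    retained = np.flatnonzero(missing_frac <= max_missing_fraction)
    report = FilterReport(
        n_sites_input=gt.n_sites,
        n_sites_removed_missingness=gt.n_sites - len(retained),
    )
    return retained, report


def extract_snp_sites(gt: GenotypeMatrix, retained: np.ndarray) -> list[Site]:
    """Retained sites with at least one non-missing ALT call, genomic order."""
    retained = np.sort(np.asarray(retained, dtype=np.int64))
    if len(retained) and (retained[0] < 0 or retained[-1] >= gt.n_sites):
        raise IndexError("retained index out of range")
    has_alt = (gt.calls[retained] == ALT).any(axis=1)
    return [gt.sites[i] for i in retained[has_alt]]


@dataclass
class ChainResult:
    """Everything the downstream stages need from one filter-chain run."""

    snp_sites: list[Site]
    report: FilterReport
    genotypes: GenotypeMatrix  # post-masking, sites passing hard filters
    retained: np.ndarray  # indices into ``genotypes`` surviving missingness
    observations: ObservationMatrix  # sites passing hard filters


def run_filter_chain(
    obs: ObservationMatrix,
    ann: SiteAnnotations,
    thresholds: HardFilterThresholds | None = None,
    rule: NucleusMaskRule | None = None,
    max_missing_fraction: float = 1 / 3,
) -> tuple[list[Site], FilterReport]:
    """Full chain: hard filters -> haploid calls -> cell mask ->
    missingness filter -> SNP extraction, with per-stage accounting."""
    result = run_filter_chain_details(obs, ann, thresholds, rule, max_missing_fraction)
    return result.snp_sites, result.report


def run_filter_chain_details(
    obs: ObservationMatrix,
    ann: SiteAnnotations,
    thresholds: HardFilterThresholds | None = None,
    rule: NucleusMaskRule | None = None,
    max_missing_fraction: float = 1 / 3,
) -> ChainResult:
    if obs.n_sites != ann.n_sites:
        raise ValueError("observations and annotations disagree on site count")
    n_input = obs.n_sites

    passed = apply_site_hard_filters(ann, thresholds)
    obs_pass = obs.subset_sites(passed)

    gt = call_genotypes(obs_pass)
    masked = mask_unreliable_cells(gt, obs_pass, rule)
    n_cells_masked = int(((gt.calls != MISSING) & (masked.calls == MISSING)).sum())

    retained, miss_report = filter_by_missingness(masked, max_missing_fraction)
    snps = extract_snp_sites(masked, retained)

    snp_idx = {s: i for i, s in enumerate(masked.sites)}
    n_all_alt = 0
    for s in snps:
        calls = masked.calls[snp_idx[s]]
        nonmiss = calls[calls != MISSING]
        if len(nonmiss) and (nonmiss == ALT).all():
            n_all_alt += 1

    report = FilterReport(
        n_sites_input=n_input,
        n_failed_hard_filters=int(n_input - passed.sum()),
        n_cells_masked=n_cells_masked,
        n_sites_removed_missingness=miss_report.n_sites_removed_missingness,
        n_snp_sites=len(snps),
        n_all_alt_sites=n_all_alt,
    )
    return ChainResult(
        snp_sites=snps,
        report=report,
        genotypes=masked,
        retained=retained,
        observations=obs_pass,
    )
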