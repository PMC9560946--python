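"""Synthetic multinucleate-spore data generator.

Produces reference models, nucleus populations (homokaryotic or
heterokaryotic), and per-nucleus read observations with the statistical
structure the downstream filters assume: whole-genome-amplification-style
overdispersed depth with locus dropout, per-read error, quality gating,
and site-level quality annotations with a tunable hard-filter violation
fraction. Ground truth is retained for parameter-recovery testing.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np

from .intervals import IntervalSet
from .model import (
    ObservationMatrix,
    ReferenceModel,
    Site,
    SiteAnnotations,
    SporeTruth,
    VariantSite,
)

__all__ = [
    "ObsParams",
    "CallerParams",
    "simulate_reference",
    "simulate_nucleus_population",
    "simulate_observations",
    "export_fixture",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ObsParams:
    """Observation-process parameters for one simulated sequencing run.

    ``depth_dispersion`` is the lognormal sigma of per-(site, nucleus)
    depth; ``dropout_rate`` models amplification unevenness as independent
    per-(site, nucleus) total locus dropout.
    """

    mean_depth: float = 30.0
    depth_dispersion: float = 0.5
    dropout_rate: float = 0.0
    error_rate: float = 0.0
    mq_below_gate_rate: float = 0.0
    bq_below_gate_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.depth_dispersion <= 0:
            raise ValueError("depth_dispersion must be positive")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must be in [0, 1]")
        for name in ("error_rate", "mq_below_gate_rate", "bq_below_gate_rate"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must be in [0, 1)")


@dataclass(frozen=True)
class CallerParams:
    """Variant-caller gates emulated by the observation process."""

    ploidy: int = 1
    min_mapping_quality: int = 30
    min_base_quality: int = 20
    max_alternate_alleles: int = 1

    def __post_init__(self) -> None:
        if self.ploidy != 1:
            raise ValueError("only haploid calling is supported")
        if self.max_alternate_alleles != 1:
            raise ValueError("only biallelic sites are supported")


def _split_positive(rng: np.random.Generator, total: int, k: int) -> np.ndarray:
    """Split ``total`` into k positive integer parts, uniformly at random."""
    k = min(k, total)
    parts = rng.multinomial(total - k, np.full(k, 1.0 / k)) + 1
    return parts


def _split_nonnegative(rng: np.random.Generator, total: int, k: int) -> np.ndarray:
    if total == 0:
        return np.zeros(k, dtype=np.int64)
    return rng.multinomial(total, np.full(k, 1.0 / k))


def _place_intervals(
    rng: np.random.Generator, contig_len: int, target_bp: int, mean_len: int = 2000
) -> list[tuple[int, int]]:
    """Place non-overlapping intervals with lengths summing to target_bp."""
    if target_bp <= 0:
        return []
    k = max(1, int(round(target_bp / mean_len)))
    lens = _split_positive(rng, target_bp, k)
    gaps = _split_nonnegative(rng, contig_len - target_bp, len(lens) + 1)
    out = []
    pos = 0
    for g, ln in zip(gaps[:-1], lens):
        pos += int(g)
        out.append((pos, pos + int(ln)))
        pos += int(ln)
    return out


def simulate_reference(
    total_len_bp: int,
    n_contigs: int,
    repeat_fraction: float,
    coding_fraction: float,
    seed: int,
) -> ReferenceModel:
    """Draw a reference model with the requested repeat/coding content.

    Repeat intervals are placed with exact per-contig bp budgets, so the
    realized repeat fraction deviates from the request only by per-contig
    rounding (well under 1% for genomes >= 100 kb). Coding intervals are
    placed inside non-repeat segments.
    """
    if total_len_bp <= 0 or n_contigs <= 0:
        raise ValueError("total_len_bp and n_contigs must be positive")
    if total_len_bp < n_contigs:
        raise ValueError("total_len_bp must be >= n_contigs")
    if not 0 <= repeat_fraction < 1 or not 0 <= coding_fraction < 1:
        raise ValueError("fractions must be in [0, 1)")
    if repeat_fraction + coding_fraction >= 1:
        raise ValueError("repeat_fraction + coding_fraction must be < 1")

    rng = np.random.default_rng(seed)
    if n_contigs == 1:
        lengths = np.array([total_len_bp], dtype=np.int64)
    else:
        cuts = rng.choice(total_len_bp - 1, size=n_contigs - 1, replace=False) + 1
        cuts.sort()
        lengths = np.diff(np.concatenate(([0], cuts, [total_len_bp])))
    contigs = tuple(
        (f"contig_{i + 1}", int(length)) for i, length in enumerate(lengths)
    )

    repeat_records: list[tuple[str, int, int]] = []
    coding_records: list[tuple[str, int, int]] = []
    coding_density = coding_fraction / (1 - repeat_fraction)
    for name, length in contigs:
        target_rep = int(round(repeat_fraction * length))
        placed = _place_intervals(rng, length, target_rep)
        repeat_records.extend((name, s, e) for s, e in placed)
        # coding lives in the gaps between repeats
        gaps: list[tuple[int, int]] = []
        prev = 0
        for s, e in placed:
            if s > prev:
                gaps.append((prev, s))
            prev = e
        if prev < length:
            gaps.append((prev, length))
        for gs, ge in gaps:
            c = int(round(coding_density * (ge - gs)))
            if c <= 0:
                continue
            c = min(c, ge - gs)
            off = int(rng.integers(0, ge - gs - c + 1))
            coding_records.append((name, gs + off, gs + off + c))

    return ReferenceModel(
        contigs=contigs,
        repeat_intervals=IntervalSet.from_records(repeat_records),
        coding_intervals=IntervalSet.from_records(coding_records),
    )


def _offsets_to_sites(ref: ReferenceModel, offsets: np.ndarray) -> list[tuple[str, int]]:
    """Map global 0-based genome offsets to (contig, 1-based pos)."""
    names = [c for c, _ in ref.contigs]
    bounds = np.cumsum([0] + [length for _, length in ref.contigs])
    idx = np.searchsorted(bounds, offsets, side="right") - 1
    return [(names[i], int(off - bounds[i]) + 1) for i, off in zip(idx, offsets)]


def simulate_nucleus_population(
    ref: ReferenceModel,
    n_nuclei: int,
    mode: str,
    divergence_per_kb: float = 0.0,
    class_ratio: float = 0.5,
    private_mut_per_kb: float = 0.0,
    seed: int = 0,
) -> SporeTruth:
    """Draw a nucleus population and its true variant sites.

    Heterokaryon mode places Poisson(divergence_per_kb * total_kb) fixed
    differences at uniform unique positions, each carried by exactly one
    haplotype class; class sizes are binomial(n_nuclei, class_ratio),
    resampled until both classes are non-empty. Private mutations are
    placed independently per nucleus in both modes.
    """
    if n_nuclei < 2:
        raise ValueError("n_nuclei must be >= 2")
    if mode not in ("homokaryon", "heterokaryon"):
        raise ValueError(f"unknown mode {mode!r}")
    if divergence_per_kb < 0 or private_mut_per_kb < 0:
        raise ValueError("mutation densities must be >= 0")
    if mode == "heterokaryon" and not 0 < class_ratio < 1:
        raise ValueError("class_ratio must be in (0, 1)")

    rng = np.random.default_rng(seed)
    total_kb = ref.total_size_bp / 1000.0

    labels = np.full(n_nuclei, "A", dtype="U1")
    n_div = 0
    if mode == "heterokaryon":
        while True:
            n_a = int(rng.binomial(n_nuclei, class_ratio))
            if 0 < n_a < n_nuclei:
                break
        perm = rng.permutation(n_nuclei)
        labels[perm[n_a:]] = "B"
        n_div = int(rng.poisson(divergence_per_kb * total_kb))
    else:
        divergence_per_kb = 0.0

    # private_mut_per_kb is the spore-level density of private (singleton)
    # mutations; each is carried by one uniformly chosen nucleus. This keeps
    # the realized SNP density comparable across nucleus counts.
    n_priv = int(rng.poisson(private_mut_per_kb * total_kb))
    n_total = n_div + n_priv
    offsets = rng.choice(ref.total_size_bp, size=n_total, replace=False)
    positions = _offsets_to_sites(ref, offsets)

    ref_alleles = _BASES[rng.integers(0, 4, size=n_total)]
    alt_shift = rng.integers(1, 4, size=n_total)
    alt_alleles = _BASES[
        (np.searchsorted(_BASES, ref_alleles) + alt_shift) % 4
    ]

    carriers: list[str] = []
    div_classes = rng.choice(["A", "B"], size=n_div)
    carriers.extend(f"class:{c}" for c in div_classes)
    carriers.extend(
        f"nucleus:{int(j)}" for j in rng.integers(0, n_nuclei, size=n_priv)
    )

    order = {name: i for i, (name, _) in enumerate(ref.contigs)}
    variants = sorted(
        (
            VariantSite(contig, pos, str(r), str(a), carrier)
            for (contig, pos), r, a, carrier in zip(
                positions, ref_alleles, alt_alleles, carriers
            )
        ),
        key=lambda v: (order[v.contig], v.pos),
    )
    return SporeTruth(
        mode=mode,
        n_nuclei=n_nuclei,
        divergence_per_kb=float(divergence_per_kb),
        class_assignment=tuple(str(x) for x in labels),
        class_ratio=float(class_ratio),
        private_mut_per_kb=float(private_mut_per_kb),
        variant_sites=tuple(variants),
    )


def _draw_annotations(
    rng: np.random.Generator,
    n_sites: int,
    violation_rate: float,
    ranksum_missing_rate: float,
) -> SiteAnnotations:
    """Sample site annotations; a ``violation_rate`` fraction of sites gets
    one annotation pushed past its hard-filter threshold."""
    qd = rng.uniform(5, 35, n_sites)
    fs = rng.uniform(0, 10, n_sites)
    mq = rng.uniform(50, 60, n_sites)
    mqrs = np.clip(rng.normal(0, 1.5, n_sites), -8, None)
    rprs = np.clip(rng.normal(0, 1.5, n_sites), -4, None)
    qual = rng.uniform(100, 2000, n_sites)
    sor = rng.uniform(0.3, 2.0, n_sites)

    violate = rng.random(n_sites) < violation_rate
    which = rng.integers(0, 7, n_sites)
    for i in np.flatnonzero(violate):
        w = which[i]
        if w == 0:
            qd[i] = rng.uniform(0, 1.99)
        elif w == 1:
            fs[i] = rng.uniform(60.01, 200)
        elif w == 2:
            mq[i] = rng.uniform(0, 39.9)
        elif w == 3:
            mqrs[i] = rng.uniform(-30, -12.51)
        elif w == 4:
            rprs[i] = rng.uniform(-20, -8.01)
        elif w == 5:
            qual[i] = rng.uniform(0, 29.9)
        else:
            sor[i] = rng.uniform(3.01, 10)

    mqrs_missing = rng.random(n_sites) < ranksum_missing_rate
    rprs_missing = rng.random(n_sites) < ranksum_missing_rate
    # missing rank-sums never fail their test, so suppress the violation there
    mqrs_missing[violate & (which == 3)] = False
    rprs_missing[violate & (which == 4)] = False
    mqrs[mqrs_missing] = np.nan
    rprs[rprs_missing] = np.nan
    return SiteAnnotations(
        qd=qd,
        fs=fs,
        mq=mq,
        mq_rank_sum=mqrs,
        mq_rank_sum_missing=mqrs_missing,
        read_pos_rank_sum=rprs,
        read_pos_rank_sum_missing=rprs_missing,
        qual=qual,
        sor=sor,
    )


def simulate_observations(
    truth: SporeTruth,
    ref: ReferenceModel,
    obs: ObsParams,
    caller: CallerParams | None = None,
    seed: int = 0,
    n_decoy_sites: int | None = None,
    annotation_violation_rate: float = 0.05,
    ranksum_missing_rate: float = 0.1,
) -> tuple[ObservationMatrix, SiteAnnotations]:
    """Simulate per-nucleus read counts and site annotations.

    Depth at each (site, nucleus) is 0 with probability ``dropout_rate``,
    else rounded lognormal with mean ``mean_depth``. Reads failing the
    mapping/base-quality gates are discarded before allele counting
    (``ref_count + alt_count <= depth``); each surviving read reports the
    nucleus's true allele with probability ``1 - error_rate``. Decoy sites
    (no true alt carrier anywhere) default to 10x the variant count.
    """
    caller = caller or CallerParams()
    rng = np.random.default_rng(seed)
    n_var = len(truth.variant_sites)
    if n_decoy_sites is None:
        n_decoy_sites = 10 * n_var
    if n_decoy_sites < 0:
        raise ValueError("n_decoy_sites must be >= 0")

    taken = {
        (v.contig, v.pos) for v in truth.variant_sites
    }
    decoys: list[VariantSite] = []
    while len(decoys) < n_decoy_sites:
        need = n_decoy_sites - len(decoys)
        offsets = rng.integers(0, ref.total_size_bp, size=2 * need + 8)
        for contig, pos in _offsets_to_sites(ref, offsets):
            if (contig, pos) in taken:
                continue
            taken.add((contig, pos))
            r, a = rng.choice(4, size=2, replace=False)
            decoys.append(
                VariantSite(contig, pos, str(_BASES[r]), str(_BASES[a]), "none")
            )
            if len(decoys) == n_decoy_sites:
                break

    order = {name: i for i, (name, _) in enumerate(ref.contigs)}
    all_variants = sorted(
        list(truth.variant_sites) + decoys, key=lambda v: (order[v.contig], v.pos)
    )
    sites = [v.site for v in all_variants]
    n_sites = len(sites)
    n_nuclei = truth.n_nuclei

    labels = np.asarray(truth.class_assignment)
    is_alt = np.zeros((n_sites, n_nuclei), dtype=bool)
    for i, v in enumerate(all_variants):
        kind, _, value = v.carrier.partition(":")
        if kind == "class":
            is_alt[i] = labels == value
        elif kind == "nucleus":
            is_alt[i, int(value)] = True

    shape = (n_sites, n_nuclei)
    mu = np.log(obs.mean_depth) - obs.depth_dispersion**2 / 2
    depth = np.rint(rng.lognormal(mu, obs.depth_dispersion, size=shape)).astype(
        np.int64
    )
    depth[rng.random(shape) < obs.dropout_rate] = 0

    p_survive = (1 - obs.mq_below_gate_rate) * (1 - obs.bq_below_gate_rate)
    surviving = rng.binomial(depth, p_survive)
    p_alt = np.where(is_alt, 1 - obs.error_rate, obs.error_rate)
    alt_count = rng.binomial(surviving, p_alt)
    ref_count = surviving - alt_count

    matrix = ObservationMatrix(
        sites=sites,
        depth=depth,
        ref_count=ref_count,
        alt_count=alt_count,
        nucleus_ids=[f"nucleus_{i}" for i in range(n_nuclei)],
    )
    annotations = _draw_annotations(
        rng, n_sites, annotation_violation_rate, ranksum_missing_rate
    )
    return matrix, annotations


def export_fixture(
    truth: SporeTruth,
    obs_matrix: ObservationMatrix,
    annotations: SiteAnnotations,
    ref: ReferenceModel,
    out_dir: str | os.PathLike,
) -> dict[str, str]:
    """Write a complete plain-text fixture: VCF, BED masks, truth and
    reference TSVs. Round-trips exactly through :mod:`sporesnp.io`."""
    from . import io as spio  # deferred: io imports model, not synthetic

    if obs_matrix.n_sites != annotations.n_sites:
        raise ValueError("observation matrix and annotations disagree on sites")
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    paths = {
        "vcf": os.path.join(out, "observations.vcf"),
        "repeats_bed": os.path.join(out, "repeats.bed"),
        "coding_bed": os.path.join(out, "coding.bed"),
        "truth_tsv": os.path.join(out, "truth.tsv"),
        "reference_tsv": os.path.join(out, "reference.tsv"),
    }
    spio.write_vcf(paths["vcf"], obs_matrix, annotations, ref)
    spio.write_bed(paths["repeats_bed"], ref.repeat_intervals)
    spio.write_bed(paths["coding_bed"], ref.coding_intervals)
    spio.write_truth_tsv(paths["truth_tsv"], truth)
    spio.write_reference_tsv(paths["reference_tsv"], ref)
    return paths
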