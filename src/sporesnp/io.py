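"""Readers and writers for the pipeline's plain-text formats.

Coordinates: VCF positions are 1-based inclusive, BED intervals are
0-based half-open; internal arithmetic is 0-based half-open with
conversion only here.
"""

from __future__ import annotations

import math
import os
from typing import Sequence

import numpy as np
from cyvcf2 import VCF

from .intervals import IntervalSet
from .model import (
    ALT,
    MISSING,
    REF,
    ObservationMatrix,
    ReferenceModel,
    Site,
    SiteAnnotations,
    SporeTruth,
    VariantSite,
)

__all__ = [
    "VcfParseError",
    "UnsupportedRecordError",
    "BedParseError",
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_truth_tsv",
    "write_truth_tsv",
    "read_reference_tsv",
    "write_reference_tsv",
]


class VcfParseError(ValueError):
    pass


class UnsupportedRecordError(VcfParseError):
    """Record outside the supported data model (e.g. multi-allelic)."""


class BedParseError(ValueError):
    pass


_INFO_FIELDS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum", "SOR")
_MANDATORY_INFO = ("QD", "FS", "MQ", "SOR")

_VCF_HEADER_META = """##fileformat=VCFv4.2
##INFO=<ID=QD,Number=1,Type=Float,Description="Variant confidence normalized by depth">
##INFO=<ID=FS,Number=1,Type=Float,Description="Phred-scaled strand bias Fisher test p-value">
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="Rank-sum of mapping qualities, alt vs ref reads">
##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="Rank-sum of read positions, alt vs ref reads">
##INFO=<ID=SOR,Number=1,Type=Float,Description="Symmetric odds ratio of strand bias">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth before allele-quality gating">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Gated read counts for ref and alt alleles">
"""


def _fmt_float(x: float) -> str:
    return format(float(x), ".6g")


def write_vcf(
    path: str | os.PathLike,
    obs: ObservationMatrix,
    ann: SiteAnnotations,
    ref: ReferenceModel | None = None,
) -> None:
    """Write a minimal VCF v4.2 with one sample column per nucleus.

    GT is the majority haploid call ("0"/"1", "." on zero depth or tie);
    DP is pre-gating depth; AD carries the gated ref,alt counts.
    """
    if obs.n_sites != ann.n_sites:
        raise ValueError("observations and annotations disagree on site count")
    lines = [_VCF_HEADER_META.rstrip("\n")]
    if ref is not None:
        lines.extend(
            f"##contig=<ID={contig},length={length}>" for contig, length in ref.contigs
        )
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                   "FORMAT", *obs.nucleus_ids]
    lines.append("\t".join(header_cols))

    for i, site in enumerate(obs.sites):
        info = [
            f"QD={_fmt_float(ann.qd[i])}",
            f"FS={_fmt_float(ann.fs[i])}",
            f"MQ={_fmt_float(ann.mq[i])}",
        ]
        if not ann.mq_rank_sum_missing[i]:
            info.append(f"MQRankSum={_fmt_float(ann.mq_rank_sum[i])}")
        if not ann.read_pos_rank_sum_missing[i]:
            info.append(f"ReadPosRankSum={_fmt_float(ann.read_pos_rank_sum[i])}")
        info.append(f"SOR={_fmt_float(ann.sor[i])}")
        row = [
            site.contig,
            str(site.pos),
            ".",
            site.ref,
            site.alt,
            _fmt_float(ann.qual[i]),
            ".",
            ";".join(info),
            "GT:DP:AD",
        ]
        for j in range(obs.n_nuclei):
            d = int(obs.depth[i, j])
            r = int(obs.ref_count[i, j])
            a = int(obs.alt_count[i, j])
            if d == 0 or r == a:
                gt = "."
            else:
                gt = "0" if r > a else "1"
            row.append(f"{gt}:{d}:{r},{a}")
        lines.append("\t".join(row))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_vcf(
    path: str | os.PathLike,
) -> tuple[ObservationMatrix, SiteAnnotations, list[str]]:
    """Load a VCF into the observation data model.

    Requires biallelic records with per-sample DP and AD; multi-allelic
    records are rejected explicitly. Missing rank-sum INFO entries are
    recorded as missing flags; a missing mandatory annotation is an error.
    """
    path = os.fspath(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    sites: list[Site] = []
    depth_rows, ref_rows, alt_rows = [], [], []
    ann_rows: dict[str, list] = {k: [] for k in
                                 ("qd", "fs", "mq", "mqrs", "mqrs_miss",
                                  "rprs", "rprs_miss", "qual", "sor")}
    for idx, rec in enumerate(vcf, start=1):
        where = f"{path} record {idx} ({rec.CHROM}:{rec.POS})"
        if len(rec.ALT) != 1:
            raise UnsupportedRecordError(
                f"{where}: expected exactly one ALT allele, got {len(rec.ALT)} "
                "(biallelic sites only)"
            )
        if rec.QUAL is None or not math.isfinite(rec.QUAL):
            raise VcfParseError(f"{where}: QUAL column must be populated")
        dp = rec.format("DP")
        ad = rec.format("AD")
        if dp is None or ad is None:
            raise VcfParseError(f"{where}: DP and AD FORMAT fields are required")
        dp = np.asarray(dp).reshape(len(samples))
        ad = np.asarray(ad).reshape(len(samples), -1)
        if ad.shape[1] != 2:
            raise UnsupportedRecordError(
                f"{where}: AD must carry exactly ref,alt counts"
            )
        # cyvcf2 encodes missing integers as large negatives
        dp = np.where(dp < 0, 0, dp)
        ad = np.where(ad < 0, 0, ad)

        def info_value(key: str) -> float | None:
            v = rec.INFO.get(key)
            return None if v is None else float(v)

        values = {k: info_value(k) for k in _INFO_FIELDS}
        for key in _MANDATORY_INFO:
            if values[key] is None:
                raise VcfParseError(f"{where}: mandatory INFO field {key} absent")

        sites.append(Site(rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
        depth_rows.append(dp.astype(np.int64))
        ref_rows.append(ad[:, 0].astype(np.int64))
        alt_rows.append(ad[:, 1].astype(np.int64))
        ann_rows["qd"].append(values["QD"])
        ann_rows["fs"].append(values["FS"])
        ann_rows["mq"].append(values["MQ"])
        ann_rows["sor"].append(values["SOR"])
        ann_rows["qual"].append(float(rec.QUAL))
        mqrs = values["MQRankSum"]
        ann_rows["mqrs"].append(np.nan if mqrs is None else mqrs)
        ann_rows["mqrs_miss"].append(mqrs is None)
        rprs = values["ReadPosRankSum"]
        ann_rows["rprs"].append(np.nan if rprs is None else rprs)
        ann_rows["rprs_miss"].append(rprs is None)

    n = len(sites)
    shape = (n, len(samples))
    obs = ObservationMatrix(
        sites=sites,
        depth=np.asarray(depth_rows, dtype=np.int64).reshape(shape),
        ref_count=np.asarray(ref_rows, dtype=np.int64).reshape(shape),
        alt_count=np.asarray(alt_rows, dtype=np.int64).reshape(shape),
        nucleus_ids=samples,
    )
    ann = SiteAnnotations(
        qd=np.asarray(ann_rows["qd"], dtype=float),
        fs=np.asarray(ann_rows["fs"], dtype=float),
        mq=np.asarray(ann_rows["mq"], dtype=float),
        mq_rank_sum=np.asarray(ann_rows["mqrs"], dtype=float),
        mq_rank_sum_missing=np.asarray(ann_rows["mqrs_miss"], dtype=bool),
        read_pos_rank_sum=np.asarray(ann_rows["rprs"], dtype=float),
        read_pos_rank_sum_missing=np.asarray(ann_rows["rprs_miss"], dtype=bool),
        qual=np.asarray(ann_rows["qual"], dtype=float),
        sor=np.asarray(ann_rows["sor"], dtype=float),
    )
    return obs, ann, samples


def read_bed(path: str | os.PathLike) -> IntervalSet:
    """Parse a 3+ column BED (0-based half-open) into a merged interval set."""
    records: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path} line {lineno}: fewer than 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path} line {lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                raise BedParseError(
                    f"{path} line {lineno}: end ({end}) must exceed start ({start})"
                )
            records.append((fields[0], start, end))
    return IntervalSet.from_records(records)


def write_bed(path: str | os.PathLike, intervals: IntervalSet) -> None:
    with open(path, "w") as fh:
        for contig, start, end in intervals.records():
            fh.write(f"{contig}\t{start}\t{end}\n")


def write_truth_tsv(path: str | os.PathLike, truth: SporeTruth) -> None:
    with open(path, "w") as fh:
        fh.write(f"#mode={truth.mode}\n")
        fh.write(f"#n_nuclei={truth.n_nuclei}\n")
        fh.write(f"#divergence_per_kb={truth.divergence_per_kb!r}\n")
        fh.write(f"#class_ratio={truth.class_ratio!r}\n")
        fh.write(f"#private_mut_per_kb={truth.private_mut_per_kb!r}\n")
        fh.write(f"#class_assignment={','.join(truth.class_assignment)}\n")
        fh.write("contig\tpos\tref\talt\tcarrier\n")
        for v in truth.variant_sites:
            fh.write(f"{v.contig}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.carrier}\n")


def read_truth_tsv(path: str | os.PathLike) -> SporeTruth:
    meta: dict[str, str] = {}
    variants: list[VariantSite] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                meta[key] = value
            elif line and not line.startswith("contig\t"):
                contig, pos, ref, alt, carrier = line.split("\t")
                variants.append(VariantSite(contig, int(pos), ref, alt, carrier))
    return SporeTruth(
        mode=meta["mode"],
        n_nuclei=int(meta["n_nuclei"]),
        divergence_per_kb=float(meta["divergence_per_kb"]),
        class_assignment=tuple(meta["class_assignment"].split(",")),
        class_ratio=float(meta["class_ratio"]),
        private_mut_per_kb=float(meta["private_mut_per_kb"]),
        variant_sites=tuple(variants),
    )


def write_reference_tsv(path: str | os.PathLike, ref: ReferenceModel) -> None:
    """Contig size table (the repeat/coding masks travel as BED)."""
    with open(path, "w") as fh:
        fh.write("contig\tlength\n")
        for contig, length in ref.contigs:
            fh.write(f"{contig}\t{length}\n")


def read_reference_tsv(
    path: str | os.PathLike,
    repeat_intervals: IntervalSet | None = None,
    coding_intervals: IntervalSet | None = None,
) -> ReferenceModel:
    contigs: list[tuple[str, int]] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("contig\t"):
            raise ValueError(f"{path}: expected 'contig\\tlength' header")
        for line in fh:
            if line.strip():
                contig, length = line.split("\t")
                contigs.append((contig, int(length)))
    return ReferenceModel(
        contigs=tuple(contigs),
        repeat_intervals=repeat_intervals or IntervalSet(),
        coding_intervals=coding_intervals or IntervalSet(),
    )
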