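"""Shared domain objects for the single-nucleus SNP pipeline.

The pipeline transforms per-(site, nucleus) read evidence
(:class:`ObservationMatrix`) into haploid calls (:class:`GenotypeMatrix`)
under site-level quality annotations (:class:`SiteAnnotations`), relative
to a reference assembly model (:class:`ReferenceModel`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .intervals import IntervalSet

__all__ = [
    "REF",
    "ALT",
    "MISSING",
    "Site",
    "VariantSite",
    "ReferenceModel",
    "SporeTruth",
    "ObservationMatrix",
    "SiteAnnotations",
    "GenotypeMatrix",
]

# Genotype call codes used throughout (int8 matrices).
REF: int = 0
ALT: int = 1
MISSING: int = -1


class Site(NamedTuple):
    """One candidate variant site; ``pos`` is 1-based as in VCF."""

    contig: str
    pos: int
    ref: str
    alt: str


@dataclass(frozen=True)
class VariantSite:
    """A true variant and its carrier.

    ``carrier`` is ``"class:A"``/``"class:B"`` for fixed differences between
    haplotype classes, or ``"nucleus:<index>"`` for a private mutation.
    """

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    carrier: str

    @property
    def site(self) -> Site:
        return Site(self.contig, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class ReferenceModel:
    """Contig sizes plus repeat/coding masks; density denominator source."""

    contigs: tuple[tuple[str, int], ...]
    repeat_intervals: IntervalSet = field(default_factory=IntervalSet)
    coding_intervals: IntervalSet = field(default_factory=IntervalSet)

    def __post_init__(self) -> None:
        lengths = dict(self.contigs)
        if any(length <= 0 for length in lengths.values()):
            raise ValueError("contig lengths must be positive")
        for name, ivs in (("repeat", self.repeat_intervals),
                          ("coding", self.coding_intervals)):
            for contig in ivs.contigs():
                if contig not in lengths:
                    raise ValueError(f"{name} interval on unknown contig {contig!r}")
                if ivs.max_end(contig) > lengths[contig]:
                    raise ValueError(
                        f"{name} interval exceeds length of contig {contig!r}"
                    )
        if self.nonrepeat_size_bp < 0:
            raise ValueError("repeat size exceeds genome size")

    @property
    def total_size_bp(self) -> int:
        return int(sum(length for _, length in self.contigs))

    @property
    def repeat_size_bp(self) -> int:
        return self.repeat_intervals.total_length

    @property
    def nonrepeat_size_bp(self) -> int:
        return self.total_size_bp - self.repeat_size_bp

    def contig_lengths(self) -> dict[str, int]:
        return dict(self.contigs)


@dataclass(frozen=True)
class SporeTruth:
    """Ground truth for one simulated multinucleate spore."""

    mode: str  # "homokaryon" | "heterokaryon"
    n_nuclei: int
    divergence_per_kb: float
    class_assignment: tuple[str, ...]  # per-nucleus "A"/"B"
    class_ratio: float
    private_mut_per_kb: float
    variant_sites: tuple[VariantSite, ...]

    def __post_init__(self) -> None:
        if self.mode not in ("homokaryon", "heterokaryon"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.class_assignment) != self.n_nuclei:
            raise ValueError("class_assignment length != n_nuclei")
        if self.mode == "homokaryon":
            if self.divergence_per_kb != 0:
                raise ValueError("homokaryon requires divergence_per_kb = 0")
            if len(set(self.class_assignment)) > 1:
                raise ValueError("homokaryon requires a single class label")
        seen: set[tuple[str, int]] = set()
        for v in self.variant_sites:
            key = (v.contig, v.pos)
            if key in seen:
                raise ValueError(f"duplicate variant position {key}")
            seen.add(key)

    def is_alt_matrix(self) -> np.ndarray:
        """Boolean (n_sites, n_nuclei): does nucleus j truly carry alt at site i."""
        out = np.zeros((len(self.variant_sites), self.n_nuclei), dtype=bool)
        labels = np.asarray(self.class_assignment)
        for i, v in enumerate(self.variant_sites):
            kind, _, value = v.carrier.partition(":")
            if kind == "class":
                out[i] = labels == value
            elif kind == "nucleus":
                out[i, int(value)] = True
            else:
                raise ValueError(f"unknown carrier {v.carrier!r}")
        return out


def _as_count_matrix(a: np.ndarray, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=np.int64)
    if a.ndim != 2:
        raise ValueError(f"{name} must be 2-D")
    if np.any(a < 0):
        raise ValueError(f"{name} must be non-negative")
    return a


@dataclass
class ObservationMatrix:
    """Per-(site, nucleus) read evidence after quality gating.

    ``ref_count + alt_count <= depth``; the gap is reads discarded by the
    mapping/base-quality gates.
    """

    sites: list[Site]
    depth: np.ndarray
    ref_count: np.ndarray
    alt_count: np.ndarray
    nucleus_ids: list[str]

    def __post_init__(self) -> None:
        self.depth = _as_count_matrix(self.depth, "depth")
        self.ref_count = _as_count_matrix(self.ref_count, "ref_count")
        self.alt_count = _as_count_matrix(self.alt_count, "alt_count")
        shape = (len(self.sites), len(self.nucleus_ids))
        for name, a in (("depth", self.depth), ("ref_count", self.ref_count),
                        ("alt_count", self.alt_count)):
            if a.shape != shape:
                raise ValueError(f"{name} shape {a.shape} != {shape}")
        if np.any(self.ref_count + self.alt_count > self.depth):
            raise ValueError("ref_count + alt_count exceeds depth")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_nuclei(self) -> int:
        return len(self.nucleus_ids)

    def subset_sites(self, index: np.ndarray) -> "ObservationMatrix":
        index = np.asarray(index)
        return ObservationMatrix(
            sites=[self.sites[i] for i in np.flatnonzero(index)]
            if index.dtype == bool else [self.sites[i] for i in index],
            depth=self.depth[index],
            ref_count=self.ref_count[index],
            alt_count=self.alt_count[index],
            nucleus_ids=list(self.nucleus_ids),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ObservationMatrix):
            return NotImplemented
        return (
            self.sites == other.sites
            and self.nucleus_ids == other.nucleus_ids
            and np.array_equal(self.depth, other.depth)
            and np.array_equal(self.ref_count, other.ref_count)
            and np.array_equal(self.alt_count, other.alt_count)
        )


@dataclass
class SiteAnnotations:
    """Per-site quality statistics consumed by the hard filters.

    Rank-sum statistics may be absent for a site (flagged, value NaN);
    the remaining five annotations are mandatory.
    """

    qd: np.ndarray
    fs: np.ndarray
    mq: np.ndarray
    mq_rank_sum: np.ndarray
    mq_rank_sum_missing: np.ndarray
    read_pos_rank_sum: np.ndarray
    read_pos_rank_sum_missing: np.ndarray
    qual: np.ndarray
    sor: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.qd)
        for name in ("qd", "fs", "mq", "mq_rank_sum", "read_pos_rank_sum",
                     "qual", "sor"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
            if len(getattr(self, name)) != n:
                raise ValueError(f"annotation {name} has inconsistent length")
        for name in ("mq_rank_sum_missing", "read_pos_rank_sum_missing"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
            if len(getattr(self, name)) != n:
                raise ValueError(f"flag {name} has inconsistent length")
        for name in ("fs", "qual", "sor"):
            vals = getattr(self, name)
            if np.any(vals[np.isfinite(vals)] < 0):
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_sites(self) -> int:
        return len(self.qd)

    def subset(self, index: np.ndarray) -> "SiteAnnotations":
        return SiteAnnotations(
            qd=self.qd[index],
            fs=self.fs[index],
            mq=self.mq[index],
            mq_rank_sum=self.mq_rank_sum[index],
            mq_rank_sum_missing=self.mq_rank_sum_missing[index],
            read_pos_rank_sum=self.read_pos_rank_sum[index],
            read_pos_rank_sum_missing=self.read_pos_rank_sum_missing[index],
            qual=self.qual[index],
            sor=self.sor[index],
        )


@dataclass
class GenotypeMatrix:
    """Per-(site, nucleus) haploid call: REF (0), ALT (1), or MISSING (-1)."""

    sites: list[Site]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2 or self.calls.shape[0] != len(self.sites):
            raise ValueError("calls shape inconsistent with site list")
        if not np.isin(self.calls, (REF, ALT, MISSING)).all():
            raise ValueError("calls must be in {REF, ALT, MISSING}")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_nuclei(self) -> int:
        return self.calls.shape[1]

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.sites), self.calls.copy())
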