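"""Karyon inference: is a spore's nucleus population consistent with one
haplotype class (homokaryon) or two (heterokaryon)?

Evidence combined: the non-repeat SNP density (compared against density
bands reported for cultured strains of known karyon status), a two-group
average-linkage partition of nuclei on pairwise Hamming distance, and a
within-site permutation null for the partition score. Verdicts are
deliberately "-consistent": without a mating-type marker this is
evidence, not proof.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .diversity import DiversityReport
from .model import ALT, MISSING, REF, GenotypeMatrix

__all__ = [
    "KaryonThresholds",
    "KaryonCall",
    "site_alt_fraction_spectrum",
    "partition_nuclei",
    "permutation_null",
    "classify_karyon",
]

SPECTRUM_BIN_WIDTH = 0.05

HOMOKARYON = "homokaryon-consistent"
HETEROKARYON = "heterokaryon-consistent"
UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class KaryonThresholds:
    """Decision thresholds. The density bands are borrowed priors from
    cultured strains of a related genus; treat them as defaults, not
    calibrated constants."""

    homokaryon_density_max: float = 0.2
    heterokaryon_density_min: float = 0.45
    partition_score_min: float = 0.8
    permutation_alpha: float = 0.05
    n_permutations: int = 999

    def __post_init__(self) -> None:
        if self.homokaryon_density_max >= self.heterokaryon_density_min:
            raise ValueError(
                "homokaryon_density_max must be < heterokaryon_density_min"
            )
        if not 0 <= self.partition_score_min <= 1:
            raise ValueError("partition_score_min must be in [0, 1]")


@dataclass(frozen=True)
class KaryonCall:
    verdict: str
    partition: tuple[str, ...]
    partition_score: float
    permutation_p: float
    density_used: float

    def __post_init__(self) -> None:
        if (
            self.verdict == HETEROKARYON
            and self.partition
            and len(set(self.partition)) < 2
        ):
            raise ValueError(
                "heterokaryon-consistent verdict requires two non-empty groups"
            )

    def to_tsv(self) -> str:
        lines = [
            "field\tvalue",
            f"verdict\t{self.verdict}",
            f"partition\t{','.join(self.partition)}",
            f"partition_score\t{self.partition_score:.6g}",
            f"permutation_p\t{self.permutation_p:.6g}",
            f"density_used\t{self.density_used:.6g}",
        ]
        return "\n".join(lines) + "\n"


def _select(gt: GenotypeMatrix, retained: np.ndarray | None) -> np.ndarray:
    if retained is None:
        return gt.calls
    retained = np.asarray(retained, dtype=np.int64)
    return gt.calls[retained]


def site_alt_fraction_spectrum(
    gt: GenotypeMatrix, retained: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site ALT fraction among non-missing calls, plus a histogram
    with fixed bins of width 0.05 (last bin closed at 1.0).

    Sites where every call is missing are excluded with a warning.
    The histogram counts sum to the number of included sites.
    """
    calls = _select(gt, retained)
    nonmiss = (calls != MISSING).sum(axis=1)
    excluded = nonmiss == 0
    if excluded.any():
        warnings.warn(
            f"excluding {int(excluded.sum())} site(s) with all calls missing",
            stacklevel=2,
        )
    keep = ~excluded
    alt = (calls[keep] == ALT).sum(axis=1)
    spectrum = alt / nonmiss[keep]
    edges = np.arange(0, 1 + SPECTRUM_BIN_WIDTH / 2, SPECTRUM_BIN_WIDTH)
    hist, _ = np.histogram(spectrum, bins=edges)
    return spectrum, hist


def _pairwise_distances(
    calls: np.ndarray, min_shared: int = 10
) -> np.ndarray:
    """Normalized Hamming distance over pairwise-complete sites.

    Pairs sharing fewer than ``min_shared`` non-missing sites get the mean
    of the defined distances (0.5 when nothing is defined).
    """
    valid = (calls != MISSING).astype(np.float64)
    is_ref = (calls == REF).astype(np.float64)
    is_alt = (calls == ALT).astype(np.float64)
    shared = valid.T @ valid
    mismatch = is_alt.T @ is_ref + is_ref.T @ is_alt
    with np.errstate(divide="ignore", invalid="ignore"):
        dist = np.where(shared > 0, mismatch / np.maximum(shared, 1), np.nan)
    defined = (shared >= min_shared) & (shared > 0)
    np.fill_diagonal(defined, True)
    np.fill_diagonal(dist, 0.0)
    off_diag = ~np.eye(len(dist), dtype=bool)
    good = defined & off_diag
    fill = float(dist[good].mean()) if good.any() else 0.5
    dist = np.where(defined, dist, fill)
    return dist


def _score_partition(dist: np.ndarray, labels: np.ndarray) -> float:
    """1 - mean(within)/mean(between), clamped to [0, 1]; 0 when the
    between-group mean is zero or there is a single group."""
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    same = labels[iu[0]] == labels[iu[1]]
    d = dist[iu]
    between = d[~same]
    if between.size == 0:
        return 0.0
    mean_between = float(between.mean())
    if mean_between <= 0:
        return 0.0
    mean_within = float(d[same].mean()) if same.any() else 0.0
    return float(np.clip(1.0 - mean_within / mean_between, 0.0, 1.0))


def _two_group_labels(dist: np.ndarray) -> np.ndarray:
    """Average-linkage cut into (at most) two groups; the group containing
    nucleus 0 is labeled 'A' for determinism."""
    n = len(dist)
    condensed = squareform(dist, checks=False)
    tree = linkage(condensed, method="average")
    raw = fcluster(tree, t=2, criterion="maxclust")
    labels = np.where(raw == raw[0], "A", "B")
    return labels


def partition_nuclei(
    gt: GenotypeMatrix,
    retained: np.ndarray | None = None,
    min_shared: int = 10,
) -> tuple[np.ndarray, float]:
    """Cluster nuclei into two groups and score the separation.

    Returns per-nucleus labels in {"A", "B"} (group of nucleus 0 is "A")
    and the partition score 1 - within/between mean distance, in [0, 1].
    """
    calls = _select(gt, retained)
    if calls.shape[1] < 2:
        raise ValueError("need at least 2 nuclei")
    if calls.shape[0] < 1:
        raise ValueError("need at least 1 retained site")
    dist = _pairwise_distances(calls, min_shared=min_shared)
    labels = _two_group_labels(dist)
    score = _score_partition(dist, labels)
    return labels, score


def permutation_null(
    gt: GenotypeMatrix,
    retained: np.ndarray | None = None,
    n_permutations: int = 999,
    seed: int = 0,
    min_shared: int = 10,
) -> float:
    """Permutation p-value for the observed partition score.

    Each permutation shuffles calls among nuclei independently at every
    site, preserving per-site REF/ALT/MISSING counts. The estimator is
    (1 + #{score_perm >= score_obs}) / (n_permutations + 1), so p is
    never below 1/(n_permutations + 1).
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    calls = _select(gt, retained)
    if calls.shape[1] < 2 or calls.shape[0] < 1:
        raise ValueError("need >= 2 nuclei and >= 1 site")
    dist = _pairwise_distances(calls, min_shared=min_shared)
    obs_labels = _two_group_labels(dist)
    obs_score = _score_partition(dist, obs_labels)

    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        idx = rng.random(calls.shape).argsort(axis=1)
        perm = np.take_along_axis(calls, idx, axis=1)
        pdist = _pairwise_distances(perm, min_shared=min_shared)
        plabels = _two_group_labels(pdist)
        if _score_partition(pdist, plabels) >= obs_score - 1e-12:
            n_ge += 1
    return (1 + n_ge) / (n_permutations + 1)


def classify_karyon(
    report: DiversityReport | float,
    partition_score: float,
    permutation_p: float,
    thr: KaryonThresholds | None = None,
    partition: tuple[str, ...] | None = None,
) -> KaryonCall:
    """Combine density and partition evidence into a verdict.

    Heterokaryon-consistent requires high density AND a strong,
    significant bipartition; homokaryon-consistent requires low density
    AND the absence of such a bipartition; anything else (including the
    intermediate densities this method was motivated by) is undetermined.
    """
    thr = thr or KaryonThresholds()
    density = (
        report.density_snp_per_kb
        if isinstance(report, DiversityReport)
        else float(report)
    )
    partition = tuple(partition) if partition is not None else ()

    strong_split = (
        partition_score >= thr.partition_score_min
        and permutation_p <= thr.permutation_alpha
    )
    if density >= thr.heterokaryon_density_min and strong_split:
        verdict = HETEROKARYON
    elif density <= thr.homokaryon_density_max and not strong_split:
        verdict = HOMOKARYON
    else:
        verdict = UNDETERMINED
    return KaryonCall(
        verdict=verdict,
        partition=partition,
        partition_score=float(partition_score),
        permutation_p=float(permutation_p),
        density_used=float(density),
    )
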