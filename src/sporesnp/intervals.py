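"""Genomic interval sets: 0-based half-open, per-contig, always normalized.

All internal arithmetic in this package is 0-based half-open; conversion
from 1-based coordinates happens only at I/O boundaries.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator

import numpy as np

__all__ = ["IntervalSet", "merge_pairs"]


def merge_pairs(pairs: Iterable[tuple[int, int]]) -> np.ndarray:
    """Sort and merge (start, end) pairs into a (k, 2) int64 array.

    Overlapping and bookended intervals are coalesced, so total length
    never double-counts overlapping annotations.
    """
    arr = np.asarray(sorted((int(s), int(e)) for s, e in pairs), dtype=np.int64)
    if arr.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    if np.any(arr[:, 1] <= arr[:, 0]):
        bad = arr[arr[:, 1] <= arr[:, 0]][0]
        raise ValueError(f"interval end must exceed start, got [{bad[0]}, {bad[1]})")
    merged: list[list[int]] = [[int(arr[0, 0]), int(arr[0, 1])]]
    for s, e in arr[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], int(e))
        else:
            merged.append([int(s), int(e)])
    return np.asarray(merged, dtype=np.int64)


class IntervalSet:
    """Mapping of contig id -> merged, sorted (start, end) interval array."""

    def __init__(self, by_contig: dict[str, np.ndarray] | None = None):
        self._by_contig: dict[str, np.ndarray] = {}
        if by_contig:
            for contig, arr in by_contig.items():
                a = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                if len(a):
                    self._by_contig[contig] = merge_pairs(map(tuple, a))

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        """Build from (contig, start, end) triples; merges per contig."""
        grouped: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in records:
            grouped.setdefault(contig, []).append((int(start), int(end)))
        return cls({c: merge_pairs(p) for c, p in grouped.items()})

    def intervals(self, contig: str) -> np.ndarray:
        return self._by_contig.get(contig, np.empty((0, 2), dtype=np.int64))

    def contigs(self) -> list[str]:
        return list(self._by_contig)

    def records(self) -> Iterator[tuple[str, int, int]]:
        for contig in sorted(self._by_contig):
            for s, e in self._by_contig[contig]:
                yield contig, int(s), int(e)

    @property
    def total_length(self) -> int:
        return int(
            sum((a[:, 1] - a[:, 0]).sum() for a in self._by_contig.values())
        )

    def length_on(self, contig: str) -> int:
        a = self.intervals(contig)
        return int((a[:, 1] - a[:, 0]).sum()) if len(a) else 0

    def contains(self, contig: str, pos0: np.ndarray | int) -> np.ndarray:
        """Vectorized membership test for 0-based positions on one contig."""
        pos0 = np.atleast_1d(np.asarray(pos0, dtype=np.int64))
        a = self.intervals(contig)
        if len(a) == 0:
            return np.zeros(pos0.shape, dtype=bool)
        idx = np.searchsorted(a[:, 0], pos0, side="right") - 1
        inside = idx >= 0
        inside[inside] &= pos0[inside] < a[idx[inside], 1]
        return inside

    def max_end(self, contig: str) -> int:
        a = self.intervals(contig)
        return int(a[-1, 1]) if len(a) else 0

    def __len__(self) -> int:
        return sum(len(a) for a in self._by_contig.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._by_contig) != set(other._by_contig):
            return False
        return all(
            np.array_equal(self._by_contig[c], other._by_contig[c])
            for c in self._by_contig
        )

    def __repr__(self) -> str:
        return f"IntervalSet({len(self)} intervals on {len(self._by_contig)} contigs)"
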