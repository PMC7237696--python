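"""Genomic interval sets with 0-based half-open coordinates.

A :class:`RegionSet` stores, per contig, a sorted array of non-overlapping
``[start, end)`` intervals.  Construction merges overlapping or bookended
input intervals.  :class:`CallableRegionSet` is the same structure used for
callable-loci bookkeeping.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Tuple

import numpy as np

Interval = Tuple[str, int, int]


class RegionSet:
    def __init__(self, intervals: Dict[str, np.ndarray] | None = None):
        # intervals: contig -> (n, 2) int64 array, sorted, non-overlapping
        self.intervals: Dict[str, np.ndarray] = intervals or {}

    @classmethod
    def from_intervals(cls, items: Iterable[Interval]) -> "RegionSet":
        by_contig: Dict[str, List[Tuple[int, int]]] = {}
        for contig, start, end in items:
            if start >= end:
                raise ValueError(f"invalid interval {contig}:{start}-{end} (start >= end)")
            by_contig.setdefault(contig, []).append((int(start), int(end)))
        merged: Dict[str, np.ndarray] = {}
        for contig, ivs in by_contig.items():
            ivs.sort()
            out = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[contig] = np.asarray(out, dtype=np.int64)
        return cls(merged)

    @property
    def total_length(self) -> int:
        return int(
            sum((arr[:, 1] - arr[:, 0]).sum() for arr in self.intervals.values())
        )

    def __len__(self) -> int:
        return sum(len(arr) for arr in self.intervals.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        if set(self.intervals) != set(other.intervals):
            return False
        return all(
            np.array_equal(self.intervals[c], other.intervals[c])
            for c in self.intervals
        )

    def __iter__(self):
        for contig in sorted(self.intervals):
            for s, e in self.intervals[contig]:
                yield contig, int(s), int(e)

    def contains(self, contig: str, positions) -> np.ndarray:
        """Vectorized membership test for 0-based positions on one contig."""
        positions = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        arr = self.intervals.get(contig)
        if arr is None or len(arr) == 0:
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(arr[:, 0], positions, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(len(positions), dtype=bool)
        hit[ok] = positions[ok] < arr[idx[ok], 1]
        return hit

    def intersect(self, other: "RegionSet") -> "RegionSet":
        out: Dict[str, np.ndarray] = {}
        for contig in set(self.intervals) & set(other.intervals):
            a, b = self.intervals[contig], other.intervals[contig]
            i = j = 0
            acc = []
            while i < len(a) and j < len(b):
                s = max(a[i, 0], b[j, 0])
                e = min(a[i, 1], b[j, 1])
                if s < e:
                    acc.append((s, e))
                if a[i, 1] < b[j, 1]:
                    i += 1
                else:
                    j += 1
            if acc:
                out[contig] = np.asarray(acc, dtype=np.int64)
        return type(self)(out)


class CallableRegionSet(RegionSet):
    """Regions with sufficient depth and quality for confident calling."""
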