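"""Per-chromosome sorted interval index for window/nearest queries.

Intervals are sorted by start; a running maximum of ends makes nearest-gap
queries O(log n) even with nested intervals.
"""

from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np

from .io import GenomicInterval


class _ChromIndex:
    def __init__(self, items: Sequence[tuple[GenomicInterval, object]]):
        order = sorted(range(len(items)), key=lambda i: items[i][0].start)
        self.starts = np.array([items[i][0].start for i in order], dtype=np.int64)
        self.ends = np.array([items[i][0].end for i in order], dtype=np.int64)
        self.payloads = [items[i][1] for i in order]
        self.max_ends = np.maximum.accumulate(self.ends)

    def min_gap(self, iv: GenomicInterval) -> float:
        """Smallest gap_distance from iv to any indexed interval."""
        idx = int(np.searchsorted(self.starts, iv.end, side="left"))
        best = math.inf
        if idx > 0:
            # intervals starting before iv.end: gap determined by max end
            best = max(0, iv.start - int(self.max_ends[idx - 1]))
        if idx < len(self.starts):
            best = min(best, max(0, int(self.starts[idx]) - iv.end))
        return best

    def within(self, iv: GenomicInterval, window: int) -> list:
        """Payloads of all intervals with gap_distance(iv, .) <= window."""
        hi = int(np.searchsorted(self.starts, iv.end + window, side="right"))
        if hi == 0:
            return []
        mask = self.ends[:hi] >= iv.start - window
        return [self.payloads[i] for i in np.nonzero(mask)[0]]

    def any_within(self, iv: GenomicInterval, window: int) -> bool:
        return self.min_gap(iv) <= window


class IntervalIndex:
    """Index a collection of (interval, payload) pairs across chromosomes."""

    def __init__(self, items: Iterable[tuple[GenomicInterval, object]]):
        by_chrom: dict[str, list] = defaultdict(list)
        for iv, payload in items:
            by_chrom[iv.chrom].append((iv, payload))
        self._chroms = {c: _ChromIndex(v) for c, v in by_chrom.items()}

    def min_gap(self, iv: GenomicInterval) -> float:
        idx = self._chroms.get(iv.chrom)
        return math.inf if idx is None else idx.min_gap(iv)

    def within(self, iv: GenomicInterval, window: int) -> list:
        idx = self._chroms.get(iv.chrom)
        return [] if idx is None else idx.within(iv, window)

    def any_within(self, iv: GenomicInterval, window: int) -> bool:
        return self.min_gap(iv) <= window
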