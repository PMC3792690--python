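"""Peak filtering, cross-replicate consensus and control-proximity screening.

A peak passes the quality filter when its FDR is strictly below ``max_fdr``
and its fold enrichment strictly above ``min_fold``; peaks lacking either
statistic fail (conservative). Replication is anchored on replicate A: each
A-peak with a B-peak within the window yields one consensus peak whose
representative interval is the A interval (or, optionally, the union span of
the matched pair group).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .index import IntervalIndex
from .io import GenomicInterval, Peak, PeakSet, gap_distance

WINDOW_MODES = ("gap", "summit")


@dataclass(frozen=True)
class Thresholds:
    """All numeric cutoffs used by the pipeline, defaulting to the published
    values: FDR < 0.05, fold > 20, 10 kb replication/control windows, 2 kb
    gene assignment distance and q < 0.05 for differential expression."""

    max_fdr: float = 0.05
    min_fold: float = 20.0
    replication_window: int = 10_000
    control_window: int = 10_000
    gene_max_dist: int = 2_000
    de_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("max_fdr", "min_fold", "replication_window",
                     "control_window", "gene_max_dist", "de_alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("max_fdr", "de_alpha"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass
class ConsensusPeak:
    """A replicated peak: representative interval plus its supporting peak
    ids per replicate and (once screened) its nearest-control gap."""

    id: str
    interval: GenomicInterval
    support: dict[str, tuple[str, ...]]
    min_partner_gap: float
    control_proximal: bool = False
    nearest_control_gap: float = math.inf


@dataclass
class ConsensusResult:
    consensus: list[ConsensusPeak]
    n_repA_in: int
    n_repB_in: int
    labelA: str
    labelB: str
    n_controls_in_window: int | None = None

    @property
    def n_replicated(self) -> int:
        return len(self.consensus)

    @property
    def n_control_proximal(self) -> int:
        return sum(1 for c in self.consensus if c.control_proximal)

    @property
    def specific(self) -> list[ConsensusPeak]:
        return [c for c in self.consensus if not c.control_proximal]


def filter_peaks(peaks: PeakSet, thresholds: Thresholds) -> PeakSet:
    """Keep peaks with fdr < max_fdr AND fold_enrichment > min_fold.

    Both inequalities are strict; peaks with an absent fdr or fold value are
    removed. Input order is preserved.
    """
    kept = [
        p
        for p in peaks
        if p.fdr is not None
        and p.fold_enrichment is not None
        and p.fdr < thresholds.max_fdr
        and p.fold_enrichment > thresholds.min_fold
    ]
    return PeakSet(label=peaks.label, role=peaks.role, peaks=kept)


def _peak_distance(a: Peak, b: Peak, mode: str) -> float:
    if mode == "gap":
        return gap_distance(a.interval, b.interval)
    if a.interval.chrom != b.interval.chrom:
        return math.inf
    return abs(a.summit - b.summit)


def replicate_consensus(
    repA: PeakSet,
    repB: PeakSet,
    window: int,
    mode: str = "gap",
    representative: str = "anchor",
) -> ConsensusResult:
    """Find repA peaks with at least one repB peak within ``window``.

    ``mode`` selects the distance notion: ``"gap"`` (interval gap, 0 on
    overlap; default) or ``"summit"`` (absolute summit-to-summit distance,
    midpoint when a summit is absent). ``representative`` is ``"anchor"``
    (the A interval) or ``"union"`` (span of A and all matched B peaks).
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if mode not in WINDOW_MODES:
        raise ValueError(f"unknown window mode {mode!r}")
    if representative not in ("anchor", "union"):
        raise ValueError(f"unknown representative mode {representative!r}")

    if mode == "gap":
        index = IntervalIndex((b.interval, b) for b in repB)

        def matches(a: Peak) -> list[Peak]:
            return index.within(a.interval, window)
    else:
        b_by_chrom: dict[str, tuple[np.ndarray, list[Peak]]] = {}
        from collections import defaultdict

        grouped: dict[str, list[Peak]] = defaultdict(list)
        for b in repB:
            grouped[b.interval.chrom].append(b)
        for chrom, items in grouped.items():
            items.sort(key=lambda p: p.summit)
            b_by_chrom[chrom] = (
                np.array([p.summit for p in items], dtype=np.int64),
                items,
            )

        def matches(a: Peak) -> list[Peak]:
            entry = b_by_chrom.get(a.interval.chrom)
            if entry is None:
                return []
            summits, items = entry
            lo = int(np.searchsorted(summits, a.summit - window, side="left"))
            hi = int(np.searchsorted(summits, a.summit + window, side="right"))
            return items[lo:hi]

    consensus: list[ConsensusPeak] = []
    for a in repA:
        hits = matches(a)
        if not hits:
            continue
        gaps = [_peak_distance(a, b, mode) for b in hits]
        iv = a.interval
        if representative == "union":
            start = min([iv.start] + [b.interval.start for b in hits])
            end = max([iv.end] + [b.interval.end for b in hits])
            iv = GenomicInterval(iv.chrom, start, end, iv.strand)
        consensus.append(
            ConsensusPeak(
                id=a.id,
                interval=iv,
                support={
                    repA.label: (a.id,),
                    repB.label: tuple(b.id for b in hits),
                },
                min_partner_gap=min(gaps),
            )
        )
    return ConsensusResult(
        consensus=consensus,
        n_repA_in=len(repA),
        n_repB_in=len(repB),
        labelA=repA.label,
        labelB=repB.label,
    )


def flag_control_proximity(
    result: ConsensusResult,
    controls: Sequence[PeakSet],
    window: int,
) -> ConsensusResult:
    """Pool control peak sets and flag consensus peaks within ``window``.

    Also counts, from the control side, how many pooled control peaks lie
    within the window of any consensus peak.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if not controls:
        raise ValueError("at least one control PeakSet is required")
    pooled = [p for cs in controls for p in cs]
    control_index = IntervalIndex((p.interval, p) for p in pooled)
    flagged = []
    for c in result.consensus:
        gap = control_index.min_gap(c.interval)
        flagged.append(
            replace(c, nearest_control_gap=gap, control_proximal=gap <= window)
        )
    consensus_index = IntervalIndex((c.interval, c) for c in result.consensus)
    n_controls_hit = sum(
        1 for p in pooled if consensus_index.any_within(p.interval, window)
    )
    return ConsensusResult(
        consensus=flagged,
        n_repA_in=result.n_repA_in,
        n_repB_in=result.n_repB_in,
        labelA=result.labelA,
        labelB=result.labelB,
        n_controls_in_window=n_controls_hit,
    )


def pairwise_window_overlap(
    peaksets: Sequence[PeakSet], window: int
) -> pd.DataFrame:
    """Fraction of each set's peaks with a partner in each other set.

    Entry (i, j) is the fraction of peaks in set i having any peak of set j
    within ``window`` (gap distance). The diagonal is 1 for non-empty sets.
    Rows for empty sets are NaN (undefined, not 0). Asymmetric in general.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if len(peaksets) < 2:
        raise ValueError("need at least two peak sets")
    labels = [ps.label for ps in peaksets]
    if len(set(labels)) != len(labels):
        raise ValueError("peak set labels must be unique")
    indexes = [IntervalIndex((p.interval, p) for p in ps) for ps in peaksets]
    mat = np.full((len(peaksets), len(peaksets)), np.nan)
    for i, ps in enumerate(peaksets):
        if len(ps) == 0:
            continue
        for j, idx in enumerate(indexes):
            hits = sum(1 for p in ps if idx.any_within(p.interval, window))
            mat[i, j] = hits / len(ps)
    return pd.DataFrame(mat, index=labels, columns=labels)
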