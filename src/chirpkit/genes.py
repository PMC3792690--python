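"""Peak-to-gene assignment and TSS-distance profiling.

Assignment measures peak-edge to gene-body-edge gap by default (a peak
inside a gene has distance 0); a midpoint-to-TSS mode exists for
sensitivity analysis. The TSS profile uses the nearest TSS genome-wide on
the peak's chromosome with no distance cutoff, signed so that negative
always means upstream in the gene's orientation.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import GeneAnnotation, GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

DISTANCE_MODES = ("gene_body", "tss_midpoint")

# signed TSS-distance bin edges in bp; bins are left-open, right-closed
TSS_BIN_EDGES = [-500_000, -50_000, -5_000, 0, 5_000, 50_000, 500_000]
TSS_BIN_LABELS = [
    "(-inf,-500kb]",
    "(-500kb,-50kb]",
    "(-50kb,-5kb]",
    "(-5kb,0]",
    "(0,5kb]",
    "(5kb,50kb]",
    "(50kb,500kb]",
    "(500kb,inf)",
]


@dataclass(frozen=True)
class PeakGeneAssignment:
    peak_id: str
    gene_id: str | None
    distance: int | None
    tie_broken: bool = False


@dataclass
class TSSDistanceProfile:
    labels: list[str]
    counts: list[int]
    n_total: int
    n_excluded: int

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.labels, self.counts))


def _genes_by_chrom(annotation: GeneAnnotation) -> dict[str, list[GeneModel]]:
    out: dict[str, list[GeneModel]] = defaultdict(list)
    for g in annotation:
        out[g.interval.chrom].append(g)
    return out


def assign_closest_gene(
    peaks: Iterable,
    annotation: GeneAnnotation,
    max_dist: int,
    mode: str = "gene_body",
) -> list[PeakGeneAssignment]:
    """Assign each peak to its closest gene if within ``max_dist`` bp.

    ``mode="gene_body"``: distance is the interval gap between peak and gene
    body (0 on overlap). ``mode="tss_midpoint"``: distance is
    ``|peak midpoint - TSS|``. Ties at the minimal distance are broken by
    smaller ``|peak midpoint - TSS|``, then lexicographic gene_id, and the
    assignment is flagged ``tie_broken``.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    if mode not in DISTANCE_MODES:
        raise ValueError(f"unknown distance mode {mode!r}")
    if len(annotation) == 0:
        raise ValueError("annotation is empty")

    by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, list[GeneModel]]] = {}
    for chrom, genes in _genes_by_chrom(annotation).items():
        by_chrom[chrom] = (
            np.array([g.interval.start for g in genes], dtype=np.int64),
            np.array([g.interval.end for g in genes], dtype=np.int64),
            np.array([g.tss for g in genes], dtype=np.int64),
            genes,
        )

    assignments: list[PeakGeneAssignment] = []
    for peak in peaks:
        iv: GenomicInterval = peak.interval
        entry = by_chrom.get(iv.chrom)
        if entry is None:
            assignments.append(PeakGeneAssignment(peak.id, None, None))
            continue
        starts, ends, tsss, genes = entry
        mid = iv.midpoint
        if mode == "gene_body":
            dist = np.maximum(0, np.maximum(starts - iv.end, iv.start - ends))
        else:
            dist = np.abs(mid - tsss)
        best = int(dist.min())
        if best > max_dist:
            assignments.append(PeakGeneAssignment(peak.id, None, None))
            continue
        cand = np.nonzero(dist == best)[0]
        tie_broken = len(cand) > 1
        if tie_broken:
            tss_dist = np.abs(mid - tsss[cand])
            cand = cand[tss_dist == tss_dist.min()]
            winner = min(cand, key=lambda i: genes[i].gene_id)
        else:
            winner = cand[0]
        assignments.append(
            PeakGeneAssignment(peak.id, genes[winner].gene_id, best, tie_broken)
        )
    return assignments


def chirp_gene_set(assignments: Iterable[PeakGeneAssignment]) -> set[str]:
    """Deduplicated set of assigned gene ids."""
    return {a.gene_id for a in assignments if a.gene_id is not None}


def signed_tss_distance(
    peak_interval: GenomicInterval, annotation_by_chrom
) -> float | None:
    """Signed bp distance from peak midpoint to the nearest same-chromosome
    TSS; negative = upstream of the gene. None if the chromosome has no gene."""
    entry = annotation_by_chrom.get(peak_interval.chrom)
    if entry is None:
        return None
    tss_sorted, strand_is_minus = entry
    mid = peak_interval.midpoint
    idx = int(np.searchsorted(tss_sorted, mid))
    best_i = None
    best_abs = None
    for i in (idx - 1, idx):
        if 0 <= i < len(tss_sorted):
            d = abs(mid - int(tss_sorted[i]))
            if best_abs is None or d < best_abs:
                best_abs, best_i = d, i
    signed = mid - int(tss_sorted[best_i])
    if strand_is_minus[best_i]:
        signed = -signed
    return signed


def tss_distance_profile(
    peaks: Iterable, annotation: GeneAnnotation
) -> TSSDistanceProfile:
    """Histogram of signed peak-midpoint-to-nearest-TSS distances.

    Bins (kb): (-inf,-500], (-500,-50], (-50,-5], (-5,0], (0,5], (5,50],
    (50,500], (500,inf); left-open/right-closed, so distance 0 falls in
    (-5,0]. Peaks on chromosomes without genes are excluded and counted.
    """
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    by_chrom = {}
    for chrom, genes in _genes_by_chrom(annotation).items():
        order = sorted(range(len(genes)), key=lambda i: genes[i].tss)
        by_chrom[chrom] = (
            np.array([genes[i].tss for i in order], dtype=np.int64),
            [genes[i].strand == "-" for i in order],
        )
    counts = [0] * len(TSS_BIN_LABELS)
    n_total = 0
    n_excluded = 0
    edges = np.array(TSS_BIN_EDGES, dtype=np.int64)
    for peak in peaks:
        signed = signed_tss_distance(peak.interval, by_chrom)
        if signed is None:
            n_excluded += 1
            continue
        bin_idx = int(np.searchsorted(edges, signed, side="left"))
        counts[bin_idx] += 1
        n_total += 1
    if n_excluded:
        logger.warning(
            "tss_distance_profile: %d peak(s) on chromosomes without genes "
            "excluded",
            n_excluded,
        )
    return TSSDistanceProfile(
        labels=list(TSS_BIN_LABELS),
        counts=counts,
        n_total=n_total,
        n_excluded=n_excluded,
    )
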