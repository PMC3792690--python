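"""Independent brute-force oracles and random-instance builders for tests.

These deliberately use naive all-pairs scans so they share no code path
with the package's sweep/index implementations.
"""

from __future__ import annotations

import math

import numpy as np

from chirpkit.io import GenomicInterval, Peak, PeakSet


def mkpeak(pid, chrom, start, end, fold=None, fdr=None, summit=None,
           strand=".", score=0):
    return Peak(
        id=pid,
        interval=GenomicInterval(chrom, start, end, strand),
        summit_offset=summit,
        fold_enrichment=fold,
        fdr=fdr,
        score=score,
    )


def brute_gap(a: GenomicInterval, b: GenomicInterval) -> float:
    if a.chrom != b.chrom:
        return math.inf
    if a.end <= b.start:
        return b.start - a.end
    if b.end <= a.start:
        return a.start - b.end
    return 0


def brute_peak_distance(a: Peak, b: Peak, mode: str) -> float:
    if mode == "gap":
        return brute_gap(a.interval, b.interval)
    if a.interval.chrom != b.interval.chrom:
        return math.inf
    return abs(a.summit - b.summit)


def brute_replicate(repA: PeakSet, repB: PeakSet, window: int,
                    mode: str = "gap"):
    """All-pairs replication: {a.id: (sorted matching b ids, min gap)}."""
    out = {}
    for a in repA:
        hits = []
        best = math.inf
        for b in repB:
            d = brute_peak_distance(a, b, mode)
            if d <= window:
                hits.append(b.id)
                best = min(best, d)
        if hits:
            out[a.id] = (sorted(hits), best)
    return out


def brute_min_gap_to_set(iv: GenomicInterval, others) -> float:
    best = math.inf
    for o in others:
        best = min(best, brute_gap(iv, o.interval))
    return best


def brute_assign(peaks, genes, max_dist, mode="gene_body"):
    """All-pairs closest-gene assignment: {peak.id: gene_id or None}."""
    out = {}
    for p in peaks:
        best = math.inf
        cands = []
        for g in genes:
            if mode == "gene_body":
                d = brute_gap(p.interval, g.interval)
            else:
                if g.interval.chrom != p.interval.chrom:
                    d = math.inf
                else:
                    d = abs(p.interval.midpoint - g.tss)
            if d < best:
                best = d
                cands = [g]
            elif d == best:
                cands.append(g)
        if best > max_dist or not cands:
            out[p.id] = None
            continue
        mid = p.interval.midpoint
        cands.sort(key=lambda g: (abs(mid - g.tss), g.gene_id))
        out[p.id] = cands[0].gene_id
    return out


def random_peakset(rng: np.random.Generator, label: str, n: int,
                   chroms=("chr1", "chr2", "chr3"), span=200_000,
                   max_len=2_000) -> PeakSet:
    peaks = []
    for i in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        width = start + length
        summit = int(rng.integers(0, length))
        peaks.append(
            mkpeak(f"{label}_{i}", chrom, start, width,
                   fold=float(rng.uniform(0, 60)),
                   fdr=float(rng.uniform(0, 1)), summit=summit)
        )
    return PeakSet(label=label, role="other", peaks=peaks)
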