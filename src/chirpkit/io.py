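"""Genomic file I/O and the core coordinate types.

All coordinates are held internally as 0-based half-open intervals (BED
convention). GTF input (1-based inclusive) is converted on read and back on
write. Peak significance is held on the linear FDR scale; narrowPeak's
``-log10(qValue)`` column is converted at parse time.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pyranges as pr

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)``."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def gap_distance(a: GenomicInterval, b: GenomicInterval) -> float:
    """Gap in bp between two intervals; 0 if they overlap or abut.

    Returns ``math.inf`` for intervals on different chromosomes. Symmetric.
    """
    if a.chrom != b.chrom:
        return math.inf
    return max(0, b.start - a.end, a.start - b.end)


@dataclass(frozen=True)
class Peak:
    """One called peak: interval plus caller statistics.

    ``fold_enrichment`` and ``fdr`` are ``None`` when the source format did
    not carry them (BED6, or ``-1`` sentinels in narrowPeak).
    """

    id: str
    interval: GenomicInterval
    summit_offset: int | None = None
    fold_enrichment: float | None = None
    fdr: float | None = None
    score: int = 0

    def __post_init__(self) -> None:
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < len(self.interval)
        ):
            raise ValueError(
                f"peak {self.id}: summit_offset {self.summit_offset} outside "
                f"interval of length {len(self.interval)}"
            )
        if self.fold_enrichment is not None and self.fold_enrichment < 0:
            raise ValueError(f"peak {self.id}: fold_enrichment must be >= 0")
        if self.fdr is not None and not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"peak {self.id}: fdr must be in [0, 1]")

    @property
    def summit(self) -> int:
        """Absolute summit position; interval midpoint when no summit."""
        if self.summit_offset is None:
            return self.interval.midpoint
        return self.interval.start + self.summit_offset


PEAKSET_ROLES = ("treatment_replicate", "control", "other")


@dataclass
class PeakSet:
    """An ordered, uniquely-identified collection of peaks from one sample."""

    label: str
    role: str = "other"
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in PEAKSET_ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        ids = [p.id for p in self.peaks]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate peak id {dup!r} in set {self.label!r}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)


@dataclass(frozen=True)
class GeneModel:
    """One gene with a strand-derived transcription start site."""

    gene_id: str
    interval: GenomicInterval
    strand: str
    gene_name: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"gene {self.gene_id}: strand must be + or -, got {self.strand!r}"
            )

    @property
    def tss(self) -> int:
        if self.strand == "+":
            return self.interval.start
        return self.interval.end - 1


class GeneAnnotation:
    """Collection of GeneModel keyed by unique gene_id."""

    def __init__(self, genes: Iterable[GeneModel]):
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self._genes[g.gene_id] = g

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    @property
    def gene_ids(self) -> set[str]:
        return set(self._genes)


# ---------------------------------------------------------------------------
# narrowPeak / BED
# ---------------------------------------------------------------------------

_SKIP_PREFIXES = ("#", "track", "browser")


def _parse_float(text: str, what: str, lineno: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise ParseError(f"line {lineno}: non-numeric {what}: {text!r}") from None


def _parse_int(text: str, what: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError:
        raise ParseError(f"line {lineno}: non-numeric {what}: {text!r}") from None


def read_narrowpeak(path: str | Path, label: str | None = None,
                    role: str = "other") -> PeakSet:
    """Read an ENCODE narrowPeak (10-column) or BED6 file into a PeakSet.

    narrowPeak column 7 becomes ``fold_enrichment``, column 9 (a
    ``-log10`` q-value) becomes ``fdr = 10**(-q)`` and column 10 becomes the
    summit offset; ``-1`` in columns 8-10 means "absent". BED6 lines yield
    peaks without statistics. Peaks named ``.`` get a synthesized id.
    """
    path = Path(path)
    if label is None:
        label = path.stem
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            cols = line.split("\t")
            if len(cols) not in (6, 10):
                raise ParseError(
                    f"line {lineno}: expected 6 or 10 tab-separated columns, "
                    f"got {len(cols)}"
                )
            chrom = cols[0]
            start = _parse_int(cols[1], "start", lineno)
            end = _parse_int(cols[2], "end", lineno)
            name = cols[3]
            score = int(_parse_float(cols[4], "score", lineno))
            strand = cols[5]
            if strand not in STRANDS:
                raise ParseError(f"line {lineno}: unknown strand {strand!r}")
            if not (0 <= start < end):
                raise ParseError(
                    f"line {lineno}: invalid interval [{start}, {end})"
                )
            fold = fdr = None
            summit = None
            if len(cols) == 10:
                fold_raw = _parse_float(cols[6], "signalValue", lineno)
                fold = None if fold_raw == -1 else fold_raw
                q_raw = _parse_float(cols[8], "qValue", lineno)
                fdr = None if q_raw == -1 else min(1.0, 10.0 ** (-q_raw))
                summit_raw = _parse_int(cols[9], "summit", lineno)
                summit = None if summit_raw == -1 else summit_raw
            if name == "." or not name:
                name = f"{label}_peak{lineno}"
            try:
                peak = Peak(
                    id=name,
                    interval=GenomicInterval(chrom, start, end, strand),
                    summit_offset=summit,
                    fold_enrichment=fold,
                    fdr=fdr,
                    score=score,
                )
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from None
            peaks.append(peak)
    return PeakSet(label=label, role=role, peaks=peaks)


def write_bed(peaks: Iterable, path: str | Path) -> None:
    """Write peaks (or any objects with ``.id`` and ``.interval``) as BED6.

    Records are sorted by (chrom, start, end, id); output is tab-separated,
    LF-terminated, headerless.
    """
    rows = sorted(
        peaks,
        key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end, p.id),
    )
    with open(path, "w", newline="\n") as fh:
        for p in rows:
            iv = p.interval
            score = getattr(p, "score", 0)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.id}\t{score}\t{iv.strand}\n"
            )


def write_narrowpeak(peakset: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as 10-column ENCODE narrowPeak (absent fields -> -1)."""
    with open(path, "w", newline="\n") as fh:
        for p in peakset:
            iv = p.interval
            fold = -1.0 if p.fold_enrichment is None else p.fold_enrichment
            if p.fdr is None:
                q = -1.0
            elif p.fdr == 0:
                q = 9999.0
            else:
                q = -math.log10(p.fdr)
            summit = -1 if p.summit_offset is None else p.summit_offset
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.id}\t{p.score}\t"
                f"{iv.strand}\t{fold:.6g}\t-1\t{q:.6g}\t{summit}\n"
            )


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------


def read_gtf(path: str | Path) -> GeneAnnotation:
    """Read gene models from a GTF file.

    Gene extents come from ``gene`` feature rows when present; otherwise a
    gene's extent is inferred as the union span of its exons. Records without
    a ``gene_id`` attribute are skipped with a warning; duplicate gene_id
    spans are merged to their union. Coordinates become 0-based half-open.
    """
    df = pr.read_gtf(str(path)).df
    if df.empty:
        raise ParseError(f"{path}: no usable gene records")
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: no record carries a gene_id attribute")
    missing = df["gene_id"].isna()
    if missing.any():
        logger.warning(
            "%s: skipped %d record(s) without gene_id", path, int(missing.sum())
        )
        df = df[~missing]

    gene_rows = df[df["Feature"] == "gene"]
    if gene_rows.empty:
        gene_rows = df[df["Feature"] == "exon"]
    if gene_rows.empty:
        raise ParseError(f"{path}: no usable gene records")

    genes: list[GeneModel] = []
    for gene_id, grp in gene_rows.groupby("gene_id", sort=True):
        start = int(grp["Start"].min())
        end = int(grp["End"].max())
        strands = set(grp["Strand"])
        if len(strands) > 1:
            raise ParseError(
                f"gene {gene_id}: records on conflicting strands {sorted(strands)}"
            )
        strand = strands.pop()
        if strand not in ("+", "-"):
            raise ParseError(
                f"gene {gene_id}: unstranded records are not supported "
                "(TSS derivation needs a strand)"
            )
        name = None
        if "gene_name" in grp.columns:
            names = grp["gene_name"].dropna()
            if not names.empty:
                name = str(names.iloc[0])
        genes.append(
            GeneModel(
                gene_id=str(gene_id),
                interval=GenomicInterval(str(grp["Chromosome"].iloc[0]),
                                         start, end, strand),
                strand=strand,
                gene_name=name,
            )
        )
    return GeneAnnotation(genes)


def write_gtf(annotation: GeneAnnotation, path: str | Path,
              source: str = "chirpkit") -> None:
    """Write an annotation as GTF ``gene`` rows (1-based inclusive)."""
    rows = sorted(
        annotation, key=lambda g: (g.interval.chrom, g.interval.start, g.gene_id)
    )
    with open(path, "w", newline="\n") as fh:
        for g in rows:
            attrs = f'gene_id "{g.gene_id}";'
            if g.gene_name:
                attrs += f' gene_name "{g.gene_name}";'
            fh.write(
                f"{g.interval.chrom}\t{source}\tgene\t{g.interval.start + 1}\t"
                f"{g.interval.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
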