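"""Differential-expression summaries and 2x2 gene-set overlap enrichment."""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import chi2 as chi2_dist


@dataclass(frozen=True)
class DERecord:
    gene_id: str
    log2fc: float
    qvalue: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.qvalue <= 1.0):
            raise ValueError(f"gene {self.gene_id}: qvalue must be in [0, 1]")
        if not math.isfinite(self.log2fc):
            raise ValueError(f"gene {self.gene_id}: log2fc must be finite")


@dataclass(frozen=True)
class DESummary:
    n_tested: int
    n_significant: int
    n_up: int
    n_down: int
    n_zero: int
    frac_up: float | None  # percent of significant genes up; None if 0 sig

    def as_dict(self) -> dict:
        return {
            "n_tested": self.n_tested,
            "n_significant": self.n_significant,
            "n_up": self.n_up,
            "n_down": self.n_down,
            "n_zero": self.n_zero,
            "frac_up_percent": self.frac_up,
        }


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a=|A∩B|, b=|A\\B|, c=|B\\A|, d=|neither| over a gene universe."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be >= 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_dict(self) -> dict:
        return {"a": self.a, "b": self.b, "c": self.c, "d": self.d, "n": self.n}


@dataclass(frozen=True)
class EnrichmentResult:
    chi2: float
    df: int
    pvalue: float
    odds_ratio: float
    low_expected_warning: bool

    def as_dict(self) -> dict:
        return {
            "chi2": self.chi2,
            "df": self.df,
            "pvalue": self.pvalue,
            "odds_ratio": self.odds_ratio,
            "low_expected_warning": self.low_expected_warning,
        }


@dataclass(frozen=True)
class OverlapPercentage:
    value: float
    rounded: int

    def as_dict(self) -> dict:
        return {"percent": self.value, "percent_rounded": self.rounded}


def read_de_table(path: str | Path) -> list[DERecord]:
    """Read a TSV with header columns gene_id, log2fc, qvalue (extras ignored)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "qvalue"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        DERecord(str(r.gene_id), float(r.log2fc), float(r.qvalue))
        for r in df.itertuples(index=False)
    ]


def de_summary(records: Iterable[DERecord], alpha: float = 0.05) -> DESummary:
    """Count significant (qvalue < alpha, strict) and up/down-regulated genes.

    ``frac_up`` is the percentage of significant genes with log2fc > 0;
    genes with log2fc exactly 0 are neither up nor down and are counted
    separately. Duplicate gene ids are an error.
    """
    seen: set[str] = set()
    n_tested = n_sig = n_up = n_down = n_zero = 0
    for rec in records:
        if rec.gene_id in seen:
            raise ValueError(f"duplicate gene_id {rec.gene_id!r}")
        seen.add(rec.gene_id)
        n_tested += 1
        if rec.qvalue < alpha:
            n_sig += 1
            if rec.log2fc > 0:
                n_up += 1
            elif rec.log2fc < 0:
                n_down += 1
            else:
                n_zero += 1
    frac_up = 100.0 * n_up / n_sig if n_sig else None
    return DESummary(n_tested, n_sig, n_up, n_down, n_zero, frac_up)


def overlap_counts(
    setA: set[str], setB: set[str], universe: set[str]
) -> ContingencyTable2x2:
    """Build the 2x2 membership table of setA x setB over a gene universe."""
    if not universe:
        raise ValueError("universe is empty")
    for name, s in (("setA", setA), ("setB", setB)):
        stray = s - universe
        if stray:
            raise ValueError(
                f"{name} contains {len(stray)} gene(s) outside the universe, "
                f"e.g. {sorted(stray)[:5]}"
            )
    a = len(setA & setB)
    b = len(setA - setB)
    c = len(setB - setA)
    d = len(universe) - a - b - c
    return ContingencyTable2x2(a, b, c, d)


def chi_squared_2x2(
    table: ContingencyTable2x2, yates: bool = False
) -> EnrichmentResult:
    """Pearson chi-squared test of independence on a 2x2 table, df = 1.

    No continuity correction by default; set ``yates=True`` for the
    corrected statistic. Degenerate margins (any zero row/column sum) are an
    error. ``low_expected_warning`` is set when any expected count < 5.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    n = table.n
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    if min(rows) == 0 or min(cols) == 0:
        raise ValueError("degenerate margin: a row or column sum is zero")
    observed = (a, b, c, d)
    expected = (
        rows[0] * cols[0] / n,
        rows[0] * cols[1] / n,
        rows[1] * cols[0] / n,
        rows[1] * cols[1] / n,
    )
    stat = 0.0
    for o, e in zip(observed, expected):
        diff = abs(o - e)
        if yates:
            diff = max(0.0, diff - 0.5)
        stat += diff * diff / e
    pvalue = float(chi2_dist.sf(stat, 1))
    odds = (a * d) / (b * c) if b * c > 0 else math.inf
    return EnrichmentResult(
        chi2=stat,
        df=1,
        pvalue=pvalue,
        odds_ratio=odds,
        low_expected_warning=min(expected) < 5,
    )


def overlap_percentage(n_overlap: int, n_total: int) -> OverlapPercentage:
    """Percentage n_overlap/n_total, with a half-away-from-zero rounding."""
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not (0 <= n_overlap <= n_total):
        raise ValueError("require 0 <= n_overlap <= n_total")
    value = 100.0 * n_overlap / n_total
    rounded = int(
        (Decimal(100 * n_overlap) / Decimal(n_total)).quantize(
            Decimal("1"), rounding=ROUND_HALF_UP
        )
    )
    return OverlapPercentage(value=value, rounded=rounded)
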