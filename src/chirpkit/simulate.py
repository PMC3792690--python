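"""Synthetic dataset generation with planted ground truth.

Every generated artifact is a pure function of ``(config, seed)``. One
global seed drives an independent named substream per generator, so changing
e.g. the DE parameters does not perturb peak placement.

True binding sites are mutually separated by at least
``noise_min_separation`` bp, and noise peaks keep the same separation from
every true site. With the default separation (25 kb) exceeding twice the
replication window (10 kb), no noise peak can replicate against a true-site
peak and no site can match another site's peak, which makes consensus
sensitivity an exact Binomial(n_true_sites, r^2) quantity.
"""

from __future__ import annotations

import bisect
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .io import (
    GeneAnnotation,
    GeneModel,
    GenomicInterval,
    Peak,
    PeakSet,
    write_gtf,
    write_narrowpeak,
)
from .stats import DERecord

_STREAMS = {"annotation": 0, "chirp": 1, "controls": 2, "de": 3}

GENE_MIN_SPACING = 1_000

DEFAULT_CHROM_LENGTHS = {f"chr{i}": 10_000_000 for i in range(1, 6)}


@dataclass
class SyntheticConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    n_genes: int = 2000
    gene_length_range: tuple[int, int] = (2_000, 10_000)
    n_true_sites: int = 500
    reproducibility: float = 0.9
    n_noise_per_replicate: int = 500
    noise_min_separation: int = 25_000
    n_subthreshold_per_replicate: int = 200
    n_controls: int = 3
    control_n_peaks: int = 300
    control_near_true_frac: float = 0.2
    fold_range_pass: tuple[float, float] = (25.0, 60.0)
    fold_range_fail: tuple[float, float] = (1.0, 15.0)
    fdr_range_pass: tuple[float, float] = (1e-6, 0.04)
    fdr_range_fail: tuple[float, float] = (0.06, 0.5)
    peak_width_range: tuple[int, int] = (200, 800)
    jitter_max: int = 200
    de_frac_significant: float = 0.3
    de_frac_up: float = 0.942
    de_planted_odds_ratio: float = 3.0
    de_alpha: float = 0.05
    log2fc_sigma: float = 0.5

    # thresholds the pass/fail ranges must straddle
    _MAX_FDR = 0.05
    _MIN_FOLD = 20.0

    def __post_init__(self) -> None:
        for name in ("reproducibility", "control_near_true_frac",
                     "de_frac_significant", "de_frac_up"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_genes", "n_true_sites", "n_noise_per_replicate",
                     "n_subthreshold_per_replicate", "n_controls",
                     "control_n_peaks", "noise_min_separation", "jitter_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.de_planted_odds_ratio <= 0:
            raise ValueError("de_planted_odds_ratio must be > 0")
        if not self.chrom_lengths:
            raise ValueError("chrom_lengths must be non-empty")
        if self.fold_range_pass[0] <= self._MIN_FOLD:
            raise ValueError("fold_range_pass must lie strictly above 20")
        if self.fold_range_fail[1] >= self._MIN_FOLD:
            raise ValueError("fold_range_fail must lie strictly below 20")
        if self.fdr_range_pass[1] >= self._MAX_FDR:
            raise ValueError("fdr_range_pass must lie strictly below 0.05")
        if self.fdr_range_fail[0] <= self._MAX_FDR:
            raise ValueError("fdr_range_fail must lie strictly above 0.05")

    def rng(self, stream: str) -> np.random.Generator:
        """Independent deterministic generator for a named substream."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(_STREAMS[stream],))
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gene_length_range"] = list(self.gene_length_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        for key in ("gene_length_range", "fold_range_pass", "fold_range_fail",
                    "fdr_range_pass", "fdr_range_fail", "peak_width_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Planted truth labels; every generated peak id belongs to exactly one
    category (true-site, noise, or sub-threshold)."""

    true_sites: list[dict]  # {"site_id", "chrom", "center"}
    site_peaks: dict[str, dict[str, str]]  # replicate label -> site_id -> peak id
    noise_peak_ids: dict[str, list[str]]
    subthreshold_peak_ids: dict[str, list[str]]
    control_near_site: dict[str, dict[str, str]]  # control label -> peak id -> site id
    de_labels: dict[str, dict] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# placement helpers
# ---------------------------------------------------------------------------


def _weighted_chrom_choice(rng, chroms: list[str], lengths: np.ndarray) -> str:
    return chroms[rng.choice(len(chroms), p=lengths / lengths.sum())]


def _too_close(sorted_pos: list[int], pos: int, sep: int) -> bool:
    i = bisect.bisect_left(sorted_pos, pos)
    if i > 0 and pos - sorted_pos[i - 1] < sep:
        return True
    return i < len(sorted_pos) and sorted_pos[i] - pos < sep


def _place_separated(
    rng: np.random.Generator,
    chrom_lengths: dict[str, int],
    n: int,
    avoid_sep: int,
    avoid: dict[str, list[int]] | None = None,
    self_sep: int | None = None,
    margin: int = 1_000,
) -> list[tuple[str, int]]:
    """Sample n (chrom, center) points by rejection.

    Each point keeps >= ``avoid_sep`` bp from every position in ``avoid``
    and >= ``self_sep`` bp from previously placed points (``self_sep=None``
    reuses ``avoid_sep``; 0 disables self-separation).
    """
    if self_sep is None:
        self_sep = avoid_sep
    chroms = sorted(chrom_lengths)
    lengths = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    avoided = {c: sorted(avoid.get(c, [])) if avoid else [] for c in chroms}
    own: dict[str, list[int]] = {c: [] for c in chroms}
    placed: list[tuple[str, int]] = []
    attempts = 0
    max_attempts = max(10_000, 400 * n)
    while len(placed) < n:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {n} points with separation {avoid_sep} bp; "
                "reduce counts or separation, or enlarge chromosomes"
            )
        chrom = _weighted_chrom_choice(rng, chroms, lengths)
        lo, hi = margin, chrom_lengths[chrom] - margin
        if hi <= lo:
            continue
        pos = int(rng.integers(lo, hi))
        if _too_close(avoided[chrom], pos, avoid_sep):
            continue
        if self_sep and _too_close(own[chrom], pos, self_sep):
            continue
        placed.append((chrom, pos))
        if self_sep:
            bisect.insort(own[chrom], pos)
    return placed


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_annotation(config: SyntheticConfig) -> GeneAnnotation:
    """Place non-nested genes with >= 1 kb spacing, random strand."""
    rng = config.rng("annotation")
    lo, hi = config.gene_length_range
    if not (0 < lo <= hi):
        raise ValueError("gene_length_range must satisfy 0 < lo <= hi")
    chroms = sorted(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    # track occupied [start, end) spans per chromosome, sorted by start
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes: list[GeneModel] = []
    attempts = 0
    max_attempts = max(10_000, 200 * config.n_genes)
    while len(genes) < config.n_genes:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                f"could not place {config.n_genes} genes with "
                f"{GENE_MIN_SPACING} bp spacing; reduce n_genes, shorten "
                "gene_length_range or enlarge chromosomes"
            )
        chrom = _weighted_chrom_choice(rng, chroms, lengths)
        glen = int(rng.integers(lo, hi + 1))
        limit = config.chrom_lengths[chrom] - glen
        if limit <= 0:
            continue
        start = int(rng.integers(0, limit))
        end = start + glen
        spans = occupied[chrom]
        i = bisect.bisect_left(spans, (start, end))
        if i > 0 and start - spans[i - 1][1] < GENE_MIN_SPACING:
            continue
        if i < len(spans) and spans[i][0] - end < GENE_MIN_SPACING:
            continue
        spans.insert(i, (start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        idx = len(genes) + 1
        genes.append(
            GeneModel(
                gene_id=f"gene{idx:05d}",
                interval=GenomicInterval(chrom, start, end, strand),
                strand=strand,
                gene_name=f"GENE{idx:05d}",
            )
        )
    return GeneAnnotation(genes)


def _draw_peak(
    rng: np.random.Generator,
    peak_id: str,
    chrom: str,
    center: int,
    chrom_len: int,
    config: SyntheticConfig,
    fold_range: tuple[float, float],
    fdr_range: tuple[float, float],
) -> Peak:
    width = int(rng.integers(config.peak_width_range[0],
                             config.peak_width_range[1] + 1))
    jitter = int(rng.integers(-config.jitter_max, config.jitter_max + 1))
    c = center + jitter
    start = max(0, c - width // 2)
    end = min(chrom_len, start + width)
    start = min(start, end - 1)
    summit = min(max(c, start), end - 1) - start
    fold = float(rng.uniform(*fold_range))
    fdr = float(rng.uniform(*fdr_range))
    return Peak(
        id=peak_id,
        interval=GenomicInterval(chrom, start, end, "."),
        summit_offset=summit,
        fold_enrichment=fold,
        fdr=fdr,
        score=int(10 * fold),
    )


def generate_chirp_experiment(
    config: SyntheticConfig,
    annotation: GeneAnnotation | None = None,
    replication_window: int = 10_000,
) -> tuple[PeakSet, PeakSet, list[PeakSet], GroundTruth]:
    """Generate two treatment replicates plus control peak sets.

    Each true site yields a peak in each replicate independently with
    probability ``reproducibility``, jittered and width-sampled within the
    configured ranges, with fold/FDR from the passing ranges. Noise peaks are
    separated from all true sites; a sub-threshold tranche (failing fold or
    FDR ranges) exercises the quality filter. Controls place a configurable
    fraction of their peaks near true sites.

    ``annotation`` is accepted for signature symmetry; site placement is
    independent of gene positions.
    """
    if config.noise_min_separation <= 2 * replication_window:
        warnings.warn(
            "noise_min_separation <= 2 * replication_window: noise peaks may "
            "replicate against true-site peaks (truth labels remain exact)",
            stacklevel=2,
        )
    rng = config.rng("chirp")
    margin = max(1_000, config.peak_width_range[1] + config.jitter_max)
    sites = _place_separated(
        rng, config.chrom_lengths, config.n_true_sites,
        config.noise_min_separation, margin=margin,
    )
    true_sites = [
        {"site_id": f"site{i + 1:05d}", "chrom": c, "center": pos}
        for i, (c, pos) in enumerate(sites)
    ]
    site_positions = {c: [] for c in config.chrom_lengths}
    for c, pos in sites:
        bisect.insort(site_positions[c], pos)

    # noise centres for BOTH replicates drawn jointly: each keeps the full
    # separation from true sites, and enough mutual separation that two
    # noise peaks can never fall within the replication window of each other
    max_extent = config.jitter_max + (config.peak_width_range[1] + 1) // 2
    noise_self_sep = replication_window + 2 * max_extent + 1
    noise_all = _place_separated(
        rng, config.chrom_lengths, 2 * config.n_noise_per_replicate,
        config.noise_min_separation, avoid=site_positions,
        self_sep=noise_self_sep, margin=margin,
    )
    noise_by_label = {
        "repA": noise_all[: config.n_noise_per_replicate],
        "repB": noise_all[config.n_noise_per_replicate:],
    }

    site_peaks: dict[str, dict[str, str]] = {}
    noise_ids: dict[str, list[str]] = {}
    sub_ids: dict[str, list[str]] = {}
    replicates: list[PeakSet] = []
    for label in ("repA", "repB"):
        peaks: list[Peak] = []
        site_peaks[label] = {}
        for site in true_sites:
            if rng.random() >= config.reproducibility:
                continue
            pid = f"{label}_{site['site_id']}"
            peaks.append(
                _draw_peak(
                    rng, pid, site["chrom"], site["center"],
                    config.chrom_lengths[site["chrom"]], config,
                    config.fold_range_pass, config.fdr_range_pass,
                )
            )
            site_peaks[label][site["site_id"]] = pid
        noise_ids[label] = []
        for i, (chrom, pos) in enumerate(noise_by_label[label]):
            pid = f"{label}_noise{i + 1:05d}"
            peaks.append(
                _draw_peak(
                    rng, pid, chrom, pos, config.chrom_lengths[chrom], config,
                    config.fold_range_pass, config.fdr_range_pass,
                )
            )
            noise_ids[label].append(pid)
        sub_ids[label] = []
        for i in range(config.n_subthreshold_per_replicate):
            chrom = sorted(config.chrom_lengths)[
                int(rng.integers(0, len(config.chrom_lengths)))
            ]
            pos = int(rng.integers(1_000, config.chrom_lengths[chrom] - 1_000))
            pid = f"{label}_sub{i + 1:05d}"
            # alternate failure cause: bad fold, bad fdr, or both
            fail_fold = i % 3 != 1
            fail_fdr = i % 3 != 0
            peaks.append(
                _draw_peak(
                    rng, pid, chrom, pos, config.chrom_lengths[chrom], config,
                    config.fold_range_fail if fail_fold else config.fold_range_pass,
                    config.fdr_range_fail if fail_fdr else config.fdr_range_pass,
                )
            )
            sub_ids[label].append(pid)
        replicates.append(
            PeakSet(label=label, role="treatment_replicate", peaks=peaks)
        )

    crng = config.rng("controls")
    controls: list[PeakSet] = []
    control_near: dict[str, dict[str, str]] = {}
    n_near = int(round(config.control_near_true_frac * config.control_n_peaks))
    for ci in range(config.n_controls):
        label = f"control{ci + 1}"
        peaks = []
        control_near[label] = {}
        near_window = 10_000
        for i in range(n_near):
            if not true_sites:
                break
            site = true_sites[int(crng.integers(0, len(true_sites)))]
            offset = int(crng.integers(1_000, max(2_000, near_window - 1_000)))
            sign = 1 if crng.random() < 0.5 else -1
            pos = site["center"] + sign * offset
            chrom_len = config.chrom_lengths[site["chrom"]]
            pos = min(max(pos, 1_000), chrom_len - 1_000)
            pid = f"{label}_near{i + 1:05d}"
            peaks.append(
                _draw_peak(
                    crng, pid, site["chrom"], pos, chrom_len, config,
                    config.fold_range_pass, config.fdr_range_pass,
                )
            )
            control_near[label][pid] = site["site_id"]
        far_pos = _place_separated(
            crng, config.chrom_lengths, config.control_n_peaks - n_near,
            config.noise_min_separation, avoid=site_positions,
            self_sep=0, margin=margin,
        )
        for i, (chrom, pos) in enumerate(far_pos):
            pid = f"{label}_far{i + 1:05d}"
            peaks.append(
                _draw_peak(
                    crng, pid, chrom, pos, config.chrom_lengths[chrom], config,
                    config.fold_range_pass, config.fdr_range_pass,
                )
            )
        controls.append(PeakSet(label=label, role="control", peaks=peaks))

    truth = GroundTruth(
        true_sites=true_sites,
        site_peaks=site_peaks,
        noise_peak_ids=noise_ids,
        subthreshold_peak_ids=sub_ids,
        control_near_site=control_near,
    )
    return replicates[0], replicates[1], controls, truth


def solve_significance_rates(
    n_chirp: int, n_other: int, overall_rate: float, odds_ratio: float
) -> tuple[float, float]:
    """Per-group significance probabilities (p_chirp, p_other) with the
    planted odds ratio and the requested overall significant fraction."""
    n = n_chirp + n_other
    if n == 0:
        raise ValueError("empty gene universe")
    if overall_rate == 0.0:
        return 0.0, 0.0
    if overall_rate == 1.0:
        if odds_ratio != 1.0:
            raise ValueError(
                "overall_rate = 1 forces both groups to probability 1, "
                "incompatible with odds_ratio != 1"
            )
        return 1.0, 1.0
    if odds_ratio == 1.0 or n_chirp == 0 or n_other == 0:
        return overall_rate, overall_rate

    def p1(p0: float) -> float:
        return odds_ratio * p0 / (1.0 + (odds_ratio - 1.0) * p0)

    def mean_gap(p0: float) -> float:
        return (n_chirp * p1(p0) + n_other * p0) / n - overall_rate

    p0 = float(brentq(mean_gap, 1e-12, 1.0 - 1e-12))
    return p1(p0), p0


def generate_de_table(
    config: SyntheticConfig,
    annotation: GeneAnnotation,
    chirp_genes: set[str],
) -> tuple[list[DERecord], dict[str, dict]]:
    """Generate per-gene DE records with a planted chirp-gene enrichment.

    Significance is Bernoulli per gene with per-group rates solving the
    planted odds ratio at the overall rate; significant genes get
    ``qvalue ~ U(0, alpha)`` and ``|log2fc|`` from LogNormal(0, sigma) with
    sign up with probability ``de_frac_up``; others get
    ``qvalue ~ U(alpha, 1)`` and a small centred log2fc.
    """
    gene_ids = sorted(g.gene_id for g in annotation)
    stray = chirp_genes - set(gene_ids)
    if stray:
        raise ValueError(
            f"chirp_genes contains {len(stray)} id(s) not in the annotation"
        )
    n_chirp = len(chirp_genes)
    p_chirp, p_other = solve_significance_rates(
        n_chirp, len(gene_ids) - n_chirp,
        config.de_frac_significant, config.de_planted_odds_ratio,
    )
    rng = config.rng("de")
    records: list[DERecord] = []
    labels: dict[str, dict] = {}
    for gid in gene_ids:
        p = p_chirp if gid in chirp_genes else p_other
        significant = bool(rng.random() < p)
        if significant:
            up = bool(rng.random() < config.de_frac_up)
            mag = float(rng.lognormal(0.0, config.log2fc_sigma))
            log2fc = mag if up else -mag
            qvalue = float(rng.uniform(0.0, config.de_alpha))
        else:
            up = None
            log2fc = float(rng.normal(0.0, 0.1))
            qvalue = float(rng.uniform(config.de_alpha, 1.0))
        records.append(DERecord(gid, log2fc, qvalue))
        labels[gid] = {"significant": significant, "up": up,
                       "chirp": gid in chirp_genes}
    return records, labels


def write_de_table(records: Sequence[DERecord], path: str | Path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("gene_id\tlog2fc\tqvalue\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.log2fc:.10g}\t{r.qvalue:.10g}\n")


def simulate_dataset(config: SyntheticConfig, outdir: str | Path) -> dict:
    """Write a complete synthetic dataset plus truth and a run config.

    Emits ``annotation.gtf``, ``repA.narrowPeak``, ``repB.narrowPeak``,
    ``control*.narrowPeak``, ``de_table.tsv``, ``truth.json`` and
    ``config.yaml`` (consumable by the pipeline runner). Returns the file map.
    """
    from .genes import assign_closest_gene, chirp_gene_set
    from .peaks import Thresholds, filter_peaks, flag_control_proximity, \
        replicate_consensus

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thresholds = Thresholds()

    annotation = generate_annotation(config)
    repA, repB, controls, truth = generate_chirp_experiment(
        config, annotation, replication_window=thresholds.replication_window
    )

    # derive the planted-enrichment target gene set with the real pipeline
    fA = filter_peaks(repA, thresholds)
    fB = filter_peaks(repB, thresholds)
    consensus = replicate_consensus(fA, fB, thresholds.replication_window)
    consensus = flag_control_proximity(
        consensus, [filter_peaks(c, thresholds) for c in controls],
        thresholds.control_window,
    )
    assignments = assign_closest_gene(
        consensus.specific, annotation, thresholds.gene_max_dist
    )
    chirp_genes = chirp_gene_set(assignments)

    de_records, de_labels = generate_de_table(config, annotation, chirp_genes)
    truth.de_labels = de_labels

    files = {"gtf": outdir / "annotation.gtf",
             "rep_a": outdir / "repA.narrowPeak",
             "rep_b": outdir / "repB.narrowPeak",
             "de_table": outdir / "de_table.tsv",
             "truth": outdir / "truth.json",
             "config": outdir / "config.yaml"}
    write_gtf(annotation, files["gtf"])
    write_narrowpeak(repA, files["rep_a"])
    write_narrowpeak(repB, files["rep_b"])
    control_paths = []
    for cs in controls:
        p = outdir / f"{cs.label}.narrowPeak"
        write_narrowpeak(cs, p)
        control_paths.append(p)
    write_de_table(de_records, files["de_table"])
    with open(files["truth"], "w", newline="\n") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")

    import yaml

    run_config = {
        "rep_a": str(files["rep_a"]),
        "rep_b": str(files["rep_b"]),
        "controls": [str(p) for p in control_paths],
        "gtf": str(files["gtf"]),
        "de_table": str(files["de_table"]),
        "outdir": str(outdir / "results"),
        "thresholds": {
            "max_fdr": thresholds.max_fdr,
            "min_fold": thresholds.min_fold,
            "replication_window": thresholds.replication_window,
            "control_window": thresholds.control_window,
            "gene_max_dist": thresholds.gene_max_dist,
            "de_alpha": thresholds.de_alpha,
        },
        "seed": config.seed,
    }
    with open(files["config"], "w", newline="\n") as fh:
        yaml.safe_dump(run_config, fh, sort_keys=True)
    files["controls"] = control_paths
    return {k: v for k, v in files.items()}
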