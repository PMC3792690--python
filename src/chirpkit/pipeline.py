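"""End-to-end pipeline: filter -> replicate -> control screen -> gene map ->
TSS profile -> DE summary -> overlap enrichment, with a JSON report."""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .genes import assign_closest_gene, chirp_gene_set, tss_distance_profile
from .io import read_gtf, read_narrowpeak, write_bed
from .peaks import (
    Thresholds,
    filter_peaks,
    flag_control_proximity,
    replicate_consensus,
)
from .stats import (
    chi_squared_2x2,
    de_summary,
    overlap_counts,
    overlap_percentage,
    read_de_table,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    rep_a: str
    rep_b: str
    controls: list[str]
    gtf: str
    de_table: str
    outdir: str
    thresholds: Thresholds = field(default_factory=Thresholds)
    window_mode: str = "gap"            # "gap" | "summit"
    exclude_control_proximal: bool = True
    gene_distance_mode: str = "gene_body"  # "gene_body" | "tss_midpoint"
    yates: bool = False
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        thresholds = Thresholds(**raw.pop("thresholds", {}))
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(thresholds=thresholds, **raw)

    def to_dict(self) -> dict:
        return {
            "rep_a": self.rep_a,
            "rep_b": self.rep_b,
            "controls": list(self.controls),
            "gtf": self.gtf,
            "de_table": self.de_table,
            "outdir": self.outdir,
            "thresholds": {
                k: getattr(self.thresholds, k)
                for k in ("max_fdr", "min_fold", "replication_window",
                          "control_window", "gene_max_dist", "de_alpha")
            },
            "window_mode": self.window_mode,
            "exclude_control_proximal": self.exclude_control_proximal,
            "gene_distance_mode": self.gene_distance_mode,
            "yates": self.yates,
            "seed": self.seed,
        }


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            return out

        return wrapper

    return deco


def _sanitize(obj):
    """Replace non-finite floats with strings so JSON stays strict."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float) and not math.isfinite(obj):
        return "inf" if obj > 0 else "-inf"
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and write output files plus ``report.json``.

    Returns the report as a dict. Output files: ``consensus.bed``,
    ``specific.bed``, ``peak_gene.tsv``, ``chirp_genes.txt``,
    ``tss_profile.tsv``, ``de_summary.json``, ``enrichment.json``,
    ``report.json`` and ``run.log``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    root = logging.getLogger("chirpkit")
    root.addHandler(log_handler)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    t = config.thresholds

    try:
        for label, path in [("rep_a", config.rep_a), ("rep_b", config.rep_b),
                            ("gtf", config.gtf), ("de_table", config.de_table),
                            *[("control", c) for c in config.controls]]:
            if not Path(path).exists():
                raise StageError(f"stage 'inputs' failed: {label} path "
                                 f"{path!r} does not exist")

        repA = read_narrowpeak(config.rep_a, label="repA",
                               role="treatment_replicate")
        repB = read_narrowpeak(config.rep_b, label="repB",
                               role="treatment_replicate")
        controls = [
            read_narrowpeak(p, label=f"control{i + 1}", role="control")
            for i, p in enumerate(config.controls)
        ]
        annotation = read_gtf(config.gtf)
        de_records = read_de_table(config.de_table)

        fA = filter_peaks(repA, t)
        fB = filter_peaks(repB, t)
        f_controls = [filter_peaks(c, t) for c in controls]
        logger.info("filter: repA %d -> %d, repB %d -> %d",
                    len(repA), len(fA), len(repB), len(fB))

        consensus = replicate_consensus(
            fA, fB, t.replication_window, mode=config.window_mode
        )
        logger.info("consensus: %d replicated of %d repA peaks",
                    consensus.n_replicated, consensus.n_repA_in)
        consensus = flag_control_proximity(
            consensus, f_controls, t.control_window
        )
        logger.info("control screen: %d proximal, %d specific",
                    consensus.n_control_proximal, len(consensus.specific))

        target_peaks = (
            consensus.specific
            if config.exclude_control_proximal
            else consensus.consensus
        )
        assignments = assign_closest_gene(
            target_peaks, annotation, t.gene_max_dist,
            mode=config.gene_distance_mode,
        )
        genes = chirp_gene_set(assignments)
        profile = tss_distance_profile(target_peaks, annotation)
        logger.info("gene map: %d/%d peaks assigned, %d distinct genes",
                    sum(1 for a in assignments if a.gene_id), len(assignments),
                    len(genes))

        summary = de_summary(de_records, t.de_alpha)
        de_by_id = {r.gene_id for r in de_records}
        universe = annotation.gene_ids & de_by_id
        set_chirp = genes & universe
        set_de = {
            r.gene_id for r in de_records if r.qvalue < t.de_alpha
        } & universe
        table = overlap_counts(set_chirp, set_de, universe)
        enrichment = chi_squared_2x2(table, yates=config.yates)
        pct = (
            overlap_percentage(table.a, len(set_chirp))
            if set_chirp
            else None
        )
        logger.info("enrichment: chi2=%.4g p=%.4g", enrichment.chi2,
                    enrichment.pvalue)

        # --- outputs -----------------------------------------------------
        write_bed(consensus.consensus, outdir / "consensus.bed")
        write_bed(consensus.specific, outdir / "specific.bed")
        with open(outdir / "consensus.tsv", "w", newline="\n") as fh:
            fh.write(
                "peak_id\tchrom\tstart\tend\tmin_partner_gap\t"
                "nearest_control_gap\tcontrol_proximal\n"
            )
            for c in consensus.consensus:
                ncg = (
                    "inf"
                    if math.isinf(c.nearest_control_gap)
                    else int(c.nearest_control_gap)
                )
                fh.write(
                    f"{c.id}\t{c.interval.chrom}\t{c.interval.start}\t"
                    f"{c.interval.end}\t{int(c.min_partner_gap)}\t{ncg}\t"
                    f"{int(c.control_proximal)}\n"
                )
        with open(outdir / "peak_gene.tsv", "w", newline="\n") as fh:
            fh.write("peak_id\tgene_id\tdistance\ttie_broken\n")
            for a in assignments:
                fh.write(
                    f"{a.peak_id}\t{a.gene_id or '.'}\t"
                    f"{'.' if a.distance is None else a.distance}\t"
                    f"{int(a.tie_broken)}\n"
                )
        with open(outdir / "chirp_genes.txt", "w", newline="\n") as fh:
            for gid in sorted(genes):
                fh.write(gid + "\n")
        with open(outdir / "tss_profile.tsv", "w", newline="\n") as fh:
            fh.write("bin\tcount\n")
            for lab, cnt in zip(profile.labels, profile.counts):
                fh.write(f"{lab}\t{cnt}\n")
        with open(outdir / "de_summary.json", "w", newline="\n") as fh:
            json.dump(summary.as_dict(), fh, indent=1)
            fh.write("\n")
        with open(outdir / "enrichment.json", "w", newline="\n") as fh:
            json.dump(
                _sanitize({
                    "contingency": table.as_dict(),
                    "enrichment": enrichment.as_dict(),
                    "overlap": pct.as_dict() if pct else None,
                }),
                fh, indent=1,
            )
            fh.write("\n")

        report = {
            "counts": {
                "repA_in": len(repA),
                "repA_filtered": len(fA),
                "repB_in": len(repB),
                "repB_filtered": len(fB),
                "controls_in": [len(c) for c in controls],
                "controls_filtered": [len(c) for c in f_controls],
                "n_replicated": consensus.n_replicated,
                "n_control_proximal": consensus.n_control_proximal,
                "n_specific": len(consensus.specific),
                "n_controls_in_window": consensus.n_controls_in_window,
                "n_peaks_assigned": sum(1 for a in assignments if a.gene_id),
                "n_chirp_genes": len(genes),
            },
            "tss_profile": profile.as_dict(),
            "tss_profile_excluded": profile.n_excluded,
            "de_summary": summary.as_dict(),
            "universe_size": len(universe),
            "contingency": table.as_dict(),
            "enrichment": enrichment.as_dict(),
            "overlap_percentage": pct.as_dict() if pct else None,
            "provenance": {
                "version": __version__,
                "config": config.to_dict(),
                "started": started,
                "finished": time.strftime("%Y-%m-%dT%H:%M:%S"),
            },
        }
        report = _sanitize(report)
        with open(outdir / "report.json", "w", newline="\n") as fh:
            json.dump(report, fh, indent=1)
            fh.write("\n")
        return report
    except StageError:
        raise
    except Exception as exc:  # annotate with a stage hint
        raise StageError(f"pipeline failed: {exc}") from exc
    finally:
        root.removeHandler(log_handler)
        log_handler.close()
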