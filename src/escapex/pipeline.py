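"""End-to-end pipeline: simulate -> QC -> screen -> enrichment -> overlap ->
domain pairing -> co-localization permutation -> peak coverage -> qPCR.

Every stochastic stage consumes a sub-seed derived deterministically from the
global seed and the stage name, so identical configs yield byte-identical
summaries and individual stages can be re-run in isolation with the same
randomness.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .core import ProbeAnnotation
from .domains import (
    DEFAULT_ANCHOR_GENES,
    PermutationSpec,
    coloc_permutation_fdr,
    domain_peak_coverage,
    domains_to_frame,
    pair_coding_noncoding,
)
from .enrichment import enrichment_table
from .io import (
    ensure_dir,
    genome_spec_from_dict,
    load_yaml,
    simulation_config_from_dict,
    write_annotation_bed,
    write_expression,
    write_peaks_bed,
    write_qpcr,
)
from .overlap import venn_regions
from .qc import balance_by_sex, report_to_frame, standardize_arrays, xist_sex_check
from .qpcr import analyze_qpcr
from .screen import results_to_frame, screen_tissue
from .synthetic import (
    GenomeSpec,
    SimulationConfig,
    generate_annotation,
    generate_expression,
    generate_peaks,
    generate_qpcr,
)

logger = logging.getLogger("escapex.pipeline")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """One seeded, configured pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    alpha: float = 0.05
    k: int = 4
    window: int = 50_000
    n_perm: int = 10_000
    max_gap: int = 50_000
    flank: int = 100_000
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = load_yaml(path)
        kwargs = {}
        if "simulation" in raw:
            kwargs["simulation"] = simulation_config_from_dict(raw["simulation"])
        kwargs["genome"] = genome_spec_from_dict(raw.get("genome"))
        for key in ("alpha", "k", "window", "n_perm", "max_gap", "flank",
                    "seed", "outdir"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class RunSummary:
    """Machine-readable result of one pipeline run."""

    version: str
    seed: int
    hit_counts: dict  # tissue -> {female_up, male_up}
    enrichment: list  # rows of tissue/chr/obs/exp/p
    overlap_regions: dict  # platform -> {"t1+t2": [genes...]}
    domains: list  # coding/noncoding/gap/relation dicts
    coloc_fdr: float
    coloc_successes: int
    peak_coverage: list  # name/inside/flank_mean/depletion_ratio
    qpcr: list  # tissue/gene/ratio/p/stars rows
    qc_flagged: list

    def to_json(self) -> str:
        def default(o):
            if o is math.inf:
                return "inf"
            raise TypeError(type(o))
        payload = dataclasses.asdict(self)
        return json.dumps(payload, indent=2, sort_keys=True, default=default)

    @classmethod
    def from_json(cls, text: str) -> "RunSummary":
        return cls(**json.loads(text))


def _screen_all_tissues(matrix, annotation, alpha):
    hits = {}
    for tissue in matrix.tissues():
        hits[tissue] = screen_tissue(matrix.tissue(tissue), annotation, alpha)
    return hits


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute all stages in order and return (and optionally write) the
    summary. Any stage error aborts with the failing stage named."""
    outdir = ensure_dir(config.outdir) if config.outdir else None
    stage = "setup"
    try:
        stage = "simulate"
        logger.info("stage=%s seed=%d", stage, stage_seed(config.seed, stage))
        annotation = generate_annotation(
            config.genome, config.simulation.n_probes,
            stage_seed(config.seed, "annotation"),
        )
        matrix, truth = generate_expression(
            config.simulation, annotation, stage_seed(config.seed, "expression")
        )
        peaks = generate_peaks(annotation, stage_seed(config.seed, "peaks"))
        qpcr_data = generate_qpcr(config.simulation, stage_seed(config.seed, "qpcr"))

        stage = "qc"
        matrix = standardize_arrays(matrix)
        xist_probes = [
            p for g, role in annotation.gene_roles.items() if role == "xist"
            for p in annotation.probes_for_gene(g)
        ]
        report = xist_sex_check(matrix, xist_probes)
        balanced = balance_by_sex(matrix, report, stage_seed(config.seed, "balance"))

        stage = "screen"
        hits = _screen_all_tissues(balanced, annotation, config.alpha)
        hit_counts = {
            t: {
                "female_up": sum(1 for h in hs if h.direction == "female_up"),
                "male_up": sum(1 for h in hs if h.direction == "male_up"),
            }
            for t, hs in hits.items()
        }

        stage = "enrich"
        enrich = enrichment_table(hits, annotation)

        stage = "overlap"
        platforms: dict[str, dict[str, set]] = {}
        for t, hs in hits.items():
            plat = config.simulation.platform_of(t)
            platforms.setdefault(plat, {})[t] = {h.gene for h in hs}
        overlap_regions: dict[str, dict[str, list[str]]] = {}
        for plat, lists in platforms.items():
            if len(lists) < 2:
                continue
            regions = venn_regions(lists)
            overlap_regions[plat] = {
                "+".join(sorted(k)): sorted(v) for k, v in regions.items()
            }

        stage = "domains"
        female_biased = sorted(
            {h.gene for hs in hits.values() for h in hs
             if h.direction == "female_up"}
        )
        domains, _unpaired = pair_coding_noncoding(
            female_biased, annotation, config.max_gap
        )

        stage = "coloc"
        anchors = tuple(
            g for g in DEFAULT_ANCHOR_GENES
            if g in set(annotation.table["gene"])
        )
        fdr, successes = coloc_permutation_fdr(
            PermutationSpec(
                anchors=anchors, k=config.k, window=config.window,
                n_perm=config.n_perm, seed=stage_seed(config.seed, "coloc"),
            ),
            annotation,
        )

        stage = "peakcov"
        coverage_rows = []
        for d in annotation.domains:
            cov = domain_peak_coverage(d.span, peaks, config.flank)
            coverage_rows.append(
                {
                    "name": f"{d.coding}|{d.noncoding}",
                    "inside": cov.inside,
                    "flank_mean": cov.flank_mean,
                    "depletion_ratio": (
                        "inf" if math.isinf(cov.depletion_ratio)
                        else cov.depletion_ratio
                    ),
                }
            )
        control_genes = [
            g for g, role in annotation.gene_roles.items()
            if role == "inactive_control"
        ]
        for g in control_genes:
            cov = domain_peak_coverage(
                annotation.gene_interval(g), peaks, config.flank
            )
            coverage_rows.append(
                {
                    "name": g, "inside": cov.inside,
                    "flank_mean": cov.flank_mean,
                    "depletion_ratio": (
                        "inf" if math.isinf(cov.depletion_ratio)
                        else cov.depletion_ratio
                    ),
                }
            )

        stage = "qpcr"
        qpcr_table = analyze_qpcr(qpcr_data)

        stage = "summarize"
        summary = RunSummary(
            version=__version__,
            seed=config.seed,
            hit_counts=hit_counts,
            enrichment=enrich.to_dict(orient="records"),
            overlap_regions=overlap_regions,
            domains=domains_to_frame(domains).to_dict(orient="records"),
            coloc_fdr=fdr,
            coloc_successes=successes,
            peak_coverage=coverage_rows,
            qpcr=qpcr_table.to_dict(orient="records"),
            qc_flagged=sorted(report.flagged),
        )

        if outdir is not None:
            stage = "write"
            write_annotation_bed(annotation, outdir / "annotation.bed")
            write_expression(matrix, outdir / "expression.tsv",
                             outdir / "samples.tsv")
            write_peaks_bed(peaks, outdir / "peaks.bed")
            write_qpcr(qpcr_data, outdir / "qpcr_ct.tsv",
                       outdir / "qpcr_dilutions.tsv")
            report_to_frame(report).to_csv(outdir / "qc_report.tsv", sep="\t")
            for t, hs in hits.items():
                results_to_frame(hs).to_csv(
                    outdir / f"screen_{t}.tsv", sep="\t", index=False
                )
            enrich.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
            domains_to_frame(domains).to_csv(
                outdir / "domains.bed", sep="\t", index=False, header=False
            )
            (outdir / "summary.json").write_text(summary.to_json())
        return summary
    except Exception:
        logger.exception("pipeline failed at stage %r", stage)
        raise
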