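"""Plain-text readers/writers: BED6+2 annotation, expression/metadata TSV,
BED3 peaks, qPCR TSVs and YAML run configs."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .core import ANNOTATION_COLUMNS, ExpressionMatrix, ProbeAnnotation
from .domains import PeakSet
from .synthetic import (
    DomainTemplate,
    GenomeSpec,
    GeneTemplate,
    QPCRDataset,
    SimulationConfig,
)


def write_annotation_bed(annotation: ProbeAnnotation, path) -> None:
    """BED6 plus gene symbol and biotype columns; name column = probe id."""
    cols = ["chrom", "start", "end", "probe_id", "score", "strand",
            "gene", "biotype"]
    annotation.table[cols].to_csv(path, sep="\t", header=False, index=False)


def read_annotation_bed(path, chrom_sizes: dict[str, int] | None = None) -> ProbeAnnotation:
    table = pd.read_csv(path, sep="\t", header=None, names=ANNOTATION_COLUMNS)
    if chrom_sizes is None:
        chrom_sizes = {
            c: int(g["end"].max()) for c, g in table.groupby("chrom")
        }
    return ProbeAnnotation(table=table, chrom_sizes=chrom_sizes)


def write_expression(matrix: ExpressionMatrix, expr_path, meta_path) -> None:
    """Expression as probes x samples TSV plus a sample-metadata sidecar."""
    out = matrix.values.copy()
    out.index.name = "probe_id"
    out.to_csv(expr_path, sep="\t")
    matrix.samples.to_csv(meta_path, sep="\t")


def read_expression(expr_path, meta_path) -> ExpressionMatrix:
    values = pd.read_csv(expr_path, sep="\t", index_col=0)
    samples = pd.read_csv(meta_path, sep="\t", index_col=0)
    return ExpressionMatrix(values=values, samples=samples)


def write_peaks_bed(peaks: PeakSet, path) -> None:
    peaks.intervals[["chrom", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_peaks_bed(path, mark: str = "H3K27me3", sample_sex: str = "F") -> PeakSet:
    table = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["chrom", "start", "end"],
    )
    return PeakSet(intervals=table, mark=mark, sample_sex=sample_sex)


def write_qpcr(dataset: QPCRDataset, ct_path, dilution_path) -> None:
    dataset.measurements.to_csv(ct_path, sep="\t", index=False)
    dataset.dilution_series.to_csv(dilution_path, sep="\t", index=False)


def read_qpcr(
    ct_path, dilution_path, reference_genes=("Actb", "Gapdh")
) -> QPCRDataset:
    return QPCRDataset(
        measurements=pd.read_csv(ct_path, sep="\t"),
        dilution_series=pd.read_csv(dilution_path, sep="\t"),
        reference_genes=tuple(reference_genes),
        true_ratios={},
    )


def simulation_config_from_dict(block: dict) -> SimulationConfig:
    block = dict(block)
    for key in ("effect_range_log2", "escapee_effect_range_log2",
                "qpcr_dilutions", "qpcr_reference_genes", "tissues"):
        if key in block and block[key] is not None:
            block[key] = tuple(block[key])
    return SimulationConfig(**block)


def genome_spec_from_dict(block: dict | None) -> GenomeSpec:
    if not block:
        return GenomeSpec()
    block = dict(block)
    if "domain_templates" in block:
        block["domain_templates"] = [
            DomainTemplate(**d) for d in block["domain_templates"]
        ]
    if "single_genes" in block:
        block["single_genes"] = [GeneTemplate(**g) for g in block["single_genes"]]
    return GenomeSpec(**block)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
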