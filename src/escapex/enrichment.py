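"""Per-chromosome observed vs expected counts of sex-biased genes.

Counting is gene-level (distinct symbols), the expected count is
proportional to each chromosome's share of annotated genes, and
over-representation is assessed with the hypergeometric upper tail
(sampling significant genes without replacement from the array's gene
universe).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .core import ProbeAnnotation
from .screen import SexBiasResult


@dataclass(frozen=True)
class EnrichmentRow:
    tissue: str
    chromosome: str
    observed: int
    expected: float
    p: float

    def __post_init__(self) -> None:
        if self.observed < 0 or self.expected < 0:
            raise ValueError("counts must be non-negative")
        if not (0 < self.p <= 1):
            raise ValueError("p must lie in (0, 1]")


def _hit_genes(hits: Iterable[SexBiasResult]) -> list[str]:
    return list(dict.fromkeys(h.gene for h in hits))


def count_by_chromosome(
    hits: Iterable[SexBiasResult], annotation: ProbeAnnotation
) -> dict[str, int]:
    """Distinct significant gene symbols per chromosome.

    Multiple significant probes of one gene count once. Raises listing any
    hit gene missing from the annotation.
    """
    gene_chrom = annotation.gene_chromosome()
    genes = _hit_genes(hits)
    missing = [g for g in genes if g not in gene_chrom.index]
    if missing:
        raise KeyError(f"hit genes without annotation: {missing}")
    counts: dict[str, int] = {}
    for g in genes:
        counts[gene_chrom[g]] = counts.get(gene_chrom[g], 0) + 1
    return counts


def expected_count(
    n_sig: int, chromosome: str, annotation: ProbeAnnotation
) -> float:
    """Expected significant genes on a chromosome under a uniform draw:
    n_sig * (annotated genes on chromosome / total annotated genes)."""
    gene_chrom = annotation.gene_chromosome()
    m_total = len(gene_chrom)
    if m_total == 0:
        raise ValueError("annotation is empty")
    m_chr = int((gene_chrom == chromosome).sum())
    return n_sig * m_chr / m_total


def enrichment_test(obs: int, n_sig: int, m_chr: int, m_total: int) -> float:
    """Hypergeometric upper-tail P(X >= obs) of seeing ``obs`` significant
    genes on a chromosome carrying ``m_chr`` of ``m_total`` genes when
    ``n_sig`` genes are significant overall."""
    if not (0 <= obs <= min(n_sig, m_chr)):
        raise ValueError("require 0 <= obs <= min(n_sig, m_chr)")
    if not (0 <= m_chr <= m_total) or n_sig > m_total:
        raise ValueError("inconsistent gene counts")
    # P(X >= obs) = sf(obs - 1); equals 1.0 at obs = 0
    return float(stats.hypergeom.sf(obs - 1, m_total, m_chr, n_sig))


def enrichment_table(
    hits_by_tissue: Mapping[str, Iterable[SexBiasResult]],
    annotation: ProbeAnnotation,
) -> pd.DataFrame:
    """Observed/expected/p per tissue and chromosome (the Obs/Exp/p layout)."""
    gene_chrom = annotation.gene_chromosome()
    m_total = len(gene_chrom)
    chrom_sizes = gene_chrom.value_counts()
    rows = []
    for tissue, hits in hits_by_tissue.items():
        hits = list(hits)
        counts = count_by_chromosome(hits, annotation)
        n_sig = len(_hit_genes(hits))
        for chrom in gene_chrom.unique():
            obs = counts.get(chrom, 0)
            row = EnrichmentRow(
                tissue=tissue,
                chromosome=chrom,
                observed=obs,
                expected=expected_count(n_sig, chrom, annotation),
                p=enrichment_test(obs, n_sig, int(chrom_sizes[chrom]), m_total),
            )
            rows.append(
                {
                    "tissue": row.tissue, "chr": row.chromosome,
                    "obs": row.observed, "exp": row.expected, "p": row.p,
                }
            )
    return pd.DataFrame(rows, columns=["tissue", "chr", "obs", "exp", "p"])
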