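"""Cross-tissue intersection of sex-biased gene lists and gene
categorization.

Overlap is computed at the gene-symbol level within an array platform
(platforms share symbols, not probes). Shared genes are split into known
sex-linked (a curated list of documented sex-biased X/Y genes, shipped as an
editable fixture), novel sex-linked, and autosomal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from typing import Iterable, Mapping

import pandas as pd

from .core import ProbeAnnotation

CATEGORIES = ("known_sex_linked", "novel_sex_linked", "autosomal")


@dataclass(frozen=True)
class GeneCategory:
    gene: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass
class OverlapSet:
    """Genes shared by a subset of tissues on one platform.

    ``exclusive`` holds the exact Venn region (in every tissue of the subset
    and in no other tissue of the platform); ``intersection`` the plain
    intersection over the subset. ``fold_changes`` optionally carries the
    per-tissue signed FC of each shared gene (None where unavailable).
    """

    platform: str
    tissues: tuple[str, ...]
    exclusive: set[str]
    intersection: set[str]
    fold_changes: dict[str, dict[str, float | None]] = field(default_factory=dict)


def _as_sets(hit_lists) -> dict[str, set[str]]:
    if isinstance(hit_lists, Mapping):
        items = list(hit_lists.items())
    else:
        items = list(hit_lists)
    names = [t for t, _ in items]
    if len(names) != len(set(names)):
        raise ValueError(f"duplicate tissue names in {names}")
    return {t: set(genes) for t, genes in items}


def venn_regions(hit_lists) -> dict[frozenset, set[str]]:
    """Exact-region Venn membership: every gene of the union is assigned to
    the unique region given by the set of tissues it is a hit in."""
    sets = _as_sets(hit_lists)
    regions: dict[frozenset, set[str]] = {}
    union = set().union(*sets.values()) if sets else set()
    for gene in union:
        members = frozenset(t for t, s in sets.items() if gene in s)
        regions.setdefault(members, set()).add(gene)
    return regions


def intersect_hits(hit_lists, platform: str) -> list[OverlapSet]:
    """All tissue subsets of size >= 2 with their exact Venn region and
    any-overlap intersection, for one platform."""
    sets = _as_sets(hit_lists)
    if len(sets) < 2:
        raise ValueError("need at least two tissues per platform")
    regions = venn_regions(sets)
    out: list[OverlapSet] = []
    tissues = sorted(sets)
    for size in range(2, len(tissues) + 1):
        for subset in combinations(tissues, size):
            inter = set.intersection(*(sets[t] for t in subset))
            out.append(
                OverlapSet(
                    platform=platform,
                    tissues=subset,
                    exclusive=set(regions.get(frozenset(subset), set())),
                    intersection=inter,
                )
            )
    return out


def load_known_sex_linked(path=None) -> set[str]:
    """Curated list of documented sex-biased X/Y genes (one symbol per line,
    '#' comments allowed)."""
    if path is not None:
        text = open(path).read()
    else:
        text = (
            resources.files("escapex.data")
            .joinpath("known_sex_linked_genes.txt")
            .read_text()
        )
    genes = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.add(line)
    return genes


def classify_genes(
    genes: Iterable[str],
    annotation: ProbeAnnotation,
    known_list: set[str] | None = None,
) -> list[GeneCategory]:
    """Split genes into known sex-linked / novel sex-linked / autosomal.

    Sex-chromosome genes are "known" when present in the curated list,
    otherwise "novel"; everything else is autosomal. Raises on genes missing
    from the annotation.
    """
    if known_list is None:
        known_list = load_known_sex_linked()
    gene_chrom = annotation.gene_chromosome()
    out = []
    for g in dict.fromkeys(genes):
        if g not in gene_chrom.index:
            raise KeyError(f"gene {g!r} not annotated")
        if gene_chrom[g] in ("X", "Y"):
            cat = "known_sex_linked" if g in known_list else "novel_sex_linked"
        else:
            cat = "autosomal"
        out.append(GeneCategory(gene=g, category=cat))
    return out


def overlap_table(
    shared_genes: Iterable[str],
    annotation: ProbeAnnotation,
    fold_changes: Mapping[str, Mapping[str, float]],
    known_list: set[str] | None = None,
) -> pd.DataFrame:
    """Gene x tissue table of signed fold changes with category labels.

    ``fold_changes`` maps tissue -> {gene -> signed FC}; genes absent from a
    tissue's array (or not significant there) get NA.
    """
    cats = {c.gene: c.category for c in
            classify_genes(shared_genes, annotation, known_list)}
    tissues = list(fold_changes)
    rows = []
    gene_chrom = annotation.gene_chromosome()
    for g in dict.fromkeys(shared_genes):
        row = {"gene": g, "chr": gene_chrom[g], "category": cats[g]}
        for t in tissues:
            row[t] = fold_changes[t].get(g, float("nan"))
        rows.append(row)
    return pd.DataFrame(rows, columns=["gene", "chr", "category", *tissues])
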