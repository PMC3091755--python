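"""X-chromosome escapee domains: coding/non-coding pairing, co-localization
null, and repressive-mark coverage.

Female-biased long non-coding RNAs on the mouse X cluster next to protein
coding genes that escape X-inactivation. This module pairs female-biased
coding and non-coding X genes into candidate escapee domains, evaluates how
surprising the observed clustering is under a permutation null (random
X-linked probes falling within a window of a fixed anchor set), and scores
depletion of a repressive histone mark (H3K27me3) over the domains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GenomicInterval, ProbeAnnotation

#: genes treated as fixed in the co-localization permutation: Xist, Jpx and
#: the coding escapees of the four candidate domains.
DEFAULT_ANCHOR_GENES = (
    "Xist", "Jpx", "Ddx3x", "Eif2s3x", "Kdm6a", "Kdm5c", "2610029G23Rik",
)

RELATIONS = ("head_to_head", "tandem", "nested_intronic")


@dataclass(frozen=True)
class EscapeeDomain:
    """A paired female-biased coding + non-coding gene on the X chromosome."""

    coding: str
    coding_interval: GenomicInterval
    noncoding: str
    noncoding_interval: GenomicInterval
    gap: int
    relation: str

    def __post_init__(self) -> None:
        if self.coding_interval.chrom != self.noncoding_interval.chrom:
            raise ValueError("domain genes must share a chromosome")
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")

    @property
    def span(self) -> GenomicInterval:
        """Interval covering both genes (used for peak-coverage scoring)."""
        return GenomicInterval(
            self.coding_interval.chrom,
            min(self.coding_interval.start, self.noncoding_interval.start),
            max(self.coding_interval.end, self.noncoding_interval.end),
        )


@dataclass
class PermutationSpec:
    """Parameters of the co-localization permutation null.

    ``k`` probes are drawn per permutation (four, one per candidate lncRNA);
    a permutation succeeds when all drawn probes lie within ``window`` bp of
    an anchor gene body. The FDR is the success fraction over ``n_perm``
    permutations.
    """

    anchors: tuple[str, ...] = DEFAULT_ANCHOR_GENES
    k: int = 4
    window: int = 50_000
    n_perm: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class PeakSet:
    """Genomic intervals carrying a histone-mark enrichment flag.

    Intervals may overlap; the union is taken wherever coverage is computed.
    """

    intervals: pd.DataFrame  # columns chrom, start, end
    mark: str = "H3K27me3"
    sample_sex: str = "F"

    def __post_init__(self) -> None:
        for col in ("chrom", "start", "end"):
            if col not in self.intervals.columns:
                raise ValueError(f"peak table missing column {col!r}")
        if (self.intervals["start"] >= self.intervals["end"]).any():
            raise ValueError("peak intervals must satisfy start < end")

    def on(self, chrom: str) -> pd.DataFrame:
        return self.intervals[self.intervals["chrom"] == chrom]


def gene_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Distance in bp between the nearest edges of two intervals.

    Zero when the intervals overlap or nest. Half-open convention: [0, 1000)
    and [1000, 2000) are adjacent with gap 0.
    """
    if a.chrom != b.chrom:
        raise ValueError(f"intervals on different chromosomes: {a.chrom} vs {b.chrom}")
    return max(0, max(a.start, b.start) - min(a.end, b.end))


def classify_relation(a: GenomicInterval, b: GenomicInterval) -> str:
    """Relative orientation of two same-chromosome gene intervals.

    nested_intronic when one interval is contained in the other; head_to_head
    when the genes are on opposite strands with their 5' ends facing each
    other across the gap; tandem otherwise.
    """
    if a.contains(b) or b.contains(a):
        return "nested_intronic"
    upstream, downstream = (a, b) if a.start <= b.start else (b, a)
    if upstream.strand == "-" and downstream.strand == "+":
        return "head_to_head"
    return "tandem"


def pair_coding_noncoding(
    female_biased: Iterable[str],
    annotation: ProbeAnnotation,
    max_gap: int = 50_000,
) -> tuple[list[EscapeeDomain], list[str]]:
    """Pair each female-biased non-coding X gene with its nearest
    female-biased coding X gene within ``max_gap`` bp (or containing it).

    Returns (domains, unpaired non-coding genes). Each non-coding gene
    appears in at most one domain; a coding gene may anchor several.
    """
    genes = list(dict.fromkeys(female_biased))
    biotype = annotation.table.drop_duplicates("gene").set_index("gene")["biotype"]
    unknown = [g for g in genes if g not in biotype.index]
    if unknown:
        raise KeyError(f"genes without annotation: {unknown}")

    on_x = [g for g in genes if annotation.gene_interval(g).chrom == "X"]
    noncoding = [g for g in on_x if biotype[g] == "noncoding"]
    coding = [g for g in on_x if biotype[g] == "coding"]
    coding_ivs = {g: annotation.gene_interval(g) for g in coding}

    domains: list[EscapeeDomain] = []
    unpaired: list[str] = []
    for nc in noncoding:
        nc_iv = annotation.gene_interval(nc)
        candidates = [
            (gene_gap(nc_iv, iv), iv.start, g, iv) for g, iv in coding_ivs.items()
        ]
        candidates = [c for c in candidates if c[0] <= max_gap]
        if not candidates:
            unpaired.append(nc)
            continue
        gap, _, best, best_iv = min(candidates)
        domains.append(
            EscapeeDomain(
                coding=best,
                coding_interval=best_iv,
                noncoding=nc,
                noncoding_interval=nc_iv,
                gap=gap,
                relation=classify_relation(best_iv, nc_iv),
            )
        )
    return domains, unpaired


def _anchor_windows(
    spec: PermutationSpec, annotation: ProbeAnnotation
) -> list[GenomicInterval]:
    windows = []
    for gene in spec.anchors:
        iv = annotation.gene_interval(gene)  # KeyError if unresolvable
        windows.append(
            GenomicInterval(iv.chrom, max(0, iv.start - spec.window),
                            iv.end + spec.window)
        )
    return windows


def coloc_permutation_fdr(
    spec: PermutationSpec, annotation: ProbeAnnotation
) -> tuple[float, int]:
    """Permutation FDR of the observed coding/non-coding co-localization.

    The eligible universe is all X-linked probes excluding those mapping to
    anchor genes. Each permutation draws ``spec.k`` distinct probes uniformly
    without replacement; it succeeds when every drawn probe lies within
    ``spec.window`` bp of some anchor gene body. Returns
    (successes / n_perm, successes).
    """
    windows = _anchor_windows(spec, annotation)
    x_probes = annotation.probes_on("X")
    eligible = x_probes[~x_probes["gene"].isin(spec.anchors)]
    n = len(eligible)
    if spec.k > n:
        raise ValueError(f"k={spec.k} exceeds eligible probe universe ({n})")

    starts = eligible["start"].to_numpy()
    ends = eligible["end"].to_numpy()
    in_window = np.zeros(n, dtype=bool)
    for w in windows:
        if w.chrom != "X":
            continue
        in_window |= (starts < w.end) & (ends > w.start)

    rng = np.random.default_rng(spec.seed)
    successes = 0
    for _ in range(spec.n_perm):
        draw = rng.choice(n, size=spec.k, replace=False)
        if in_window[draw].all():
            successes += 1
    return successes / spec.n_perm, successes


def analytic_coloc_probability(n_in: int, n_total: int, k: int) -> float:
    """Exact probability that all k probes drawn without replacement from
    n_total fall among the n_in probes inside the anchor windows:
    C(n_in, k) / C(n_total, k)."""
    if not (0 <= n_in <= n_total):
        raise ValueError("require 0 <= n_in <= n_total")
    if not (1 <= k <= n_total):
        raise ValueError("require 1 <= k <= n_total")
    if n_in < k:
        return 0.0
    return math.comb(n_in, k) / math.comb(n_total, k)


class CoverageResult(NamedTuple):
    inside: float
    flank_mean: float
    depletion_ratio: float


def _union_coverage(interval: GenomicInterval, peaks: pd.DataFrame) -> float:
    """Fraction of ``interval`` covered by the union of peak intervals."""
    tree = IntervalTree()
    for s, e in zip(peaks["start"], peaks["end"]):
        s = max(int(s), interval.start)
        e = min(int(e), interval.end)
        if s < e:
            tree.addi(s, e)
    tree.merge_overlaps()
    covered = sum(iv.end - iv.begin for iv in tree)
    return covered / interval.length


def domain_peak_coverage(
    domain: GenomicInterval, peaks: PeakSet, flank: int = 100_000
) -> CoverageResult:
    """Peak coverage inside a domain versus its two flanking intervals.

    ``inside`` is |union(peaks) ∩ domain| / |domain|; ``flank_mean`` averages
    coverage of the flanks [start-flank, start) and [end, end+flank) (clipped
    at zero; empty flanks are dropped from the average). depletion_ratio is
    inside / flank_mean, reported as inf when flank_mean is zero.
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")
    chrom_peaks = peaks.on(domain.chrom)
    inside = _union_coverage(domain, chrom_peaks)

    flank_covs = []
    if flank > 0:
        left_start = max(0, domain.start - flank)
        if left_start < domain.start:
            flank_covs.append(
                _union_coverage(
                    GenomicInterval(domain.chrom, left_start, domain.start),
                    chrom_peaks,
                )
            )
        flank_covs.append(
            _union_coverage(
                GenomicInterval(domain.chrom, domain.end, domain.end + flank),
                chrom_peaks,
            )
        )
    flank_mean = float(np.mean(flank_covs)) if flank_covs else 0.0
    ratio = inside / flank_mean if flank_mean > 0 else math.inf
    return CoverageResult(inside, flank_mean, ratio)


def domains_to_frame(domains: Iterable[EscapeeDomain]) -> pd.DataFrame:
    rows = []
    for d in domains:
        rows.append(
            {
                "chrom": d.span.chrom,
                "start": d.span.start,
                "end": d.span.end,
                "coding": d.coding,
                "noncoding": d.noncoding,
                "gap": d.gap,
                "relation": d.relation,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "coding", "noncoding", "gap", "relation"],
    )
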