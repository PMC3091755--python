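"""Domain tests: gap geometry, pairing, permutation null, peak coverage."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from escapex.core import GenomicInterval
from escapex.domains import (
    PeakSet,
    PermutationSpec,
    analytic_coloc_probability,
    coloc_permutation_fdr,
    domain_peak_coverage,
    gene_gap,
    pair_coding_noncoding,
)
from escapex.synthetic import generate_peaks

from conftest import make_annotation

import pandas as pd


def sweepline_union_coverage(interval, starts, ends):
    """Independent union-length oracle: sweep over sorted clipped endpoints."""
    events = []
    for s, e in zip(starts, ends):
        s, e = max(s, interval.start), min(e, interval.end)
        if s < e:
            events.append((s, +1))
            events.append((e, -1))
    events.sort()
    covered, depth, last = 0, 0, None
    for pos, delta in events:
        if depth > 0:
            covered += pos - last
        depth += delta
        last = pos
    return covered / (interval.end - interval.start)


class TestGeneGap:
    def test_overlapping_intervals_gap_zero(self):
        a = GenomicInterval("X", 100, 200)
        b = GenomicInterval("X", 150, 300)
        assert gene_gap(a, b) == 0

    def test_33kb_separation(self):
        a = GenomicInterval("X", 0, 1000)
        b = GenomicInterval("X", 34_000, 40_000)
        assert gene_gap(a, b) == 33_000

    def test_different_chromosomes_error(self):
        with pytest.raises(ValueError, match="chromosome"):
            gene_gap(GenomicInterval("X", 0, 10), GenomicInterval("Y", 0, 10))

    @given(
        st.integers(0, 10_000), st.integers(1, 5_000),
        st.integers(0, 10_000), st.integers(1, 5_000),
    )
    def test_symmetric(self, s1, l1, s2, l2):
        a = GenomicInterval("X", s1, s1 + l1)
        b = GenomicInterval("X", s2, s2 + l2)
        assert gene_gap(a, b) == gene_gap(b, a)


class TestPairing:
    def test_planted_domains_recovered_with_relations(self, annotation):
        female = [d.coding for d in annotation.domains] + [
            d.noncoding for d in annotation.domains
        ]
        domains, unpaired = pair_coding_noncoding(female, annotation)
        assert unpaired == []
        got = {(d.coding, d.noncoding): (d.gap, d.relation) for d in domains}
        assert got[("Ddx3x", "2010308F09Rik")] == (33_000, "head_to_head")
        assert got[("Eif2s3x", "D330035K16Rik")] == (0, "nested_intronic")
        assert got[("Kdm5c", "D930009K15Rik")] == (2_600, "tandem")
        assert got[("2610029G23Rik", "5530601H04Rik")] == (9_700, "head_to_head")

    def test_distant_noncoding_left_unpaired(self):
        ann = make_annotation(
            [
                ("X", 0, 10_000, "pc", "+", "CodingGene", "coding"),
                ("X", 200_000, 203_000, "pn", "-", "LncGene", "noncoding"),
            ]
        )
        domains, unpaired = pair_coding_noncoding(
            ["CodingGene", "LncGene"], ann, max_gap=50_000
        )
        assert domains == []
        assert unpaired == ["LncGene"]

    def test_nearest_coding_gene_chosen(self):
        ann = make_annotation(
            [
                ("X", 0, 5_000, "p1", "+", "FarGene", "coding"),
                ("X", 40_000, 45_000, "p2", "+", "NearGene", "coding"),
                ("X", 50_000, 52_000, "p3", "-", "Lnc", "noncoding"),
            ]
        )
        domains, _ = pair_coding_noncoding(["FarGene", "NearGene", "Lnc"], ann)
        (d,) = domains
        assert d.coding == "NearGene"
        assert d.gap == 5_000

    def test_unknown_candidate_errors(self, annotation):
        with pytest.raises(KeyError, match="NoSuchGene"):
            pair_coding_noncoding(["NoSuchGene"], annotation)


def window_annotation(n_in, n_total, anchor_end=1_000, window=50_000):
    """Anchor at [0, anchor_end); n_in probes inside the window, the rest
    far downstream on a long X."""
    rows = [("X", 0, anchor_end, "p_anchor", "+", "Anchor", "coding")]
    for i in range(n_in):
        s = anchor_end + 1_000 + i * 100
        rows.append(("X", s, s + 50, f"p_in{i}", "+", f"in{i}", "coding"))
    for i in range(n_total - n_in):
        s = 10_000_000 + i * 1_000
        rows.append(("X", s, s + 50, f"p_out{i}", "+", f"out{i}", "coding"))
    return make_annotation(rows, {"X": 166_000_000})


class TestColocPermutation:
    def test_all_probes_in_window_certain_success(self):
        ann = window_annotation(n_in=6, n_total=6)
        spec = PermutationSpec(anchors=("Anchor",), k=4, n_perm=500, seed=1)
        fdr, successes = coloc_permutation_fdr(spec, ann)
        assert fdr == 1.0 and successes == 500

    def test_converges_to_combinatorial_probability(self):
        # 4 of 10 eligible probes inside; all-4 success prob = 1/C(10,4)
        ann = window_annotation(n_in=4, n_total=10)
        spec = PermutationSpec(anchors=("Anchor",), k=4, n_perm=10_000, seed=2)
        fdr, _ = coloc_permutation_fdr(spec, ann)
        p = analytic_coloc_probability(4, 10, 4)
        assert p == pytest.approx(1 / 210)
        se = math.sqrt(p * (1 - p) / 10_000)
        assert abs(fdr - p) <= 3 * se

    def test_estimator_consistent_across_grid(self):
        grid = [(4, 12), (6, 15), (8, 20), (5, 10), (10, 30)]
        for n_in, n_total in grid:
            ann = window_annotation(n_in=n_in, n_total=n_total)
            spec = PermutationSpec(anchors=("Anchor",), k=4, n_perm=3_000,
                                   seed=n_in * 100 + n_total)
            fdr, _ = coloc_permutation_fdr(spec, ann)
            p = analytic_coloc_probability(n_in, n_total, 4)
            se = math.sqrt(p * (1 - p) / 3_000)
            assert abs(fdr - p) <= 3 * se + 1e-12

    def test_deterministic_under_seed(self):
        ann = window_annotation(n_in=4, n_total=10)
        spec = PermutationSpec(anchors=("Anchor",), k=4, n_perm=2_000, seed=9)
        assert coloc_permutation_fdr(spec, ann) == coloc_permutation_fdr(spec, ann)

    def test_k_exceeding_universe_errors(self):
        ann = window_annotation(n_in=1, n_total=2)
        spec = PermutationSpec(anchors=("Anchor",), k=4, n_perm=10, seed=0)
        with pytest.raises(ValueError, match="eligible"):
            coloc_permutation_fdr(spec, ann)

    def test_anchor_probes_excluded_from_universe(self):
        # only anchor probes inside the window -> success impossible
        ann = window_annotation(n_in=0, n_total=8)
        spec = PermutationSpec(anchors=("Anchor",), k=4, n_perm=1_000, seed=3)
        fdr, successes = coloc_permutation_fdr(spec, ann)
        assert successes == 0


class TestAnalyticProbability:
    def test_certain_event(self):
        assert analytic_coloc_probability(10, 10, 4) == 1.0

    def test_four_of_ten(self):
        assert analytic_coloc_probability(4, 10, 4) == pytest.approx(1 / 210)

    def test_impossible_event(self):
        assert analytic_coloc_probability(3, 10, 4) == 0.0

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            analytic_coloc_probability(11, 10, 4)
        with pytest.raises(ValueError):
            analytic_coloc_probability(5, 10, 0)


def peakset(rows):
    return PeakSet(intervals=pd.DataFrame(rows, columns=["chrom", "start", "end"]))


class TestPeakCoverage:
    def test_no_peaks_zero_inside(self):
        cov = domain_peak_coverage(
            GenomicInterval("X", 0, 1_000), peakset([]), flank=100
        )
        assert cov.inside == 0.0

    def test_half_covered_domain(self):
        cov = domain_peak_coverage(
            GenomicInterval("X", 0, 1_000),
            peakset([("X", 0, 500)]), flank=0,
        )
        assert cov.inside == pytest.approx(0.5)

    def test_infinite_marker_when_flanks_empty(self):
        cov = domain_peak_coverage(
            GenomicInterval("X", 0, 1_000),
            peakset([("X", 100, 200)]), flank=500,
        )
        assert cov.flank_mean == 0.0
        assert math.isinf(cov.depletion_ratio)

    def test_union_matches_sweepline_oracle_on_random_peaks(self):
        rng = np.random.default_rng(12)
        domain = GenomicInterval("X", 10_000, 60_000)
        for _ in range(300):
            n = rng.integers(1, 40)
            starts = rng.integers(0, 80_000, size=n)
            lengths = rng.integers(1, 5_000, size=n)
            ends = starts + lengths
            ps = peakset(
                [("X", int(s), int(e)) for s, e in zip(starts, ends)]
            )
            cov = domain_peak_coverage(domain, ps, flank=0)
            oracle = sweepline_union_coverage(domain, starts, ends)
            assert cov.inside == pytest.approx(oracle, abs=1e-12)

    def test_synthetic_domains_depleted_control_covered(self, annotation):
        peaks = generate_peaks(annotation, seed=21)
        for d in annotation.domains:
            cov = domain_peak_coverage(d.span, peaks)
            assert cov.depletion_ratio < 0.2
        control = domain_peak_coverage(
            annotation.gene_interval("Rps4x"), peaks
        )
        assert control.inside > 0.5
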