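"""Generator tests: planted structure, ground-truth bookkeeping, determinism."""

import math

import numpy as np
import pandas as pd
import pytest

from escapex.domains import domain_peak_coverage
from escapex.qpcr import compare_sexes
from escapex.synthetic import (
    GenomeSpec,
    SimulationConfig,
    generate_annotation,
    generate_expression,
    generate_peaks,
    generate_qpcr,
)


class TestGenerateAnnotation:
    def test_template_gaps_realized_exactly(self, annotation):
        by_name = {(d.coding, d.noncoding): d for d in annotation.domains}
        assert by_name[("Ddx3x", "2010308F09Rik")].gap == 33_000
        assert by_name[("2610029G23Rik", "5530601H04Rik")].gap == 9_700
        assert by_name[("Kdm5c", "D930009K15Rik")].gap == 2_600
        nested = by_name[("Eif2s3x", "D330035K16Rik")]
        assert nested.gap == 0
        assert nested.coding_interval.contains(nested.noncoding_interval)

    def test_no_filler_probes_at_template_count(self, genome):
        n = genome.n_template_probes()
        ann = generate_annotation(genome, n, seed=0)
        assert len(ann) == n
        assert not any(g.startswith("G0") for g in ann.table["gene"])

    def test_deterministic_under_seed(self, genome):
        a = generate_annotation(genome, 300, seed=42)
        b = generate_annotation(genome, 300, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_every_probe_maps_to_one_gene_interval(self, annotation):
        assert annotation.table["probe_id"].is_unique
        assert (annotation.table["start"] < annotation.table["end"]).all()
        # two Xist probes map to the same single gene interval
        xist = annotation.table[annotation.table["gene"] == "Xist"]
        assert len(xist) == 2
        assert xist["start"].nunique() == 1

    def test_overflowing_interval_rejected(self):
        genome = GenomeSpec(
            chromosomes={"chr1": 10_000, "chr2": 10_000, "X": 50_000, "Y": 10_000}
        )
        with pytest.raises(ValueError, match="exceeds"):
            generate_annotation(genome, genome.n_template_probes(), seed=0)

    def test_too_few_probes_rejected(self, genome):
        with pytest.raises(ValueError, match="template"):
            generate_annotation(genome, 3, seed=0)

    def test_genome_requires_sex_chromosomes_and_autosomes(self):
        with pytest.raises(ValueError, match="X chromosome"):
            GenomeSpec(chromosomes={"chr1": 1_000, "chr2": 1_000, "Y": 1_000})
        with pytest.raises(ValueError, match="autosomes"):
            GenomeSpec(chromosomes={"chr1": 1_000, "X": 200_000_000, "Y": 1_000})


class TestGenerateExpression:
    def test_null_dataset_has_no_effects(self, annotation):
        cfg = SimulationConfig(
            n_tissues=1, samples_per_sex_per_tissue=10, n_probes=500,
            frac_sex_biased=0.0, mislabel_frac=0.0, seed=1,
        )
        matrix, truth = generate_expression(cfg, annotation, seed=1)
        assert (truth.effects == 0.0).all()
        assert truth.mislabeled == []
        assert matrix.values.shape == (500, 20)

    def test_planted_effect_recovered_within_3_se(self, genome):
        # single planted 1 log2-unit effect, 60 vs 60, noise_sd 0.5:
        # SE of the mean difference is noise_sd * sqrt(2/60)
        ann = generate_annotation(genome, 500, seed=2)
        cfg = SimulationConfig(
            n_tissues=1, samples_per_sex_per_tissue=60, n_probes=500,
            frac_sex_biased=0.05, noise_sd=0.5, seed=2,
            escapee_effect_range_log2=(1.0, 1.0),
        )
        matrix, truth = generate_expression(cfg, ann, seed=2)
        probe = "p_Ddx3x"
        assert truth.effects[probe] == 1.0
        f = matrix.values.loc[probe, matrix.sample_ids(sex="F")]
        m = matrix.values.loc[probe, matrix.sample_ids(sex="M")]
        se = 0.5 * math.sqrt(2 / 60)
        assert abs((f.mean() - m.mean()) - 1.0) <= 3 * se

    def test_xist_ratio_near_ten_thousand_fold(self, annotation):
        cfg = SimulationConfig(
            n_tissues=1, samples_per_sex_per_tissue=43, n_probes=500,
            frac_sex_biased=0.05, noise_sd=0.5, seed=3,
        )
        matrix, truth = generate_expression(cfg, annotation, seed=3)
        for probe in ("p_Xist_1", "p_Xist_2"):
            f = matrix.values.loc[probe, matrix.sample_ids(sex="F")].mean()
            m = matrix.values.loc[probe, matrix.sample_ids(sex="M")].mean()
            ratio = 2.0 ** (f - m)
            assert 0.5e4 <= ratio <= 2e4

    def test_ground_truth_bookkeeping(self, annotation):
        cfg = SimulationConfig(
            n_tissues=2, samples_per_sex_per_tissue=10, n_probes=500,
            frac_sex_biased=0.08, mislabel_frac=0.1, seed=4,
        )
        matrix, truth = generate_expression(cfg, annotation, seed=4)
        assert len(truth.planted_probes) == round(0.08 * 500)
        assert set(truth.mislabeled) <= set(matrix.values.columns)
        assert len(truth.mislabeled) == round(0.1 * matrix.n_samples)
        # recorded sex differs from true sex exactly on the mislabeled set
        flipped = [
            s for s in matrix.values.columns
            if matrix.samples.loc[s, "sex"] != truth.true_sex[s]
        ]
        assert sorted(flipped) == sorted(truth.mislabeled)

    def test_deterministic_under_seed(self, genome, simple_config):
        ann = generate_annotation(genome, simple_config.n_probes, seed=9)
        a, _ = generate_expression(simple_config, ann, seed=9)
        b, _ = generate_expression(simple_config, ann, seed=9)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_impossible_balancing_rejected(self, genome):
        ann = generate_annotation(genome, 100, seed=0)
        cfg = SimulationConfig(
            n_tissues=1, samples_per_sex_per_tissue=1, n_probes=100,
            mislabel_frac=1.0, seed=0,
        )
        with pytest.raises(ValueError, match="mislabel"):
            generate_expression(cfg, ann, seed=0)


class TestGeneratePeaks:
    def test_domains_depleted_and_control_covered(self, annotation):
        peaks = generate_peaks(annotation, seed=5)
        for d in annotation.domains:
            cov = domain_peak_coverage(d.span, peaks)
            assert cov.inside < 0.05
        control = domain_peak_coverage(
            annotation.gene_interval("Rps4x"), peaks
        )
        assert control.inside > 0.5

    def test_empty_domain_list_covers_whole_x(self, annotation):
        bare = generate_annotation(
            GenomeSpec(domain_templates=[]), 200, seed=6
        )
        peaks = generate_peaks(bare, seed=6)
        from escapex.core import GenomicInterval

        whole_x = GenomicInterval("X", 0, bare.chrom_sizes["X"])
        cov = domain_peak_coverage(whole_x, peaks, flank=0)
        assert cov.inside > 0.5

    def test_deterministic_under_seed(self, annotation):
        a = generate_peaks(annotation, seed=7)
        b = generate_peaks(annotation, seed=7)
        pd.testing.assert_frame_equal(a.intervals, b.intervals)


class TestGenerateQpcr:
    def test_dilution_series_slope_near_ideal(self, simple_config):
        data = generate_qpcr(simple_config, seed=8)
        from escapex.qpcr import fit_standard_curve

        for gene, grp in data.dilution_series.groupby("gene"):
            curve = fit_standard_curve(grp["dilution"], grp["ct"])
            assert curve.slope == pytest.approx(-3.3219, abs=0.25)

    def test_noiseless_null_ratio_exactly_one(self):
        cfg = SimulationConfig(
            n_tissues=1, samples_per_sex_per_tissue=5, n_probes=100,
            qpcr_ct_sd=0.0, qpcr_targets={"Rps4x": 1.0}, seed=0,
        )
        data = generate_qpcr(cfg, seed=0)
        from escapex.qpcr import analyze_qpcr

        table = analyze_qpcr(data)
        assert table.loc[table["gene"] == "Rps4x", "ratio"].iloc[0] == pytest.approx(1.0)

    def test_planted_ratio_recovered(self):
        cfg = SimulationConfig(
            n_tissues=1, samples_per_sex_per_tissue=5, n_probes=100,
            qpcr_n_per_sex=16, qpcr_targets={"Kdm5c": 1.5}, seed=1,
        )
        ratios = []
        from escapex.qpcr import analyze_qpcr

        for seed in range(20):
            table = analyze_qpcr(generate_qpcr(cfg, seed=seed))
            ratios.append(table["ratio"].iloc[0])
        mean = np.mean(ratios)
        se = np.std(ratios, ddof=1) / math.sqrt(len(ratios))
        assert abs(mean - 1.5) <= 3 * se + 0.02

    def test_reference_genes_null_type_I(self):
        # Welch p > 0.05 for the no-effect reference genes in >= 90% of runs
        cfg = SimulationConfig(
            n_tissues=1, samples_per_sex_per_tissue=5, n_probes=100,
            qpcr_targets={"Actb_as_target": 1.0}, seed=2,
        )
        from escapex.qpcr import analyze_qpcr

        null_ps = []
        for seed in range(50):
            table = analyze_qpcr(generate_qpcr(cfg, seed=seed))
            null_ps.append(table["p"].iloc[0])
        assert np.mean(np.array(null_ps) > 0.05) >= 0.9

    def test_nonpositive_dilutions_rejected(self, simple_config):
        cfg = SimulationConfig(
            n_tissues=1, samples_per_sex_per_tissue=5, n_probes=100,
            qpcr_dilutions=(1.0, 0.0, 0.1), seed=0,
        )
        with pytest.raises(ValueError, match="dilution"):
            generate_qpcr(cfg, seed=0)


class TestConfigValidation:
    def test_proportions_validated(self):
        with pytest.raises(ValueError, match="frac_sex_biased"):
            SimulationConfig(frac_sex_biased=1.5)
        with pytest.raises(ValueError, match="mislabel_frac"):
            SimulationConfig(mislabel_frac=-0.1)

    def test_effect_bounds_ordered(self):
        with pytest.raises(ValueError, match="ordered"):
            SimulationConfig(effect_range_log2=(1.0, 0.5))
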