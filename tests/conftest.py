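import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from escapex.core import ANNOTATION_COLUMNS, ExpressionMatrix, ProbeAnnotation
from escapex.synthetic import GenomeSpec, SimulationConfig, generate_annotation

settings.register_profile("default", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("default")


@pytest.fixture(scope="session")
def genome():
    return GenomeSpec()


@pytest.fixture(scope="session")
def annotation(genome):
    """Default genome realized with 500 probes."""
    return generate_annotation(genome, 500, seed=11)


@pytest.fixture
def make_matrix():
    """Build a small ExpressionMatrix from a dict of probe -> values plus
    per-sample sexes (one tissue, one platform)."""

    def build(values: dict, sexes: list, tissue="tissue1", sample_ids=None):
        n = len(sexes)
        if sample_ids is None:
            sample_ids = [f"s{i + 1:02d}" for i in range(n)]
        vals = pd.DataFrame(values, index=sample_ids).T
        samples = pd.DataFrame(
            {"sex": sexes, "tissue": tissue, "platform": "platform_A"},
            index=pd.Index(sample_ids, name="sample_id"),
        )
        return ExpressionMatrix(values=vals, samples=samples)

    return build


def make_annotation(rows, chrom_sizes=None):
    """Annotation from (chrom, start, end, probe_id, strand, gene, biotype)."""
    table = pd.DataFrame(
        [
            {
                "chrom": r[0], "start": r[1], "end": r[2], "probe_id": r[3],
                "score": 0, "strand": r[4], "gene": r[5], "biotype": r[6],
            }
            for r in rows
        ],
        columns=ANNOTATION_COLUMNS,
    )
    return ProbeAnnotation(table=table, chrom_sizes=chrom_sizes or {})


@pytest.fixture
def simple_config():
    return SimulationConfig(
        n_tissues=1, samples_per_sex_per_tissue=20, n_probes=200,
        frac_sex_biased=0.1, noise_sd=0.3, seed=5,
    )
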