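"""Shared containers: genomic intervals, probe annotation, expression matrices.

Coordinates are 0-based half-open throughout, matching native BED. Expression
values are log2 intensities as deposited by standardized array pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: column order of the on-disk annotation table (BED6 plus gene symbol, biotype)
ANNOTATION_COLUMNS = [
    "chrom", "start", "end", "probe_id", "score", "strand", "gene", "biotype",
]

SEXES = ("F", "M")


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware interval on a named chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class ProbeAnnotation:
    """Probe-to-gene mapping with genomic intervals.

    ``table`` has one row per probe with columns :data:`ANNOTATION_COLUMNS`.
    A gene may carry several probes (e.g. the two Xist probes used for sex QC)
    but each probe maps to exactly one gene interval. ``chrom_sizes`` carries
    the chromosome lengths of the genome the intervals live on; ``domains``
    optionally records escapee domains realized by the simulator.
    """

    table: pd.DataFrame
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    domains: list = field(default_factory=list)
    #: optional gene -> role tags (e.g. "xist", "y_linked") set by the simulator
    gene_roles: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"annotation table missing columns {missing}")
        if self.table["probe_id"].duplicated().any():
            dupes = self.table.loc[self.table["probe_id"].duplicated(), "probe_id"]
            raise ValueError(f"duplicate probe ids: {sorted(set(dupes))}")
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def probe_ids(self) -> pd.Index:
        return pd.Index(self.table["probe_id"])

    def gene_chromosome(self) -> pd.Series:
        """Map gene symbol -> chromosome (first probe wins; genes are single-locus)."""
        return self.table.drop_duplicates("gene").set_index("gene")["chrom"]

    def gene_interval(self, gene: str) -> GenomicInterval:
        rows = self.table[self.table["gene"] == gene]
        if rows.empty:
            raise KeyError(f"gene {gene!r} not in annotation")
        chroms = rows["chrom"].unique()
        if len(chroms) > 1:
            raise ValueError(f"gene {gene!r} maps to multiple chromosomes")
        strand = rows["strand"].iloc[0]
        return GenomicInterval(chroms[0], int(rows["start"].min()),
                               int(rows["end"].max()), strand)

    def probes_for_gene(self, gene: str) -> list[str]:
        return list(self.table.loc[self.table["gene"] == gene, "probe_id"])

    def probes_on(self, chrom: str) -> pd.DataFrame:
        return self.table[self.table["chrom"] == chrom]

    def genes_on(self, chrom: str) -> list[str]:
        return list(dict.fromkeys(self.probes_on(chrom)["gene"]))


@dataclass
class ExpressionMatrix:
    """Log2 expression values (probes x samples) plus per-sample metadata.

    ``samples`` is indexed by sample id with columns ``sex`` (recorded sex,
    "F"/"M"), ``tissue`` and ``platform``. Column order of ``values`` and row
    order of ``samples`` agree.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate probe ids in expression values")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in expression values")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample metadata does not match value columns")
        bad = set(self.samples["sex"]) - set(SEXES)
        if bad:
            raise ValueError(f"recorded sex must be one of {SEXES}, got {bad}")

    @property
    def n_probes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def sample_ids(self, sex: str | None = None, tissue: str | None = None) -> list[str]:
        meta = self.samples
        if sex is not None:
            meta = meta[meta["sex"] == sex]
        if tissue is not None:
            meta = meta[meta["tissue"] == tissue]
        return list(meta.index)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(self.values[ids], self.samples.loc[ids])

    def tissue(self, name: str) -> "ExpressionMatrix":
        ids = self.sample_ids(tissue=name)
        if not ids:
            raise KeyError(f"no samples for tissue {name!r}")
        return self.subset_samples(ids)

    def tissues(self) -> list[str]:
        return list(dict.fromkeys(self.samples["tissue"]))

    def sex_counts(self) -> dict[str, int]:
        counts = self.samples["sex"].value_counts()
        return {s: int(counts.get(s, 0)) for s in SEXES}


def check_proportion(name: str, value: float) -> float:
    if not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be in [0, 1], got {value}")
    return float(value)


def geometric_mean(values) -> float:
    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("geometric mean requires positive values")
    return float(np.exp(np.mean(np.log(arr))))
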