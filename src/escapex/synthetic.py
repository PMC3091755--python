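"""Seeded synthetic data with the statistical structure of sex-balanced mouse
tissue array studies.

The generators plant known ground truth so every downstream stage of the
pipeline can be verified: a mostly-null expression matrix with a small
fraction of sex-biased probes (1.1- to 2-fold), a near-binary Xist signal
(~10^4-fold female/male) usable for sample-sex QC, male-specific Y-linked
probes, optional sex-mislabeled arrays, an X chromosome carrying paired
coding/non-coding escapee genes at realistic gap distances, H3K27me3-like
peak tracks depleted over those domains, and qPCR Ct tables with dilution
series for standard-curve quantification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ANNOTATION_COLUMNS,
    ExpressionMatrix,
    GenomicInterval,
    ProbeAnnotation,
    check_proportion,
)
from .domains import EscapeeDomain, classify_relation, gene_gap

LOG2_10FOLD_SLOPE = -1.0 / math.log10(2.0)  # ideal qPCR slope, about -3.3219


@dataclass(frozen=True)
class DomainTemplate:
    """Template for one paired coding + non-coding escapee domain on the X."""

    coding: str
    coding_len: int
    noncoding: str
    noncoding_len: int
    gap: int
    orientation: str  # head_to_head | tandem | nested_intronic
    start: int  # left edge of the domain block on the X

    def __post_init__(self) -> None:
        if self.gap < 0:
            raise ValueError("gap must be non-negative")
        if self.orientation not in ("head_to_head", "tandem", "nested_intronic"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.orientation == "nested_intronic":
            if self.noncoding_len + self.coding_len // 3 >= self.coding_len:
                raise ValueError("nested non-coding gene does not fit in host intron")


@dataclass(frozen=True)
class GeneTemplate:
    """A single (unpaired) gene placed at a fixed locus."""

    name: str
    chrom: str
    start: int
    length: int
    strand: str
    biotype: str
    role: str


def _default_domain_templates() -> list[DomainTemplate]:
    # Gap distances mirror the observed mouse escapee domains: a lncRNA
    # 33 kb upstream of Ddx3x (head-to-head), one inside an Eif2s3x intron,
    # one 2.6 kb downstream of Kdm5c, and a head-to-head pair 9.7 kb apart.
    return [
        DomainTemplate("Ddx3x", 15_000, "2010308F09Rik", 3_000, 33_000,
                       "head_to_head", 25_000_000),
        DomainTemplate("Eif2s3x", 21_000, "D330035K16Rik", 2_000, 0,
                       "nested_intronic", 50_000_000),
        DomainTemplate("Kdm5c", 8_000, "D930009K15Rik", 2_500, 2_600,
                       "tandem", 75_000_000),
        DomainTemplate("2610029G23Rik", 6_000, "5530601H04Rik", 3_000, 9_700,
                       "head_to_head", 98_400_000),
    ]


def _default_single_genes() -> list[GeneTemplate]:
    return [
        GeneTemplate("Xist", "X", 100_000_000, 10_000, "-", "noncoding", "xist"),
        GeneTemplate("Jpx", "X", 100_050_000, 9_000, "+", "noncoding", "jpx"),
        GeneTemplate("Kdm6a", "X", 18_000_000, 10_000, "+", "coding",
                     "coding_escapee"),
        GeneTemplate("Rps4x", "X", 135_000_000, 5_000, "+", "coding",
                     "inactive_control"),
        GeneTemplate("Ddx3y", "Y", 3_000_000, 8_000, "+", "coding", "y_linked"),
        GeneTemplate("Eif2s3y", "Y", 6_000_000, 8_000, "+", "coding", "y_linked"),
        GeneTemplate("Kdm5d", "Y", 9_000_000, 8_000, "+", "coding", "y_linked"),
        GeneTemplate("Uty", "Y", 12_000_000, 8_000, "+", "coding", "y_linked"),
        GeneTemplate("Actb", "chr5", 30_000_000, 4_000, "+", "coding",
                     "housekeeping"),
        GeneTemplate("Gapdh", "chr1", 40_000_000, 4_000, "+", "coding",
                     "housekeeping"),
    ]


@dataclass
class GenomeSpec:
    """Synthetic genome layout: chromosome sizes plus fixed gene loci.

    One X and one Y chromosome are mandatory; at least two autosomes are
    required so that chromosome-enrichment statistics have a background.
    """

    chromosomes: dict[str, int] = field(
        default_factory=lambda: {
            "chr1": 195_000_000,
            "chr5": 152_000_000,
            "X": 166_000_000,
            "Y": 91_000_000,
        }
    )
    domain_templates: list[DomainTemplate] = field(
        default_factory=_default_domain_templates
    )
    single_genes: list[GeneTemplate] = field(default_factory=_default_single_genes)
    n_xist_probes: int = 2
    #: relative per-bp gene density used when placing filler probes; the sex
    #: chromosomes are gene-poor on expression arrays (a few percent of genes
    #: on X, well under 1% on Y), so they get reduced weight by default
    gene_density: dict[str, float] = field(
        default_factory=lambda: {"X": 0.09, "Y": 0.008}
    )

    def __post_init__(self) -> None:
        for required in ("X", "Y"):
            if required not in self.chromosomes:
                raise ValueError(f"genome must contain an {required} chromosome")
        autosomes = [c for c in self.chromosomes if c not in ("X", "Y")]
        if len(autosomes) < 2:
            raise ValueError("genome must contain at least two autosomes")
        if any(length <= 0 for length in self.chromosomes.values()):
            raise ValueError("chromosome lengths must be positive")
        if self.n_xist_probes < 1:
            raise ValueError("need at least one Xist probe")

    def n_template_probes(self) -> int:
        n = 2 * len(self.domain_templates)
        for g in self.single_genes:
            n += self.n_xist_probes if g.role == "xist" else 1
        return n


@dataclass
class SimulationConfig:
    """Study conditions for the expression / qPCR simulators.

    Defaults mirror the array study being emulated: 43 arrays per sex per
    tissue, sex-bias effects between 1.1- and 2-fold on the linear scale,
    a ~10^4-fold Xist female/male ratio (log2 ~13.3), and balanced tissues
    on up to two array platforms.
    """

    n_tissues: int = 2
    samples_per_sex_per_tissue: int = 43
    n_probes: int = 1_000
    frac_sex_biased: float = 0.03
    effect_range_log2: tuple[float, float] = (math.log2(1.1), math.log2(2.0))
    escapee_effect_range_log2: tuple[float, float] = (math.log2(1.5), math.log2(2.0))
    xist_log2_effect: float = 13.3
    y_log2_effect: float = 5.0
    noise_sd: float = 0.5
    mislabel_frac: float = 0.0
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    floor_log2: float = 2.0
    seed: int = 0
    tissues: tuple[str, ...] | None = None

    # qPCR block: planted female/male ratios, reference genes, group sizes
    qpcr_targets: dict[str, float] = field(
        default_factory=lambda: {
            "2010308F09Rik": 1.6, "Ddx3x": 1.3,
            "D330035K16Rik": 1.8, "Eif2s3x": 1.6,
            "D930009K15Rik": 1.7, "Kdm5c": 1.5,
            "5530601H04Rik": 1.6, "2610029G23Rik": 1.4,
            "Xist": 1.0e4, "Rps4x": 1.0,
        }
    )
    qpcr_reference_genes: tuple[str, str] = ("Actb", "Gapdh")
    qpcr_n_per_sex: int = 16
    qpcr_ct_sd: float = 0.15
    qpcr_dilutions: tuple[float, ...] = (1.0, 0.1, 0.01, 1e-3, 1e-4)
    qpcr_base_input: float = 0.01
    qpcr_intercept: float = 20.0

    def __post_init__(self) -> None:
        check_proportion("frac_sex_biased", self.frac_sex_biased)
        check_proportion("mislabel_frac", self.mislabel_frac)
        lo, hi = self.effect_range_log2
        if lo > hi:
            raise ValueError("effect_range_log2 bounds must be ordered")
        lo, hi = self.escapee_effect_range_log2
        if lo > hi:
            raise ValueError("escapee_effect_range_log2 bounds must be ordered")
        if self.n_tissues < 1 or self.samples_per_sex_per_tissue < 1:
            raise ValueError("need at least one tissue and one sample per sex")
        if self.n_probes < 1:
            raise ValueError("n_probes must be positive")
        if self.noise_sd < 0 or self.qpcr_ct_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.tissues is not None and len(self.tissues) != self.n_tissues:
            raise ValueError("tissues list must have n_tissues entries")

    def tissue_names(self) -> list[str]:
        if self.tissues is not None:
            return list(self.tissues)
        return [f"tissue{i + 1}" for i in range(self.n_tissues)]

    def platform_of(self, tissue: str) -> str:
        names = self.tissue_names()
        if self.n_tissues < 4:
            return "platform_A"
        half = (self.n_tissues + 1) // 2
        return "platform_A" if names.index(tissue) < half else "platform_B"


@dataclass
class GroundTruth:
    """Planted truth for one simulated expression dataset."""

    effects: pd.Series  # per-probe signed log2 effect, female-positive
    true_sex: pd.Series  # per-sample true sex
    mislabeled: list[str]  # sample ids with flipped recorded sex
    domains: list[EscapeeDomain]

    @property
    def planted_probes(self) -> pd.Index:
        return self.effects.index[self.effects != 0.0]


@dataclass
class QPCRDataset:
    """Synthetic qPCR run: per-sample Ct values plus per-gene dilution series."""

    measurements: pd.DataFrame  # sample_id, sex, tissue, gene, ct
    dilution_series: pd.DataFrame  # gene, dilution, ct
    reference_genes: tuple[str, str]
    true_ratios: dict[str, float]


def _place_interval(chrom: str, start: int, length: int,
                    chrom_sizes: dict[str, int]) -> None:
    if start < 0 or start + length > chrom_sizes[chrom]:
        raise ValueError(
            f"interval [{start}, {start + length}) exceeds {chrom} "
            f"(length {chrom_sizes[chrom]})"
        )


def _realize_domain(t: DomainTemplate) -> tuple[GenomicInterval, GenomicInterval]:
    """Return (coding, noncoding) intervals for a domain template."""
    if t.orientation == "head_to_head":
        # non-coding on the minus strand upstream, 5' ends facing across the gap
        nc = GenomicInterval("X", t.start, t.start + t.noncoding_len, "-")
        c0 = nc.end + t.gap
        cod = GenomicInterval("X", c0, c0 + t.coding_len, "+")
    elif t.orientation == "tandem":
        cod = GenomicInterval("X", t.start, t.start + t.coding_len, "+")
        n0 = cod.end + t.gap
        nc = GenomicInterval("X", n0, n0 + t.noncoding_len, "+")
    else:  # nested_intronic: non-coding antisense within the coding gene body
        cod = GenomicInterval("X", t.start, t.start + t.coding_len, "+")
        n0 = t.start + t.coding_len // 3
        nc = GenomicInterval("X", n0, n0 + t.noncoding_len, "-")
    return cod, nc


def generate_annotation(
    genome: GenomeSpec, n_probes: int, seed: int
) -> ProbeAnnotation:
    """Emit a probe annotation realizing the genome spec.

    Template genes (escapee domains, Xist/Jpx, Y genes, controls) are placed
    at their configured loci; the remaining ``n_probes - templates`` filler
    probes are placed uniformly at random across chromosomes (weighted by
    chromosome length). Every probe maps to exactly one gene interval.
    """
    n_template = genome.n_template_probes()
    if n_probes < n_template:
        raise ValueError(
            f"n_probes={n_probes} below the {n_template} template probes"
        )
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    roles: dict[str, str] = {}
    domains: list[EscapeeDomain] = []

    def add_probe(probe_id, iv: GenomicInterval, gene, biotype):
        _place_interval(iv.chrom, iv.start, iv.length, genome.chromosomes)
        rows.append(
            {
                "chrom": iv.chrom, "start": iv.start, "end": iv.end,
                "probe_id": probe_id, "score": 0, "strand": iv.strand,
                "gene": gene, "biotype": biotype,
            }
        )

    for t in genome.domain_templates:
        cod, nc = _realize_domain(t)
        add_probe(f"p_{t.coding}", cod, t.coding, "coding")
        add_probe(f"p_{t.noncoding}", nc, t.noncoding, "noncoding")
        roles[t.coding] = "escapee_coding"
        roles[t.noncoding] = "escapee_noncoding"
        domains.append(
            EscapeeDomain(
                coding=t.coding, coding_interval=cod,
                noncoding=t.noncoding, noncoding_interval=nc,
                gap=gene_gap(cod, nc),
                relation=classify_relation(cod, nc),
            )
        )

    for g in genome.single_genes:
        iv = GenomicInterval(g.chrom, g.start, g.start + g.length, g.strand)
        n_copies = genome.n_xist_probes if g.role == "xist" else 1
        for i in range(n_copies):
            pid = f"p_{g.name}" if n_copies == 1 else f"p_{g.name}_{i + 1}"
            add_probe(pid, iv, g.name, g.biotype)
        roles[g.name] = g.role

    n_filler = n_probes - n_template
    if n_filler:
        chroms = list(genome.chromosomes)
        weights = np.array(
            [
                genome.chromosomes[c] * genome.gene_density.get(c, 1.0)
                for c in chroms
            ],
            dtype=float,
        )
        weights /= weights.sum()
        picks = rng.choice(len(chroms), size=n_filler, p=weights)
        lengths = rng.integers(2_000, 10_001, size=n_filler)
        strands = rng.choice(["+", "-"], size=n_filler)
        for i in range(n_filler):
            chrom = chroms[picks[i]]
            length = int(lengths[i])
            start = int(rng.integers(0, genome.chromosomes[chrom] - length))
            gene = f"G{i:05d}"
            add_probe(
                f"p_{gene}",
                GenomicInterval(chrom, start, start + length, strands[i]),
                gene, "coding",
            )

    table = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)
    return ProbeAnnotation(
        table=table,
        chrom_sizes=dict(genome.chromosomes),
        domains=domains,
        gene_roles=roles,
    )


def _planted_order(annotation: ProbeAnnotation) -> list[str]:
    """Priority order in which probes receive planted effects."""
    by_role: dict[str, list[str]] = {}
    for _, row in annotation.table.iterrows():
        role = annotation.gene_roles.get(row["gene"], "filler")
        by_role.setdefault(role, []).append(row["probe_id"])
    order: list[str] = []
    for role in ("xist", "y_linked", "escapee_coding", "escapee_noncoding",
                 "jpx", "coding_escapee"):
        order.extend(by_role.get(role, []))
    return order


def generate_expression(
    config: SimulationConfig, annotation: ProbeAnnotation, seed: int
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Simulate a log2 expression matrix with planted sex effects.

    Planted probes receive a signed female-positive log2 effect split evenly
    between the sexes around a Gaussian per-probe baseline. Special probes
    are planted first (Xist, then Y-linked genes, then the escapee-domain
    genes) until the ``frac_sex_biased`` budget is reached; any remainder is
    drawn at random from filler probes with random sign. Xist and Y probes
    use a detection-floor model: the silenced sex sits at near-floor signal
    so the female/male Xist ratio reaches ~2^xist_log2_effect. A
    ``mislabel_frac`` fraction of samples have their recorded (not true) sex
    flipped.
    """
    if len(annotation) != config.n_probes:
        raise ValueError("annotation does not cover the configured probe count")
    rng = np.random.default_rng(seed)
    probe_ids = list(annotation.probe_ids)

    tissues = config.tissue_names()
    k = config.samples_per_sex_per_tissue
    sample_ids, true_sex, tissue_of = [], [], []
    for t in tissues:
        for sex in ("F", "M"):
            for i in range(k):
                sample_ids.append(f"{t}_{sex}{i + 1:03d}")
                true_sex.append(sex)
                tissue_of.append(t)
    n_samples = len(sample_ids)

    n_mislabel = int(round(config.mislabel_frac * n_samples))
    mislabel_idx = (
        rng.choice(n_samples, size=n_mislabel, replace=False)
        if n_mislabel else np.array([], dtype=int)
    )
    recorded = np.array(true_sex)
    for i in mislabel_idx:
        recorded[i] = "M" if recorded[i] == "F" else "F"
    mislabeled = [sample_ids[i] for i in sorted(mislabel_idx)]

    truth_sex = pd.Series(true_sex, index=sample_ids, name="true_sex")
    for t in tissues:
        for sex in ("F", "M"):
            ok = sum(
                1 for i, s in enumerate(sample_ids)
                if tissue_of[i] == t and true_sex[i] == sex
                and s not in mislabeled
            )
            if ok == 0:
                raise ValueError(
                    "mislabel_frac too high: no correctly labeled "
                    f"{sex} arrays left in {t}; balancing impossible"
                )

    # --- planted effects -------------------------------------------------
    effects = pd.Series(0.0, index=probe_ids, name="log2_effect")
    probe_gene = annotation.table.set_index("probe_id")["gene"]
    n_planted = int(round(config.frac_sex_biased * config.n_probes))
    specials = _planted_order(annotation)
    chosen = specials[:n_planted]
    if n_planted > len(chosen):
        protected = {
            p for p in probe_ids
            if annotation.gene_roles.get(probe_gene[p], "filler") != "filler"
        }
        pool = [p for p in probe_ids if p not in protected]
        extra = rng.choice(len(pool), size=n_planted - len(chosen), replace=False)
        chosen = chosen + [pool[i] for i in sorted(extra)]
    lo_e, hi_e = config.escapee_effect_range_log2
    lo_r, hi_r = config.effect_range_log2
    floor_probes: dict[str, str] = {}  # probe -> high-signal sex
    for p in chosen:
        role = annotation.gene_roles.get(probe_gene[p], "filler")
        if role == "xist":
            effects[p] = config.xist_log2_effect
            floor_probes[p] = "F"
        elif role == "y_linked":
            effects[p] = -config.y_log2_effect
            floor_probes[p] = "M"
        elif role in ("escapee_coding", "escapee_noncoding", "jpx",
                      "coding_escapee"):
            effects[p] = rng.uniform(lo_e, hi_e)
        else:
            sign = rng.choice([-1.0, 1.0])
            effects[p] = sign * rng.uniform(lo_r, hi_r)

    # --- values -----------------------------------------------------------
    baseline = rng.normal(config.baseline_mean, config.baseline_sd,
                          size=config.n_probes)
    female = (np.array(true_sex) == "F").astype(float)
    half = effects.to_numpy()[:, None] * (female[None, :] - 0.5)
    values = baseline[:, None] + half
    for p, high_sex in floor_probes.items():
        i = probe_ids.index(p)
        high = (np.array(true_sex) == high_sex)
        values[i, :] = np.where(
            high, config.floor_log2 + abs(effects[p]), config.floor_log2
        )
    values = values + rng.normal(0.0, config.noise_sd, size=values.shape)

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=sample_ids),
        samples=pd.DataFrame(
            {
                "sex": recorded,
                "tissue": tissue_of,
                "platform": [config.platform_of(t) for t in tissue_of],
            },
            index=pd.Index(sample_ids, name="sample_id"),
        ),
    )
    truth = GroundTruth(
        effects=effects,
        true_sex=truth_sex,
        mislabeled=mislabeled,
        domains=list(annotation.domains),
    )
    return matrix, truth


def generate_peaks(
    annotation: ProbeAnnotation,
    seed: int,
    peak_len: int = 1_000,
    spacing: int = 1_500,
    jitter: int = 150,
) -> "PeakSet":
    """Tile the X chromosome with repressive-mark peaks, skipping escapee
    domains.

    Emulates an H3K27me3 track from female tissue: dense enrichment across
    the (largely inactivated) X with coverage ~peak_len/spacing, and no peaks
    over the escapee domain spans, so X-inactivated control genes are covered
    while escapee domains are depleted.
    """
    from .domains import PeakSet  # local import to avoid cycle at module load

    if "X" not in annotation.chrom_sizes:
        x_probes = annotation.probes_on("X")
        if x_probes.empty:
            raise ValueError("annotation has no X chromosome")
        x_len = int(x_probes["end"].max())
    else:
        x_len = annotation.chrom_sizes["X"]

    rng = np.random.default_rng(seed)
    grid = np.arange(0, x_len - peak_len, spacing)
    starts = grid + rng.integers(-jitter, jitter + 1, size=grid.size)
    starts = np.clip(starts, 0, x_len - peak_len)
    ends = starts + peak_len

    keep = np.ones(starts.size, dtype=bool)
    for d in annotation.domains:
        span = d.span
        keep &= ~((starts < span.end) & (ends > span.start))

    table = pd.DataFrame({"chrom": "X", "start": starts[keep], "end": ends[keep]})
    return PeakSet(intervals=table.reset_index(drop=True))


def generate_qpcr(config: SimulationConfig, seed: int) -> QPCRDataset:
    """Simulate qPCR Ct tables plus per-gene cDNA dilution series.

    Dilution-series Ct follows Ct = a + b*log10(dilution) with the ideal
    slope b = -1/log10(2) (about -3.32, 100% efficiency) plus Gaussian Ct
    noise. Per-sample target Ct encodes the planted female/male ratios;
    reference genes carry no sex effect.
    """
    if any(d <= 0 for d in config.qpcr_dilutions):
        raise ValueError("dilution factors must be positive")
    rng = np.random.default_rng(seed)
    genes = list(config.qpcr_targets) + list(config.qpcr_reference_genes)
    intercepts = {
        g: config.qpcr_intercept + rng.uniform(-1.0, 1.0) for g in genes
    }
    slope = LOG2_10FOLD_SLOPE

    dil_rows = []
    for g in genes:
        for d in config.qpcr_dilutions:
            ct = intercepts[g] + slope * math.log10(d)
            ct += rng.normal(0.0, config.qpcr_ct_sd)
            dil_rows.append({"gene": g, "dilution": d, "ct": ct})

    meas_rows = []
    for tissue in config.tissue_names():
        for sex in ("F", "M"):
            for i in range(config.qpcr_n_per_sex):
                sid = f"{tissue}_{sex}{i + 1:02d}"
                for g in genes:
                    ratio = config.qpcr_targets.get(g, 1.0)
                    q = config.qpcr_base_input * (ratio if sex == "F" else 1.0)
                    ct = intercepts[g] + slope * math.log10(q)
                    ct += rng.normal(0.0, config.qpcr_ct_sd)
                    meas_rows.append(
                        {"sample_id": sid, "sex": sex, "tissue": tissue,
                         "gene": g, "ct": ct}
                    )

    return QPCRDataset(
        measurements=pd.DataFrame(meas_rows),
        dilution_series=pd.DataFrame(dil_rows),
        reference_genes=tuple(config.qpcr_reference_genes),
        true_ratios=dict(config.qpcr_targets),
    )
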