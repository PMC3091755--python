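"""qPCR validation: standard-curve quantification, reference-gene
normalization, and female/male comparison.

Background-subtracted Ct values are converted to relative copy numbers via a
per-gene standard curve fitted to a cDNA dilution series, normalized to the
geometric mean of two endogenous reference genes (Actb and Gapdh), and
compared between sexes with a two-sided unequal-variance (Welch) t-test on
the linear normalized values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import QPCRDataset


@dataclass(frozen=True)
class StandardCurve:
    """Linear fit Ct = intercept + slope * log10(relative input)."""

    slope: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")

    @property
    def efficiency(self) -> float:
        """Amplification efficiency E = 10^(-1/slope) - 1 (1.0 = doubling)."""
        if self.slope >= 0:
            raise ValueError("efficiency undefined for non-negative slope")
        return 10.0 ** (-1.0 / self.slope) - 1.0


@dataclass(frozen=True)
class SexComparison:
    """Female/male expression comparison for one gene in one tissue."""

    ratio: float  # mean(F) / mean(M), linear scale
    sem_f: float
    sem_m: float
    p: float
    stars: str  # "***", "**", "*", or "ns"


def fit_standard_curve(dilutions, ct) -> StandardCurve:
    """Least-squares fit of Ct against log10(relative input)."""
    d = np.asarray(dilutions, dtype=float)
    y = np.asarray(ct, dtype=float)
    if d.shape != y.shape:
        raise ValueError("dilutions and Ct must have matching lengths")
    if np.any(d <= 0):
        raise ValueError("dilution factors must be positive")
    if np.unique(d).size < 3:
        raise ValueError("need at least 3 distinct dilution levels")
    x = np.log10(d)
    res = stats.linregress(x, y)
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 0.0
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=min(r2, 1.0))


def quantify(ct: float, curve: StandardCurve) -> float:
    """Relative copy number 10^((ct - intercept)/slope); NaN for missing Ct."""
    if curve.slope == 0:
        raise ValueError("standard curve has zero slope")
    if not np.isfinite(ct):
        return float("nan")  # flagged missing, not an error
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def normalize_geomean(target: float, ref1: float, ref2: float) -> float:
    """Target copies over the geometric mean of two reference-gene copies."""
    if ref1 <= 0 or ref2 <= 0:
        raise ValueError("reference copy numbers must be positive")
    return target / math.sqrt(ref1 * ref2)


def significance_stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "ns"


def compare_sexes(values_f, values_m) -> SexComparison:
    """Welch two-sided t-test and female/male ratio of means with SEMs."""
    f = np.asarray(values_f, dtype=float)
    m = np.asarray(values_m, dtype=float)
    if f.size < 2 or m.size < 2:
        raise ValueError("need at least 2 values per sex")
    if m.mean() == 0:
        raise ValueError("male mean is zero; ratio undefined")
    if f.mean() == m.mean():
        p = 1.0  # zero mean difference, including the all-constant case
    else:
        p = float(stats.ttest_ind(f, m, equal_var=False).pvalue)
        if not np.isfinite(p):
            p = 1.0
    return SexComparison(
        ratio=float(f.mean() / m.mean()),
        sem_f=float(stats.sem(f)),
        sem_m=float(stats.sem(m)),
        p=p,
        stars=significance_stars(p),
    )


def analyze_qpcr(dataset: QPCRDataset) -> pd.DataFrame:
    """Full qPCR analysis of a Ct table with per-gene dilution series.

    For each gene, fit its standard curve, convert sample Ct to relative
    copies, normalize each sample's targets by the geometric mean of the two
    reference-gene copies in the same sample, then compare sexes per tissue.
    Returns one row per (tissue, gene) with ratio, SEMs, p and stars.
    """
    curves = {
        g: fit_standard_curve(grp["dilution"], grp["ct"])
        for g, grp in dataset.dilution_series.groupby("gene")
    }
    meas = dataset.measurements.copy()
    meas["copies"] = [
        quantify(ct, curves[g]) for ct, g in zip(meas["ct"], meas["gene"])
    ]

    ref1, ref2 = dataset.reference_genes
    ref_copies = (
        meas[meas["gene"].isin([ref1, ref2])]
        .pivot(index="sample_id", columns="gene", values="copies")
    )
    rows = []
    targets = [g for g in meas["gene"].unique() if g not in (ref1, ref2)]
    for tissue, tgrp in meas.groupby("tissue", sort=False):
        for gene in targets:
            sub = tgrp[tgrp["gene"] == gene]
            norm = {
                sid: normalize_geomean(
                    c, ref_copies.loc[sid, ref1], ref_copies.loc[sid, ref2]
                )
                for sid, c in zip(sub["sample_id"], sub["copies"])
            }
            f_vals = [norm[s] for s in sub.loc[sub["sex"] == "F", "sample_id"]]
            m_vals = [norm[s] for s in sub.loc[sub["sex"] == "M", "sample_id"]]
            cmp = compare_sexes(f_vals, m_vals)
            rows.append(
                {
                    "tissue": tissue, "gene": gene, "ratio": cmp.ratio,
                    "sem_f": cmp.sem_f, "sem_m": cmp.sem_m,
                    "p": cmp.p, "stars": cmp.stars,
                }
            )
    return pd.DataFrame(
        rows, columns=["tissue", "gene", "ratio", "sem_f", "sem_m", "p", "stars"]
    )
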