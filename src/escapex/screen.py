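"""Per-probe sex-bias screen: Wilcoxon Mann-Whitney tests with
Benjamini-Hochberg FDR control and signed linear fold changes.

The screen is run per tissue on a sex-balanced matrix. The BH family is all
probes of that tissue. Fold changes follow the signed convention used for
sex-bias tables: positive values are female-up linear ratios, negative
values are the negative reciprocal for male-up genes (|FC| >= 1 always).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import ExpressionMatrix, ProbeAnnotation

_P_FLOOR = np.finfo(float).tiny  # keep p in (0, 1]

#: combined-n cutoff below which the exact null distribution is enumerated
EXACT_N_CUTOFF = 12


@dataclass(frozen=True)
class SexBiasResult:
    """One significant probe from the per-tissue screen."""

    probe_id: str
    gene: str
    chrom: str
    u_statistic: float
    p_raw: float
    p_adj: float
    fold_change: float  # signed: >= +1 female-up, <= -1 male-up
    direction: str  # female_up | male_up

    def __post_init__(self) -> None:
        if self.direction not in ("female_up", "male_up"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.p_adj < self.p_raw - 1e-12:
            raise ValueError("adjusted p below raw p")
        if abs(self.fold_change) < 1.0 - 1e-12:
            raise ValueError("|fold change| must be >= 1")
        if (self.fold_change > 0) != (self.direction == "female_up"):
            raise ValueError("fold-change sign inconsistent with direction")


def mann_whitney_u(values_f, values_m) -> tuple[float, float]:
    """Two-sided Mann-Whitney test of female vs male values.

    Returns (U for the female group from midranks, two-sided p). The exact
    null distribution is used when the combined sample size is at most
    :data:`EXACT_N_CUTOFF` and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.
    """
    f = np.asarray(values_f, dtype=float)
    m = np.asarray(values_m, dtype=float)
    if f.size == 0 or m.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([f, m])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_N_CUTOFF and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(f, m, alternative="two-sided", method=method)
    p = float(np.clip(res.pvalue, _P_FLOOR, 1.0))
    return float(res.statistic), p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change_signed(mean_log2_f: float, mean_log2_m: float) -> float:
    """Signed linear female/male fold change from log2 group means."""
    r = 2.0 ** (mean_log2_f - mean_log2_m)
    return r if r >= 1.0 else -1.0 / r


def _test_all_probes(values_f: np.ndarray, values_m: np.ndarray):
    """Vectorized U and two-sided p for each probe row."""
    n = values_f.shape[1] + values_m.shape[1]
    if n <= EXACT_N_CUTOFF:
        out_u = np.empty(values_f.shape[0])
        out_p = np.empty(values_f.shape[0])
        for i in range(values_f.shape[0]):
            out_u[i], out_p[i] = mann_whitney_u(values_f[i], values_m[i])
        return out_u, out_p
    res = stats.mannwhitneyu(
        values_f, values_m, alternative="two-sided", method="asymptotic", axis=1
    )
    return (
        np.asarray(res.statistic, dtype=float),
        np.clip(np.asarray(res.pvalue, dtype=float), _P_FLOOR, 1.0),
    )


def screen_tissue(
    matrix: ExpressionMatrix,
    annotation: ProbeAnnotation | None = None,
    alpha: float = 0.05,
) -> list[SexBiasResult]:
    """Screen one balanced tissue for sex-biased probes at FDR ``alpha``.

    One Mann-Whitney test per probe; BH adjustment across all probes of the
    tissue; probes with adjusted p <= alpha are returned with signed fold
    change and direction. The input must hold a single tissue with equal
    female and male counts (the output of QC balancing).
    """
    tissues = matrix.tissues()
    if len(tissues) != 1:
        raise ValueError(f"screen_tissue expects one tissue, got {tissues}")
    counts = matrix.sex_counts()
    if counts["F"] != counts["M"] or counts["F"] == 0:
        raise ValueError(f"matrix is not sex-balanced: {counts}")

    f_ids = matrix.sample_ids(sex="F")
    m_ids = matrix.sample_ids(sex="M")
    vf = matrix.values[f_ids].to_numpy()
    vm = matrix.values[m_ids].to_numpy()
    u, p_raw = _test_all_probes(vf, vm)
    p_adj = bh_adjust(p_raw)

    gene_of: dict[str, tuple[str, str]] = {}
    if annotation is not None:
        t = annotation.table.set_index("probe_id")
        gene_of = {pid: (t.loc[pid, "gene"], t.loc[pid, "chrom"])
                   for pid in matrix.values.index if pid in t.index}

    mean_f = vf.mean(axis=1)
    mean_m = vm.mean(axis=1)
    hits: list[SexBiasResult] = []
    for i, probe in enumerate(matrix.values.index):
        if p_adj[i] > alpha:
            continue
        fc = fold_change_signed(mean_f[i], mean_m[i])
        gene, chrom = gene_of.get(probe, (probe, "NA"))
        hits.append(
            SexBiasResult(
                probe_id=probe,
                gene=gene,
                chrom=chrom,
                u_statistic=float(u[i]),
                p_raw=float(p_raw[i]),
                p_adj=float(p_adj[i]),
                fold_change=fc,
                direction="female_up" if fc > 0 else "male_up",
            )
        )
    return hits


def heatmap_matrix(
    matrix: ExpressionMatrix, hits: list[SexBiasResult]
) -> pd.DataFrame:
    """Hit rows centered on their overall (both-sex) mean, for heatmaps."""
    probes = [h.probe_id for h in hits]
    missing = [p for p in probes if p not in matrix.values.index]
    if missing:
        raise KeyError(f"hits not in matrix: {missing}")
    rows = matrix.values.loc[probes]
    return rows.sub(rows.mean(axis=1), axis=0)


def results_to_frame(hits: list[SexBiasResult]) -> pd.DataFrame:
    """Hits as a table mirroring the per-tissue significant-probe lists."""
    return pd.DataFrame(
        [
            {
                "probe": h.probe_id, "gene": h.gene, "chr": h.chrom,
                "U": h.u_statistic, "p_raw": h.p_raw, "p_adj": h.p_adj,
                "fold_change": h.fold_change, "direction": h.direction,
            }
            for h in hits
        ],
        columns=["probe", "gene", "chr", "U", "p_raw", "p_adj",
                 "fold_change", "direction"],
    )
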