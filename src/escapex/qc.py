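"""Array-level quality control: per-array standardization, Xist-based
detection of sex-mislabeled arrays, and sex balancing.

Xist is expressed almost exclusively from the inactive X in females, so its
log2 intensity separates the sexes by orders of magnitude. An array whose
Xist signal falls on the wrong side of the between-sex threshold for *every*
Xist probe is flagged as potentially sex-reversed in the metadata and
excluded before the differential screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import ExpressionMatrix


@dataclass
class QCReport:
    """Outcome of the Xist sex check and subsequent balancing."""

    flagged: dict[str, str] = field(default_factory=dict)  # sample -> reason
    xist_values: pd.DataFrame | None = None  # samples x Xist probes
    thresholds: dict[str, float] = field(default_factory=dict)  # probe -> cut
    excluded_for_balance: list[str] = field(default_factory=list)

    @property
    def flagged_samples(self) -> list[str]:
        return sorted(self.flagged)


def standardize_arrays(
    matrix: ExpressionMatrix, target_mean: float = 8.0, target_sd: float = 2.0
) -> ExpressionMatrix:
    """Affinely rescale every sample column to the target mean and SD.

    Uses the population (1/n) SD convention so that a repeat application is
    an exact fixed point. Raises on constant columns, naming the sample.
    """
    values = matrix.values
    means = values.mean(axis=0)
    sds = values.std(axis=0, ddof=0)
    constant = sds[sds == 0]
    if len(constant):
        raise ValueError(
            f"constant expression column(s): {list(constant.index)}; "
            "cannot standardize"
        )
    scaled = (values - means) / sds * target_sd + target_mean
    return ExpressionMatrix(values=scaled, samples=matrix.samples.copy())


def xist_sex_check(
    matrix: ExpressionMatrix, xist_probe_ids: list[str]
) -> QCReport:
    """Flag samples whose Xist signal contradicts their recorded sex.

    For each Xist probe a decision threshold is placed at the midpoint
    between the recorded-female and recorded-male medians (robust to the
    mislabeled arrays themselves). A sample is flagged iff, on *all* Xist
    probes, its value falls strictly on the opposite side of the threshold
    relative to its recorded sex — the scatter-plot "opposite quadrant" rule.
    """
    probes = [p for p in xist_probe_ids if p in matrix.values.index]
    if not probes:
        raise ValueError("no Xist probes present in the expression matrix")
    f_ids = matrix.sample_ids(sex="F")
    m_ids = matrix.sample_ids(sex="M")
    if not f_ids or not m_ids:
        raise ValueError("both recorded sexes must be non-empty for the Xist check")

    thresholds: dict[str, float] = {}
    female_high: dict[str, bool] = {}
    for p in probes:
        med_f = matrix.values.loc[p, f_ids].median()
        med_m = matrix.values.loc[p, m_ids].median()
        if med_f == med_m:
            raise ValueError(
                f"Xist probe {p!r}: female and male medians coincide; "
                "threshold undefined"
            )
        thresholds[p] = (med_f + med_m) / 2.0
        female_high[p] = med_f > med_m

    flagged: dict[str, str] = {}
    for sample in matrix.values.columns:
        sex = matrix.samples.loc[sample, "sex"]
        discordant_all = True
        for p in probes:
            v = matrix.values.loc[p, sample]
            on_female_side = (v > thresholds[p]) if female_high[p] else (v < thresholds[p])
            on_male_side = (v < thresholds[p]) if female_high[p] else (v > thresholds[p])
            discordant = on_male_side if sex == "F" else on_female_side
            if not discordant:
                discordant_all = False
                break
        if discordant_all:
            flagged[sample] = "xist_discordant"

    return QCReport(
        flagged=flagged,
        xist_values=matrix.values.loc[probes].T.copy(),
        thresholds=thresholds,
    )


def balance_by_sex(
    matrix: ExpressionMatrix, flagged: QCReport, seed: int
) -> ExpressionMatrix:
    """Drop flagged samples, then equalize sex counts within each tissue.

    The larger recorded-sex group of each tissue is down-sampled uniformly at
    random (seeded) to the size of the smaller. The removed ids are recorded
    on the report's ``excluded_for_balance``.
    """
    rng = np.random.default_rng(seed)
    keep = [s for s in matrix.values.columns if s not in flagged.flagged]
    trimmed = matrix.subset_samples(keep)

    selected: list[str] = []
    excluded: list[str] = []
    for tissue in trimmed.tissues():
        f_ids = trimmed.sample_ids(sex="F", tissue=tissue)
        m_ids = trimmed.sample_ids(sex="M", tissue=tissue)
        n = min(len(f_ids), len(m_ids))
        if n == 0:
            raise ValueError(
                f"tissue {tissue!r}: a sex group is empty after QC; "
                "cannot balance"
            )
        for ids in (f_ids, m_ids):
            if len(ids) > n:
                drop = rng.choice(len(ids), size=len(ids) - n, replace=False)
                dropped = {ids[i] for i in drop}
                excluded.extend(sorted(dropped))
                ids = [s for s in ids if s not in dropped]
            selected.extend(ids)

    flagged.excluded_for_balance = excluded
    # preserve original column order
    order = [s for s in matrix.values.columns if s in set(selected)]
    return trimmed.subset_samples(order)


def report_to_frame(report: QCReport) -> pd.DataFrame:
    """Tabular QC report: one row per sample with flag status and Xist values."""
    if report.xist_values is None:
        raise ValueError("report carries no Xist values")
    out = report.xist_values.copy()
    out.insert(0, "flag", [
        report.flagged.get(s, "ok") for s in out.index
    ])
    out["excluded_for_balance"] = [
        s in set(report.excluded_for_balance) for s in out.index
    ]
    out.index.name = "sample_id"
    return out
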