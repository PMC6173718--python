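"""Cohort-level comparison of PK parameters between treatment fractions.

Fraction F1 and F2 summaries are compared parameter by parameter with the
two-sided Mann–Whitney U test at α = 0.05 (unpaired, as the emulated study
design prescribes even though part of the cohort received both fractions; a
paired Wilcoxon signed-rank option is available behind a flag).  No
multiple-testing correction is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["ComparisonRow", "mann_whitney", "compare_fractions"]


@dataclass(frozen=True)
class ComparisonRow:
    """One parameter's F1-vs-F2 comparison."""

    parameter: str
    f1_values: Tuple[float, ...]
    f2_values: Tuple[float, ...]
    f1_mean: float
    f1_sd: float
    f2_mean: float
    f2_sd: float
    u_statistic: float
    p_value: float
    alpha: float
    significant: bool
    method: str

    def formatted(self) -> Dict[str, str]:
        return {
            "parameter": self.parameter,
            "F1": f"{self.f1_mean:.4g} ({self.f1_sd:.4g})",
            "F2": f"{self.f2_mean:.4g} ({self.f2_sd:.4g})",
            "p": f"{self.p_value:.3g}",
            "significant": str(self.significant),
        }


def mann_whitney(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alpha: float = 0.05,
    parameter: str = "",
) -> ComparisonRow:
    """Two-sided Mann–Whitney U comparison of two independent samples.

    Uses the exact null distribution when both groups have ≤ 20 values and
    no ties are present, otherwise the tie-corrected normal approximation
    with continuity correction.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and max(a.size, b.size) <= 20:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return ComparisonRow(
        parameter=parameter,
        f1_values=tuple(a),
        f2_values=tuple(b),
        f1_mean=float(a.mean()),
        f1_sd=float(a.std(ddof=1)) if a.size > 1 else 0.0,
        f2_mean=float(b.mean()),
        f2_sd=float(b.std(ddof=1)) if b.size > 1 else 0.0,
        u_statistic=float(res.statistic),
        p_value=p,
        alpha=alpha,
        significant=p < alpha,
        method=method,
    )


def _wilcoxon_row(a, b, alpha, parameter) -> ComparisonRow:
    res = sps.wilcoxon(a, b, alternative="two-sided")
    p = float(res.pvalue)
    return ComparisonRow(
        parameter=parameter,
        f1_values=tuple(a), f2_values=tuple(b),
        f1_mean=float(np.mean(a)), f1_sd=float(np.std(a, ddof=1)),
        f2_mean=float(np.mean(b)), f2_sd=float(np.std(b, ddof=1)),
        u_statistic=float(res.statistic), p_value=p, alpha=alpha,
        significant=p < alpha, method="wilcoxon_paired",
    )


def compare_fractions(
    summaries_f1: pd.DataFrame,
    summaries_f2: pd.DataFrame,
    alpha: float = 0.05,
    parameters: Optional[Sequence[Tuple[str, str]]] = None,
    paired: bool = False,
) -> List[ComparisonRow]:
    """One comparison row per (compartment, parameter).

    Inputs are long-format summary frames with columns patient_id,
    compartment, parameter, value (one frame per fraction — fractions are
    never pooled).  ``parameters`` restricts/orders the rows as a list of
    (compartment, parameter) pairs; by default every pair present in both
    fractions is compared.  ``paired=True`` switches to the Wilcoxon
    signed-rank test on the patients present in both fractions.
    """
    required = {"patient_id", "compartment", "parameter", "value"}
    for df in (summaries_f1, summaries_f2):
        if not required.issubset(df.columns):
            raise ValueError(f"summary frame must have columns {sorted(required)}")
    if summaries_f1.empty or summaries_f2.empty:
        raise ValueError("both fraction summary sets must be non-empty")

    if parameters is None:
        keys1 = set(map(tuple, summaries_f1[["compartment", "parameter"]].drop_duplicates().values))
        keys2 = set(map(tuple, summaries_f2[["compartment", "parameter"]].drop_duplicates().values))
        parameters = sorted(keys1 & keys2)

    rows: List[ComparisonRow] = []
    for comp, param in parameters:
        s1 = summaries_f1[(summaries_f1["compartment"] == comp)
                          & (summaries_f1["parameter"] == param)]
        s2 = summaries_f2[(summaries_f2["compartment"] == comp)
                          & (summaries_f2["parameter"] == param)]
        label = f"{comp}:{param}"
        if paired:
            merged = s1.merge(s2, on="patient_id", suffixes=("_1", "_2"))
            rows.append(_wilcoxon_row(
                merged["value_1"].to_numpy(), merged["value_2"].to_numpy(), alpha, label))
        else:
            rows.append(mann_whitney(
                s1["value"].to_numpy(), s2["value"].to_numpy(), alpha, label))
    return rows
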