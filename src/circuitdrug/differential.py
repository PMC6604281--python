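"""Two-group differential circuit-activity testing.

Each circuit's activities are compared between cases and controls with the
Wilcoxon rank-sum (Mann-Whitney) test.  The reported statistic is the
normal-approximation z with tie and continuity corrections, signed to agree
with the direction of the group-mean difference (UP = higher in cases); the
p-value is exact (permutation distribution of U) when both groups have at
most ``exact_max`` samples and no ties, asymptotic otherwise.  Circuit-level
p-values are corrected with the Benjamini-Hochberg step-up FDR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .mechanistic import CircuitActivityMatrix


@dataclass
class DifferentialReport:
    """Per-circuit direction, signed z statistic, p-value and BH-adjusted p."""

    table: pd.DataFrame  # index=circuit; columns: direction, statistic, p_value, fdr_adjusted

    def __post_init__(self) -> None:
        t = self.table
        if (t["fdr_adjusted"] + 1e-15 < t["p_value"]).any():
            raise ValueError("FDR-adjusted p-values cannot be below raw p-values")


def _rank_sum_z(group_a: np.ndarray, group_b: np.ndarray) -> float:
    """z statistic of the rank-sum test for a vs b, with tie and continuity
    corrections (positive when a tends to exceed b)."""
    n1, n2 = len(group_a), len(group_b)
    pooled = np.concatenate([group_a, group_b])
    ranks = stats.rankdata(pooled)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return 0.0
    num = u1 - mu
    if num != 0:  # continuity correction toward the null
        num -= 0.5 * np.sign(num)
    return float(num / np.sqrt(var))


def wilcoxon_circuit_test(
    group_a: np.ndarray | list,
    group_b: np.ndarray | list,
    exact_max: int = 10,
) -> tuple[float, float]:
    """Rank-sum test of group_a vs group_b -> (signed z, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    z = _rank_sum_z(a, b)
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(a) <= exact_max and len(b) <= exact_max and not has_ties:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue)
    else:
        p = float(2.0 * stats.norm.sf(abs(z)))
    return z, min(p, 1.0)


def bh_adjust(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_report(
    activities: CircuitActivityMatrix,
    labels: pd.Series | dict[str, str],
    case_level: str,
) -> DifferentialReport:
    """Per-circuit case-vs-control report (direction, z, p, BH-adjusted p).

    ``labels`` maps sample id -> group label; ``case_level`` names the case
    group, every other label is control.  Direction is UP when the case mean
    activity exceeds the control mean, and the statistic carries that sign.
    """
    labels = pd.Series(labels)
    samples = activities.sample_ids
    missing = [s for s in samples if s not in labels.index]
    if missing:
        raise ValueError(f"samples without a group label: {missing[:5]}")
    is_case = labels.loc[samples] == case_level
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise ValueError("both groups need at least two samples")
    rows = []
    for circuit in activities.circuit_ids:
        vals = activities.activities.loc[circuit].to_numpy(dtype=float)
        case_vals, ctrl_vals = vals[is_case.to_numpy()], vals[~is_case.to_numpy()]
        z, p = wilcoxon_circuit_test(case_vals, ctrl_vals)
        diff = case_vals.mean() - ctrl_vals.mean()
        direction = "UP" if diff > 0 else "DOWN"
        statistic = abs(z) if direction == "UP" else -abs(z)
        rows.append((circuit, direction, statistic, p))
    df = pd.DataFrame(
        rows, columns=["circuit", "direction", "statistic", "p_value"]
    ).set_index("circuit")
    df["fdr_adjusted"] = bh_adjust(df["p_value"].to_numpy())
    return DifferentialReport(table=df)


def write_report_tsv(report: DifferentialReport, path) -> None:
    report.table.to_csv(path, sep="\t")
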