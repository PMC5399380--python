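"""Group comparison of cell/body ratios: one-way ANOVA + Tukey's HSD.

The luminal-filling statistic is compared across treatment groups
(e.g. control / induced / induced+inhibitor) by classical one-way
fixed-effects ANOVA, followed by Tukey's honestly-significant-difference
post-hoc test on all pairs.  Unequal group sizes use the Tukey–Kramer
standard error.  Each spheroid is one observation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupMeasurements",
    "ComparisonResult",
    "one_way_anova",
    "tukey_hsd",
    "compare_groups",
]

GroupMeasurements = Dict[str, Sequence[float]]


def _validate(groups: GroupMeasurements) -> Dict[str, np.ndarray]:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            raise ValueError(f"group {name!r} has n < 2")
        out[name] = arr
    return out


@dataclass
class ComparisonResult:
    """ANOVA F and p, Tukey pairwise table, and per-group summaries.

    ``pairwise`` has one row per unordered group pair with columns
    (group_a, group_b, mean_diff, q, p_adj, significant_05,
    significant_01); ``degenerate`` flags a zero within-group variance
    with unequal means (F reported as inf, p as 0).
    """

    f_statistic: float
    anova_p: float
    pairwise: pd.DataFrame
    group_means: Dict[str, float]
    group_sds: Dict[str, float]
    degenerate: bool = False

    def summary(self) -> str:
        """Human-readable report with the figure-style significance marks."""
        lines = [f"one-way ANOVA: F = {self.f_statistic:.4g}, p = {self.anova_p:.4g}"]
        for name in self.group_means:
            lines.append(f"  {name}: mean = {self.group_means[name]:.4f} "
                         f"± {self.group_sds[name]:.4f} (SD)")
        for _, row in self.pairwise.iterrows():
            stars = "**" if row.p_adj < 0.01 else ("*" if row.p_adj < 0.05 else "ns")
            lines.append(f"  {row.group_a} vs {row.group_b}: "
                         f"Δ = {row.mean_diff:+.4f}, q = {row.q:.3f}, "
                         f"p_adj = {row.p_adj:.4g} {stars}")
        return "\n".join(lines)


def _mean_squares(arrs: Dict[str, np.ndarray]) -> tuple[float, float, int, int]:
    """(MS_between, MS_within, df_between, df_within) by sums of squares."""
    allv = np.concatenate(list(arrs.values()))
    grand = allv.mean()
    k = len(arrs)
    n_total = allv.size
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrs.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrs.values())
    return (ss_between / (k - 1), ss_within / (n_total - k), k - 1, n_total - k)


def one_way_anova(groups: GroupMeasurements) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA.

    F = MS_between / MS_within on (k-1, N-k) degrees of freedom.  If the
    within-group variance is exactly zero while group means differ, the
    groups are perfectly separated: returns (inf, 0.0).
    """
    arrs = _validate(groups)
    ms_b, ms_w, df_b, df_w = _mean_squares(arrs)
    if ms_w == 0.0:
        if ms_b == 0.0:
            return 0.0, 1.0
        return math.inf, 0.0
    f, p = sps.f_oneway(*arrs.values())
    return float(f), float(p)


def tukey_hsd(groups: GroupMeasurements) -> pd.DataFrame:
    """Tukey's HSD pairwise table (Tukey–Kramer for unequal n).

    For groups i, j: q = |m_i - m_j| / sqrt(MS_within/2 · (1/n_i + 1/n_j));
    the adjusted p is the survival function of the studentized-range
    distribution with k groups and N - k error degrees of freedom.
    """
    arrs = _validate(groups)
    _, ms_w, _, df_w = _mean_squares(arrs)
    k = len(arrs)
    names = list(arrs)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            a, b = arrs[names[i]], arrs[names[j]]
            diff = a.mean() - b.mean()
            if ms_w == 0.0:
                q = math.inf if diff != 0 else 0.0
                p_adj = 0.0 if diff != 0 else 1.0
            else:
                se = math.sqrt(ms_w / 2.0 * (1.0 / a.size + 1.0 / b.size))
                q = abs(diff) / se
                p_adj = float(sps.studentized_range.sf(q, k, df_w))
            rows.append({
                "group_a": names[i], "group_b": names[j],
                "mean_diff": float(diff), "q": float(q),
                "p_adj": min(max(p_adj, 0.0), 1.0),
                "significant_05": p_adj < 0.05,
                "significant_01": p_adj < 0.01,
            })
    return pd.DataFrame(rows)


def compare_groups(groups: GroupMeasurements) -> ComparisonResult:
    """Full comparison: ANOVA, Tukey table, group means and SDs."""
    arrs = _validate(groups)
    f, p = one_way_anova(groups)
    table = tukey_hsd(groups)
    return ComparisonResult(
        f_statistic=f,
        anova_p=p,
        pairwise=table,
        group_means={n: float(a.mean()) for n, a in arrs.items()},
        group_sds={n: float(a.std(ddof=1)) for n, a in arrs.items()},
        degenerate=math.isinf(f),
    )
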