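"""Between-group comparison of motility metrics.

Groups (treatment, stage, shape class …) are compared per metric with the
two-sided Mann-Whitney U test, each track counting as one statistical
unit.  Significance stars follow the convention

    *** p < 0.0001   ** p < 0.01   * p < 0.05   ns otherwise

(note the *** cut at 1e-4, stricter than the common 1e-3).  No
multiple-testing correction is applied to the primary p-values; a
Holm-adjusted column is emitted alongside for transparency.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class GroupComparison:
    metric_name: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    stars: str


@dataclass(frozen=True)
class ComparisonDesign:
    """What to compare: one grouping column, its contrasts, the metrics.

    ``contrasts`` is a sequence of (level_a, level_b) pairs drawn from
    ``group_column``; empty means all unordered level pairs.
    """

    group_column: str
    metrics: tuple[str, ...] = ("velocity_um_min", "md_um", "mi")
    contrasts: tuple[tuple[str, str], ...] = ()


def mann_whitney(sample_a, sample_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (tie-corrected); returns (U_a, p).

    The exact null distribution is enumerated when both samples are small
    (min n ≤ 8) and tie-free; otherwise the tie-corrected normal
    approximation (with continuity correction) is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("both samples must contain at least one value")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def significance_stars(p: float) -> str:
    """Map a p-value to the star label used in the figures."""
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    if p < 0.0001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_design(table: pd.DataFrame,
                   design: ComparisonDesign) -> pd.DataFrame:
    """Run every (metric × contrast) Mann-Whitney comparison of a design.

    Tracks are pooled per group level; empty groups cause the comparison
    to be skipped with a warning, not an error.  Output rows are ordered
    by (metric, contrast) as given, with Holm-adjusted p-values attached.
    """
    if design.group_column not in table.columns:
        raise ValueError(f"missing grouping column {design.group_column!r}")
    contrasts = design.contrasts
    if not contrasts:
        levels = sorted(table[design.group_column].dropna().unique())
        contrasts = tuple(itertools.combinations(levels, 2))

    comparisons: list[GroupComparison] = []
    for metric in design.metrics:
        if metric not in table.columns:
            raise ValueError(f"missing metric column {metric!r}")
        for ga, gb in contrasts:
            a = table.loc[table[design.group_column] == ga, metric].dropna()
            b = table.loc[table[design.group_column] == gb, metric].dropna()
            if len(a) == 0 or len(b) == 0:
                warnings.warn(
                    f"skipping {metric} {ga} vs {gb}: empty group",
                    stacklevel=2)
                continue
            u, p = mann_whitney(a, b)
            comparisons.append(GroupComparison(
                metric_name=metric, group_a=str(ga), group_b=str(gb),
                n_a=len(a), n_b=len(b), u_statistic=u, p_value=p,
                stars=significance_stars(p)))

    out = pd.DataFrame([c.__dict__ for c in comparisons])
    if len(out):
        out["p_holm"] = _holm(out["p_value"].to_numpy())
    return out


def _holm(p: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj
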