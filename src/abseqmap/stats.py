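"""Group-comparison statistics for pairwise repertoire features.

Pairwise feature values (usage correlations, Jaccard overlaps) grouped by
category (same/different donor, sequencing method, isotype, ...) are
compared with a Kruskal-Wallis global test followed by all pairwise
two-sided Wilcoxon rank-sum tests, Bonferroni-adjusted. Each pair of
samples is treated as an independent observation — a known
pseudo-replication that is standard practice for these features and is
documented rather than corrected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_groups", "bonferroni"]

SIGNIFICANCE_THRESHOLD = 0.05


def bonferroni(p: float, m: int) -> float:
    """Bonferroni adjustment: min(1, m * p)."""
    return min(1.0, p * m)


@dataclass
class GroupComparison:
    """Kruskal-Wallis global test plus Bonferroni-adjusted pairwise
    rank-sum tests over labelled value groups."""

    groups: dict[str, np.ndarray]
    global_p: float
    pairwise_raw: pd.DataFrame
    pairwise_adjusted: pd.DataFrame
    n_tests: int

    @property
    def medians(self) -> dict[str, float]:
        return {k: float(np.median(v)) for k, v in self.groups.items()}

    @property
    def group_sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.groups.items()}

    def significant_pairs(self, threshold: float = SIGNIFICANCE_THRESHOLD):
        out = []
        labels = list(self.groups)
        for a, b in itertools.combinations(labels, 2):
            if self.pairwise_adjusted.loc[a, b] < threshold:
                out.append((a, b))
        return out

    def summary(self) -> pd.DataFrame:
        rows = [
            {"group": k, "n": len(v), "median": float(np.median(v))}
            for k, v in self.groups.items()
        ]
        return pd.DataFrame(rows, columns=["group", "n", "median"])


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p.

    Exact distribution when both groups are small (<= 25) and tie-free,
    normal approximation with tie correction otherwise.
    """
    combined = np.concatenate([x, y])
    if np.ptp(combined) == 0:
        return 1.0  # every value tied: the rank-sum statistic is degenerate
    ties = len(np.unique(combined)) < len(x) + len(y)
    if len(x) <= 25 and len(y) <= 25 and not ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def compare_groups(values, groups) -> GroupComparison:
    """Compare labelled value groups.

    ``values`` and ``groups`` are parallel sequences (a value and its group
    label). Requires at least two groups, each non-empty.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(groups)
    if len(values) != len(labels):
        raise ValueError("values and groups must have equal length")
    by_group: dict[str, np.ndarray] = {}
    for g in pd.unique(labels):
        by_group[str(g)] = values[labels == g]
    if len(by_group) < 2:
        raise ValueError("need at least two groups")
    if any(len(v) == 0 for v in by_group.values()):
        raise ValueError("every group needs at least one value")

    arrays = list(by_group.values())
    if np.ptp(values) == 0:
        global_p = 1.0  # all values tied: no evidence of any difference
    else:
        global_p = float(sps.kruskal(*arrays).pvalue)

    names = list(by_group)
    m = len(names) * (len(names) - 1) // 2
    raw = pd.DataFrame(np.nan, index=names, columns=names)
    adj = pd.DataFrame(np.nan, index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        p = _rank_sum_p(by_group[a], by_group[b])
        raw.loc[a, b] = raw.loc[b, a] = p
        adj.loc[a, b] = adj.loc[b, a] = bonferroni(p, m)
    return GroupComparison(
        groups=by_group,
        global_p=global_p,
        pairwise_raw=raw,
        pairwise_adjusted=adj,
        n_tests=m,
    )
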