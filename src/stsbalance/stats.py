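"""Exact nonparametric group comparisons for small cohorts.

Group sizes in sit-to-stand studies are small (here 10 vs 8), so the
rank tests use the exact permutation null distribution of the rank-sum
statistic, computed by dynamic programming over the (mid)rank multiset,
whenever each group has at most 25 members; beyond that a normal
approximation with tie correction is used.  Two-sided p-values are
``P(|W - E[W]| >= |w_obs - E[W]|)`` under the exact null, which gives
p = 1 for identical groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

EXACT_LIMIT = 25


def _midranks(values: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    values = np.asarray(values, float)
    order = np.argsort(values, kind="mergesort")
    ranks = np.empty(len(values))
    sorted_v = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_v[j + 1] == sorted_v[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _subset_sum_distribution(weights: np.ndarray, k: int) -> np.ndarray:
    """Counts of subsets of size k by total weight (integer weights)."""
    total = int(weights.sum())
    table = np.zeros((k + 1, total + 1))
    table[0, 0] = 1.0
    for w in weights:
        w = int(w)
        for kk in range(k, 0, -1):  # descending so each item is used once
            table[kk, w:] += table[kk - 1, :-w or None]
    return table[k]


def rank_sum_test(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact by enumeration of the rank-sum null for groups of at most
    ``EXACT_LIMIT``; normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    w_obs = ranks[:len(x)].sum()
    n1, n = len(x), len(pooled)
    if max(len(x), len(y)) <= EXACT_LIMIT:
        weights = np.round(2.0 * ranks).astype(int)  # doubled midranks are ints
        counts = _subset_sum_distribution(weights, n1)
        sums = np.arange(counts.size)
        e = n1 * weights.mean()
        dev = abs(2.0 * w_obs - e)
        p = counts[np.abs(sums - e) >= dev - 1e-9].sum() / counts.sum()
        return float(min(1.0, p))
    e = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / ((n - 1) * n)
    var = n1 * (n - n1) / 12.0 * (n + 1 - tie_term)
    z = (w_obs - e) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


def signed_rank_test(x, y=None) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired data.

    Pass paired samples ``(x, y)`` or a single array of differences.
    Zero differences are dropped; an all-zero sample is an error.
    Exact sign-enumeration null (DP) up to ``EXACT_LIMIT`` pairs.
    """
    d = np.asarray(x, float) if y is None else np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are tied at zero")
    ranks = _midranks(np.abs(d))
    w_pos = ranks[d > 0].sum()
    n = d.size
    if n <= EXACT_LIMIT:
        weights = np.round(2.0 * ranks).astype(int)
        total = int(weights.sum())
        counts = np.zeros(total + 1)
        counts[0] = 1.0
        for w in weights:
            shifted = np.zeros_like(counts)
            shifted[w:] = counts[:-w or None]
            counts = counts + shifted
        sums = np.arange(counts.size)
        e = total / 2.0
        dev = abs(2.0 * w_pos - e)
        p = counts[np.abs(sums - e) >= dev - 1e-9].sum() / counts.sum()
        return float(min(1.0, p))
    e = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    z = (w_pos - e) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))


@dataclass
class GroupComparison:
    """Median/IQR summary and p-value of one metric's group contrast."""

    metric: str
    design: str  # "unpaired" | "paired"
    group_a: str
    group_b: str
    median_a: float
    median_b: float
    iqr_a: tuple
    iqr_b: tuple
    p: float
    n_a: int
    n_b: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p < self.alpha

    @property
    def median_difference(self) -> float:
        """median_a - median_b (a minus b)."""
        return self.median_a - self.median_b


def _summary(vals: np.ndarray):
    q = np.percentile(vals, [25, 50, 75])
    return float(q[1]), (float(q[0]), float(q[2]))


def compare_groups(table: pd.DataFrame, design: str = "unpaired") -> list:
    """Group comparisons of per-participant metric values.

    ``table`` is tidy with columns participant, group, condition,
    metric, value (one row per participant after aggregation over
    repetitions).  Unpaired: young vs old per metric and condition.
    Paired: condition contrast per metric and group, matched on
    participant.
    """
    out = []
    if design == "unpaired":
        for (cond, metric), sub in table.groupby(["condition", "metric"], sort=True):
            groups = sorted(sub["group"].unique())
            if len(groups) != 2:
                continue
            a = sub.loc[sub["group"] == groups[0], "value"].to_numpy()
            b = sub.loc[sub["group"] == groups[1], "value"].to_numpy()
            if len(a) < 2 or len(b) < 2:
                continue
            med_a, iqr_a = _summary(a)
            med_b, iqr_b = _summary(b)
            out.append(GroupComparison(
                metric=metric, design=design, group_a=groups[0], group_b=groups[1],
                median_a=med_a, median_b=med_b, iqr_a=iqr_a, iqr_b=iqr_b,
                p=rank_sum_test(a, b), n_a=len(a), n_b=len(b)))
    elif design == "paired":
        for (grp, metric), sub in table.groupby(["group", "metric"], sort=True):
            conds = sorted(sub["condition"].unique())
            if len(conds) != 2:
                continue
            wide = sub.pivot_table(index="participant", columns="condition",
                                   values="value").dropna()
            if len(wide) < 2:
                continue
            a = wide[conds[0]].to_numpy()
            b = wide[conds[1]].to_numpy()
            med_a, iqr_a = _summary(a)
            med_b, iqr_b = _summary(b)
            out.append(GroupComparison(
                metric=f"{metric}[{grp}]", design=design,
                group_a=conds[0], group_b=conds[1],
                median_a=med_a, median_b=med_b, iqr_a=iqr_a, iqr_b=iqr_b,
                p=signed_rank_test(a, b), n_a=len(a), n_b=len(b)))
    else:
        raise ValueError("design must be 'unpaired' or 'paired'")
    return out
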