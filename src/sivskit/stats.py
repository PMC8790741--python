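"""Exact small-sample Wilcoxon rank-sum tests and replicate aggregation.

Studies of this kind compare a per-animal summary statistic between cell
subsets with only a handful of animals per group, where the normal
approximation to the rank-sum distribution is poor.  ``wilcoxon_exact``
therefore computes the exact two-sided p-value by enumerating the null
distribution of the rank sum over all C(n+m, n) equally likely rank
assignments whenever both groups have at most ``EXACT_MAX`` observations,
with midranks for ties; larger groups fall back to the tie-corrected
normal approximation with continuity correction.  Two-sidedness follows
the tail-doubling convention: p = min(1, 2 * min(P(W <= w), P(W >= w))).

Technical replicates are averaged per animal before testing, and the mean
and standard error of the mean across replicates are reported.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Exact enumeration is used whenever both group sizes are <= this bound.
EXACT_MAX = 8


@dataclass(frozen=True)
class GroupComparison:
    """Rank-sum comparison of two groups of per-animal values."""

    group_x: str
    group_y: str
    x: tuple[float, ...]
    y: tuple[float, ...]
    rank_sum_x: float
    p_value: float
    method: str  # "exact" or "normal"
    degenerate: bool = False


@dataclass(frozen=True)
class ReplicateAggregate:
    """Mean and SEM across technical replicates; SEM is undefined (None),
    not zero, for a single replicate."""

    mean: float
    sem: float | None
    n: int


def _rank_sum_distribution(doubled_ranks: np.ndarray, n_x: int) -> np.ndarray:
    """Number of n_x-subsets of the ranks attaining each doubled rank sum.

    Dynamic program over items: dp[k, s] = number of k-subsets with doubled
    rank sum s.  Midranks are half-integers, so doubling makes every sum an
    exact integer and the enumeration is free of floating-point comparison
    error.
    """
    total = int(doubled_ranks.sum())
    dp = np.zeros((n_x + 1, total + 1))
    dp[0, 0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        for k in range(n_x, 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    return dp[n_x]


def wilcoxon_exact(
    x: Sequence[float],
    y: Sequence[float],
    group_x: str = "x",
    group_y: str = "y",
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test, exact for small groups.

    Midranks handle ties; the exact branch enumerates the permutation
    distribution of the rank sum of ``x`` via a subset-sum dynamic program
    (equivalent to full enumeration of all C(n+m, n) assignments).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    w = float(ranks[:n].sum())

    if np.all(pooled == pooled[0]):
        return GroupComparison(
            group_x, group_y, tuple(x), tuple(y), w, 1.0, "exact", degenerate=True
        )

    if n <= EXACT_MAX and m <= EXACT_MAX:
        doubled = np.rint(2 * ranks).astype(np.int64)
        counts = _rank_sum_distribution(doubled, n)
        total = counts.sum()
        w2 = int(round(2 * w))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return GroupComparison(group_x, group_y, tuple(x), tuple(y), w, p, "exact")

    # tie-corrected normal approximation with continuity correction
    total_n = n + m
    mu = n * (total_n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (total_n * (total_n - 1))
    var = n * m / 12.0 * ((total_n + 1) - tie_term)
    if var <= 0:
        return GroupComparison(
            group_x, group_y, tuple(x), tuple(y), w, 1.0, "normal", degenerate=True
        )
    z = (w - mu - math.copysign(0.5, w - mu)) / math.sqrt(var) if w != mu else 0.0
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return GroupComparison(group_x, group_y, tuple(x), tuple(y), w, p, "normal")


def wilcoxon_enumeration_oracle(x: Sequence[float], y: Sequence[float]) -> float:
    """Brute-force oracle: explicitly enumerate every assignment of the
    pooled midranks into a group of size len(x) and sum the probabilities of
    rank sums at least as extreme as observed (tail-doubling, capped at 1).

    Independent of ``wilcoxon_exact``'s dynamic program; for tests only.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ranks = sps.rankdata(np.concatenate([x, y]))
    n = x.size
    w_obs = ranks[:n].sum()
    sums = np.array([sum(c) for c in combinations(ranks, n)])
    eps = 1e-9
    p_le = np.mean(sums <= w_obs + eps)
    p_ge = np.mean(sums >= w_obs - eps)
    return min(1.0, 2.0 * min(p_le, p_ge))


def aggregate_technical_replicates(values: Sequence[float]) -> ReplicateAggregate:
    """Mean and standard error of the mean across technical replicates."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("at least one replicate value required")
    if v.size == 1:
        return ReplicateAggregate(mean=float(v[0]), sem=None, n=1)
    sem = float(np.std(v, ddof=1) / math.sqrt(v.size))
    return ReplicateAggregate(mean=float(v.mean()), sem=sem, n=int(v.size))


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment (optional; pairwise p-values are reported
    unadjusted by default, matching common practice for three subset
    pairs)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    k = p.size
    adjusted = np.empty(k)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (k - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted.tolist()


def compare_subsets(
    summaries: pd.DataFrame,
    metric: str,
    subset_pair: tuple[str, str],
    subset_col: str = "subset",
    animal_col: str = "animal",
) -> GroupComparison:
    """Rank-sum comparison of a summary metric between two subsets, with
    animals as biological replicates.

    ``summaries`` holds one row per animal x subset (or per technical
    replicate thereof; replicates are averaged per animal first).  Animals
    with the metric undefined (NaN) are dropped and logged.
    """
    sx, sy = subset_pair
    groups: dict[str, list[float]] = {}
    for name in subset_pair:
        rows = summaries[summaries[subset_col] == name]
        per_animal = []
        for animal, sub in rows.groupby(animal_col):
            vals = sub[metric].dropna().to_numpy(dtype=float)
            if vals.size == 0:
                logger.info(
                    "compare_subsets: animal %s has no defined %r for subset %s; dropped",
                    animal, metric, name,
                )
                continue
            per_animal.append(aggregate_technical_replicates(vals).mean)
        if len(per_animal) < 2:
            raise ValueError(
                f"subset {name!r} has fewer than 2 animals with {metric!r} defined"
            )
        groups[name] = per_animal
    return wilcoxon_exact(groups[sx], groups[sy], group_x=sx, group_y=sy)
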