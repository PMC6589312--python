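"""Nonparametric comparison statistics for grade-vs-measurement analyses.

Spearman rank correlation relates an ordinal response (e.g. an ensemble's
grade) to a continuous measurement (vessel-area percentage); the
Kruskal–Wallis test asks whether the measurement differs across grades at
all; the Steel–Dwass procedure locates which grade pairs differ, holding
the familywise error rate by referring each standardised pairwise
rank-sum statistic to the studentized-range distribution.

Steel–Dwass has no scipy implementation, so the pairwise statistic is
computed here directly: for groups i and j, midrank the combined sample,
take the rank sum of group i, centre by n_i (N + 1) / 2 and scale by the
tie-corrected variance n_i n_j / (N (N - 1)) * (sum r^2 - N (N+1)^2 / 4);
the two-sided p-value refers sqrt(2) |t| to the studentized range with k
groups and infinite degrees of freedom.  A Monte-Carlo permutation mode
(max-statistic adjusted: relabel the full dataset, compare each observed
|t| to the permutation distribution of the maximum pairwise |t|) serves
as a distribution-free cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatsError",
    "PairwiseComparison",
    "spearman",
    "kruskal_wallis",
    "steel_dwass",
]


class StatsError(ValueError):
    """Statistic undefined on the given data."""


@dataclass(frozen=True)
class PairwiseComparison:
    group_a: int
    group_b: int
    statistic: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise StatsError(f"p-value {self.p_value} outside [0, 1]")


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with midranks for ties.

    Returns (rho, p) with p from the large-sample approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise StatsError("need two equal-length vectors of at least 3 values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise StatsError("constant input vector: rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with a chi-square reference."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise StatsError("need at least 2 non-empty groups")
    if sum(len(g) for g in groups) < 3:
        raise StatsError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise StatsError("degenerate: all observations identical")
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def _pairwise_t(gi: np.ndarray, gj: np.ndarray) -> float:
    """Standardised tie-corrected rank-sum statistic for one group pair."""
    ni, nj = len(gi), len(gj)
    n = ni + nj
    ranks = sps.rankdata(np.concatenate([gi, gj]))
    r_i = ranks[:ni].sum()
    expected = ni * (n + 1) / 2.0
    var = ni * nj / (n * (n - 1.0)) * ((ranks**2).sum() - n * (n + 1.0) ** 2 / 4.0)
    if var <= 0:
        return 0.0
    return float((r_i - expected) / np.sqrt(var))


def steel_dwass(
    groups: Sequence[Sequence[float]],
    method: str = "analytic",
    n_permutations: int = 2000,
    seed: int | None = None,
) -> list[PairwiseComparison]:
    """All-pairs Steel–Dwass comparisons.

    ``method="analytic"`` refers sqrt(2)|t| to the studentized-range
    distribution with k groups (infinite df).  ``method="permutation"``
    estimates each pairwise p by Monte-Carlo relabelling of the full
    dataset with the max-statistic familywise adjustment.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 3 or any(len(g) < 2 for g in groups):
        raise StatsError("need at least 3 groups with at least 2 observations each")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        raise StatsError("degenerate: all observations identical")

    pairs = list(combinations(range(k), 2))
    t_obs = {(i, j): _pairwise_t(groups[i], groups[j]) for i, j in pairs}

    out: list[PairwiseComparison] = []
    if method == "analytic":
        for i, j in pairs:
            t = t_obs[(i, j)]
            p = float(sps.studentized_range.sf(np.sqrt(2.0) * abs(t), k, np.inf))
            out.append(PairwiseComparison(i, j, t, min(p, 1.0), "analytic"))
        return out
    if method != "permutation":
        raise StatsError(f"unknown method {method!r}")

    rng = np.random.default_rng(seed)
    sizes = [len(g) for g in groups]
    edges = np.cumsum([0, *sizes])
    max_null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(pooled)
        regrouped = [perm[edges[m] : edges[m + 1]] for m in range(k)]
        max_null[b] = max(
            abs(_pairwise_t(regrouped[i], regrouped[j])) for i, j in pairs
        )
    for i, j in pairs:
        t = t_obs[(i, j)]
        p = float((1 + np.sum(max_null >= abs(t))) / (1 + n_permutations))
        out.append(PairwiseComparison(i, j, t, min(p, 1.0), "permutation"))
    return out
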