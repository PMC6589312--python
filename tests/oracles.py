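"""Independent brute-force oracles used across the test suite.

These are deliberately naive re-derivations (explicit contingency tables,
double loops) kept separate from the package's computation paths.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def contingency_kappa(a, b, n_categories: int = 4) -> float:
    """Quadratic-weighted kappa from an explicitly built contingency table."""
    a = list(a)
    b = list(b)
    n = len(a)
    obs = [[0.0] * n_categories for _ in range(n_categories)]
    for x, y in zip(a, b):
        obs[x][y] += 1.0 / n
    row = [sum(obs[i][j] for j in range(n_categories)) for i in range(n_categories)]
    col = [sum(obs[i][j] for i in range(n_categories)) for j in range(n_categories)]
    num = den = 0.0
    for i in range(n_categories):
        for j in range(n_categories):
            w = (i - j) ** 2 / (n_categories - 1) ** 2
            num += w * obs[i][j]
            den += w * row[i] * col[j]
    return 1.0 - num / den


def rank_by_hand(values) -> list[float]:
    """Midranks computed by explicit enumeration."""
    values = list(values)
    ranks = []
    for v in values:
        less = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        ranks.append(less + (equal + 1) / 2.0)
    return ranks


def kruskal_by_hand(groups) -> float:
    """Tie-corrected Kruskal-Wallis H from hand-built ranks."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    ranks = rank_by_hand(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = sum(ranks[start : start + len(g)])
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    ties = 0.0
    for v in set(pooled):
        t = pooled.count(v)
        ties += t**3 - t
    correction = 1.0 - ties / (n**3 - n)
    return h / correction


def exact_pairwise_permutation_p(gi, gj, k_groups: int) -> float:
    """Exact permutation p for one Steel-Dwass pair (no max adjustment).

    Enumerates every split of the combined sample; usable only for tiny
    groups.  Refers the observed |standardised rank sum| to the exhaustive
    relabelling distribution of the same statistic.
    """

    def stat(idx_i, pooled):
        ni = len(idx_i)
        n = len(pooled)
        ranks = rank_by_hand(pooled)
        r_i = sum(ranks[i] for i in idx_i)
        expected = ni * (n + 1) / 2.0
        var = (
            ni
            * (n - ni)
            / (n * (n - 1.0))
            * (sum(r * r for r in ranks) - n * (n + 1.0) ** 2 / 4.0)
        )
        return abs((r_i - expected) / np.sqrt(var))

    pooled = list(gi) + list(gj)
    ni = len(gi)
    observed = stat(list(range(ni)), pooled)
    count = total = 0
    for idx in combinations(range(len(pooled)), ni):
        total += 1
        if stat(list(idx), pooled) >= observed - 1e-12:
            count += 1
    return count / total
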