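"""Shared fixtures and independent statistical oracles.

The oracles deliberately avoid the package's own code paths (and scipy):
CLES and U by explicit pair counting, exact Mann-Whitney p-values by
enumeration of group assignments, and the tie-free null distribution of
the rank sum by dynamic programming.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pytest

from cgdscan import DriverGeneSpec, TargetLabel
from cgdscan.synth import PlantedDependency, make_truth


# -- independent oracles --------------------------------------------------

def oracle_u_cles(altered, wildtype):
    """U (altered-beats-wildtype pairs, ties 1/2) and CLES by pair counting."""
    u = 0.0
    for a in altered:
        for w in wildtype:
            if a < w:
                u += 1.0
            elif a == w:
                u += 0.5
    return u, u / (len(altered) * len(wildtype))


def oracle_exact_p(altered, wildtype):
    """One-sided exact p by enumerating all group assignments.

    p = fraction of the C(n1+n2, n1) equally likely assignments whose U is
    at least the observed U (larger U = more extreme evidence that the
    altered group is smaller).
    """
    pooled = list(altered) + list(wildtype)
    n1 = len(altered)
    u_obs, _ = oracle_u_cles(altered, wildtype)
    n_extreme = 0
    n_total = 0
    for idx in combinations(range(len(pooled)), n1):
        group_a = [pooled[i] for i in idx]
        group_w = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        u, _ = oracle_u_cles(group_a, group_w)
        n_total += 1
        if u >= u_obs - 1e-9:
            n_extreme += 1
    return n_extreme / n_total


def ranksum_counts(n1: int, n2: int) -> dict[int, int]:
    """Number of size-n1 subsets of ranks 1..n1+n2 per rank sum (DP)."""
    n = n1 + n2
    # f[k][s]: subsets of {1..r} with k elements summing to s
    f = [{0: 1}] + [dict() for _ in range(n1)]
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            for s, c in list(f[k - 1].items()):
                f[k][s + r] = f[k].get(s + r, 0) + c
    return f[n1]


def exact_null_p_of_u(u: float, n1: int, n2: int) -> float:
    """P(U >= u) under the tie-free null, from the rank-sum distribution.

    U = n1*n2 - (R1 - n1(n1+1)/2), so U >= u iff R1 <= n1*n2 + n1(n1+1)/2 - u.
    """
    counts = ranksum_counts(n1, n2)
    bound = n1 * n2 + n1 * (n1 + 1) / 2 - u
    hits = sum(c for s, c in counts.items() if s <= bound + 1e-9)
    return hits / comb(n1 + n2, n1)


def joint_null_rate(n1: int, n2: int, p_max: float, cles_min: float) -> float:
    """Exact null probability of {p < p_max and CLES >= cles_min} (tie-free)."""
    counts = ranksum_counts(n1, n2)
    total = comb(n1 + n2, n1)
    rate = 0
    for s, c in counts.items():
        u = n1 * n2 + n1 * (n1 + 1) / 2 - s
        if u / (n1 * n2) >= cles_min and exact_null_p_of_u(u, n1, n2) < p_max:
            rate += c
    return rate / total


# -- shared fixtures ------------------------------------------------------

@pytest.fixture
def ts_driver():
    return DriverGeneSpec(TargetLabel("DRV1", 9001), "tumor_suppressor", "both")


@pytest.fixture
def planted_truth(ts_driver):
    """10 altered / 20 wild-type lines, one planted -2 shift dependency."""
    target = TargetLabel("TGT1", 9101)
    return make_truth(
        n_cell_lines=30,
        drivers=[ts_driver],
        n_altered=10,
        planted=[PlantedDependency(ts_driver, target, -2.0)],
        seed=11,
    )
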