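"""Classical tests used in the retrogene analyses.

Thin, explicit wrappers around the standard implementations: Fisher's exact
test (2x2, two-sided), Pearson's chi-square (2x2, one degree of freedom) and
the Mann-Whitney U test.  Mann-Whitney switches to full enumeration of the
permutation distribution when the product of sample sizes is small enough
that the normal approximation is questionable.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "fisher_exact",
    "chi_square_2x2",
    "mann_whitney_u",
]

#: below this n1*n2 the Mann-Whitney p-value is computed by enumeration
EXACT_MWU_MAX_PRODUCT = 400


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of a 2x2 contingency table, rows = groups, columns = outcomes."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in counts):
            raise ValueError("counts must be non-negative integers")
        if sum(counts) == 0:
            raise ValueError("table total must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def _as_table(table) -> ContingencyTable2x2:
    if isinstance(table, ContingencyTable2x2):
        return table
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    return ContingencyTable2x2(*(int(x) for x in arr.ravel()))


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Two-sided by the common "sum of all tables at least as improbable as the
    observed one" convention.  A table with a zero margin carries no
    information about association; p = 1 by convention.
    """
    t = _as_table(table)
    arr = t.as_array()
    if 0 in arr.sum(axis=0) or 0 in arr.sum(axis=1):
        return 1.0
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    return float(min(p, 1.0))


def chi_square_2x2(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square statistic and upper-tail p (1 df) for a 2x2 table.

    No continuity correction by default.  Raises on a zero margin (expected
    counts would be zero).
    """
    t = _as_table(table)
    arr = t.as_array()
    if 0 in arr.sum(axis=0) or 0 in arr.sum(axis=1):
        raise ValueError("chi-square undefined for a table with a zero margin")
    statistic, p, _, _ = stats.chi2_contingency(arr, correction=yates)
    return float(statistic), float(p)


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x, with the midrank convention for ties."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def _exact_mwu_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p by enumerating every assignment of pooled values to groups."""
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    observed = _u_statistic(x, y)
    n = len(pooled)
    mean_u = n1 * (n - n1) / 2.0
    obs_dev = abs(observed - mean_u)
    hits = 0
    total = 0
    offset = n1 * (n1 + 1) / 2.0
    for combo in itertools.combinations(range(n), n1):
        u = ranks[list(combo)].sum() - offset
        if abs(u - mean_u) >= obs_dev - 1e-9:
            hits += 1
        total += 1
    return hits / total


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U (for the first sample) and a two-sided p-value.

    Uses full permutation enumeration when ``len(x) * len(y)`` <=
    :data:`EXACT_MWU_MAX_PRODUCT`, otherwise the normal approximation with
    tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    if len(x) * len(y) <= EXACT_MWU_MAX_PRODUCT:
        p = _exact_mwu_p(x, y)
    else:
        _, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(p)
    return u, min(p, 1.0)
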