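"""Tally statistics: 2x2 tables, exact Fisher tests, proportion z-tests.

The Fisher test is computed from first principles by exact enumeration of
the hypergeometric support at fixed margins, using integer binomial weights
(no floating-point probabilities enter the tail decision, and no asymptotic
approximation is used).  The two-sided p-value follows the
minimum-likelihood convention: the sum of probabilities of all tables whose
point probability does not exceed that of the observed table, with a 1e-7
relative slack on the comparison to absorb representation ties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable, Iterable, Sequence

from scipy.stats import norm

from swapmeta.dataset import SwapExperiment

#: relative slack on the "point probability <= observed" comparison
_REL_TOL = 1e-7
# integer form: w <= w_obs * (1 + 1e-7)  <=>  (w - w_obs) * 10^7 <= w_obs
_TOL_NUM, _TOL_DEN = 1, 10**7


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Labeled 2x2 tally table ``[[a, b], [c, d]]``."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise StatsError("tally cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_list(self) -> list[list[int]]:
        return [[self.a, self.b], [self.c, self.d]]

    @property
    def degenerate(self) -> bool:
        """A zero row or zero column margin (test is uninformative)."""
        return (self.a + self.b == 0 or self.c + self.d == 0
                or self.a + self.c == 0 or self.b + self.d == 0)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a tally test; ``statistic`` is None for exact tests."""

    p_value: float
    sidedness: str
    method: str
    statistic: float | None = None
    degenerate: bool = False

    def __post_init__(self):
        if not (0.0 < self.p_value <= 1.0):
            raise StatsError(f"p-value {self.p_value} outside (0, 1]")


# ---------------------------------------------------------------------------
# Table construction
# ---------------------------------------------------------------------------

Factor = tuple[str, tuple[str, str], Callable[[SwapExperiment], str | None]]
"""A binary factor: (name, (level1, level2), experiment -> level or None)."""


def tabulate(experiments: Iterable[SwapExperiment], row_factor: Factor,
             col_factor: Factor) -> ContingencyTable2x2:
    """Cross-tabulate two binary factors over the given experiments.

    Every experiment must evaluate to one of the two levels of each factor;
    an experiment falling outside a factor's levels raises, naming it
    (pre-filter the input to the union of the strata being compared).
    """
    row_name, row_levels, row_fn = row_factor
    col_name, col_levels, col_fn = col_factor
    cells = {(r, c): 0 for r in row_levels for c in col_levels}
    for e in experiments:
        r, c = row_fn(e), col_fn(e)
        if r not in row_levels:
            raise StatsError(
                f"experiment {e.id}: factor {row_name!r} evaluated to "
                f"{r!r}, not one of {row_levels}")
        if c not in col_levels:
            raise StatsError(
                f"experiment {e.id}: factor {col_name!r} evaluated to "
                f"{c!r}, not one of {col_levels}")
        cells[(r, c)] += 1
    return ContingencyTable2x2(
        a=cells[(row_levels[0], col_levels[0])],
        b=cells[(row_levels[0], col_levels[1])],
        c=cells[(row_levels[1], col_levels[0])],
        d=cells[(row_levels[1], col_levels[1])],
        row_labels=row_levels, col_labels=col_levels)


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------

def _support_weights(table: ContingencyTable2x2) -> tuple[range, list[int], int]:
    """Integer hypergeometric weights over the support at fixed margins.

    With row margins (r1, r2) and first-column margin m, cell ``a`` ranges
    over max(0, m - r2) .. min(r1, m) and the point probability of a table
    is proportional to C(r1, a) * C(r2, m - a).
    """
    r1 = table.a + table.b
    r2 = table.c + table.d
    m = table.a + table.c
    lo, hi = max(0, m - r2), min(r1, m)
    support = range(lo, hi + 1)
    weights = [math.comb(r1, a) * math.comb(r2, m - a) for a in support]
    return support, weights, table.a


def fisher_exact_two_sided(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact test (minimum-likelihood convention).

    p = sum over the support of the probabilities of all tables whose point
    probability is <= that of the observed table (within 1e-7 relative
    slack), computed with exact integer arithmetic.  A degenerate margin
    yields p = 1 with the degenerate flag set.
    """
    if table.total < 1:
        raise StatsError("empty table")
    if table.degenerate:
        return TestResult(p_value=1.0, sidedness="two_sided",
                          method="fisher_exact", degenerate=True)
    support, weights, a_obs = _support_weights(table)
    w_obs = weights[a_obs - support.start]
    # w <= w_obs * (1 + 1e-7), kept in exact integers
    in_tail = [w for w in weights
               if w <= w_obs or (w - w_obs) * _TOL_DEN <= w_obs * _TOL_NUM]
    p = Fraction(sum(in_tail), sum(weights))
    return TestResult(p_value=float(p), sidedness="two_sided",
                      method="fisher_exact")


def fisher_exact_one_sided(table: ContingencyTable2x2,
                           alternative: str = "greater") -> TestResult:
    """One-sided Fisher exact test on the (1,1) cell (provided for
    completeness; the meta-analysis report uses the two-sided test)."""
    if table.total < 1:
        raise StatsError("empty table")
    if table.degenerate:
        return TestResult(p_value=1.0, sidedness="one_tailed",
                          method="fisher_exact", degenerate=True)
    support, weights, a_obs = _support_weights(table)
    if alternative == "greater":
        tail = [w for a, w in zip(support, weights) if a >= a_obs]
    elif alternative == "less":
        tail = [w for a, w in zip(support, weights) if a <= a_obs]
    else:
        raise StatsError(f"unknown alternative {alternative!r}")
    p = Fraction(sum(tail), sum(weights))
    return TestResult(p_value=float(p), sidedness="one_tailed",
                      method="fisher_exact")


# ---------------------------------------------------------------------------
# Two-proportion z-test
# ---------------------------------------------------------------------------

def z_test_proportions_one_tailed(x1: int, n1: int, x2: int, n2: int,
                                  direction: str = "greater") -> TestResult:
    """Pooled-variance one-tailed z-test comparing x1/n1 against x2/n2.

    z = (p1 - p2) / sqrt(p (1 - p) (1/n1 + 1/n2)) with p the pooled
    proportion; the p-value is the standard normal upper (``greater``) or
    lower (``less``) tail.  A pooled proportion of 0 or 1 leaves z undefined
    and returns p = 1 with the degenerate flag set.
    """
    if direction not in ("greater", "less"):
        raise StatsError(f"unknown direction {direction!r}")
    if n1 < 1 or n2 < 1:
        raise StatsError("sample sizes must be >= 1")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise StatsError("counts must satisfy 0 <= x <= n")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return TestResult(p_value=1.0, sidedness="one_tailed",
                          method="z_test_proportions", degenerate=True)
    p1, p2 = x1 / n1, x2 / n2
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p = float(norm.sf(z)) if direction == "greater" else float(norm.cdf(z))
    p = min(max(p, 5e-324), 1.0)  # keep within (0, 1]
    return TestResult(p_value=p, sidedness="one_tailed",
                      method="z_test_proportions", statistic=z)


# ---------------------------------------------------------------------------
# Proportions
# ---------------------------------------------------------------------------

def proportion_summary(experiments: Sequence[SwapExperiment],
                       predicate: Callable[[SwapExperiment], bool]
                       ) -> tuple[int, int, float | None]:
    """(count, total, percent) of experiments satisfying the predicate.

    Percent is 100*count/total rounded half-up to one decimal; None when the
    input is empty.
    """
    total = len(experiments)
    count = sum(1 for e in experiments if predicate(e))
    if total == 0:
        return 0, 0, None
    percent = math.floor(1000.0 * count / total + 0.5) / 10.0
    return count, total, percent
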