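"""Exact categorical association tests built on the hypergeometric law.

Fisher's exact test for 2x2 tables, computed in exact rational arithmetic
(so p-values carry no enumeration round-off), plus the directional
gene-co-occurrence wrapper: do two resistance genes occur together in the
same strains more often than chance given their margins?
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np

ALTERNATIVES = ("two-sided", "greater", "less")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows factor-1 yes/no, columns factor-2 yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or v != int(v):
                raise ValueError("counts must be non-negative integers")
        if self.total < 1:
            raise ValueError("table total must be >= 1")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def margins(self):
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def odds_ratio(self) -> float:
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else math.nan
        return (self.a * self.d) / (self.b * self.c)


def _hypergeom_pmf(k: int, t: ContingencyTable2x2) -> Fraction:
    """P(top-left cell = k | margins), as an exact rational."""
    r1, r2, c1, _ = t.margins
    n = t.total
    return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), math.comb(n, c1))


def fisher_exact(t: ContingencyTable2x2, alternative: str = "two-sided"):
    """Fisher's exact test on a 2x2 table.

    Two-sided p sums the conditional probabilities of every table (with
    the same margins) no more probable than the observed one; one-sided
    alternatives sum the tail at least as extreme in the stated
    direction.  A zero margin makes the table degenerate: p = 1.

    Returns
    -------
    (p, odds_ratio) : the p-value and the sample odds ratio ad/bc
        (infinite when bc = 0 < ad; nan when both products vanish).
    """
    if alternative not in ALTERNATIVES:
        raise ValueError(f"alternative must be one of {ALTERNATIVES}")
    r1, r2, c1, c2 = t.margins
    if min(r1, r2, c1, c2) == 0:
        return 1.0, t.odds_ratio()
    lo, hi = max(0, c1 - r2), min(r1, c1)
    p_obs = _hypergeom_pmf(t.a, t)
    if alternative == "greater":
        p = sum(_hypergeom_pmf(k, t) for k in range(t.a, hi + 1))
    elif alternative == "less":
        p = sum(_hypergeom_pmf(k, t) for k in range(lo, t.a + 1))
    else:
        p = sum(
            pk
            for k in range(lo, hi + 1)
            if (pk := _hypergeom_pmf(k, t)) <= p_obs
        )
    return float(min(p, Fraction(1))), t.odds_ratio()


def co_occurrence_test(presence_a, presence_b, alternative: str = "greater"):
    """Test whether two genes co-occur across strains more than chance.

    ``presence_a`` and ``presence_b`` are equal-length 0/1 indicator
    vectors over the same strains.  The default alternative is "greater"
    (toward co-occurrence), the directional reading of "more often
    together than separately"; pass "two-sided" for the neutral test.

    Returns (table, p).
    """
    a = np.asarray(presence_a, dtype=bool)
    b = np.asarray(presence_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("presence vectors must be 1-D and of equal length")
    table = ContingencyTable2x2(
        int(np.sum(a & b)),
        int(np.sum(a & ~b)),
        int(np.sum(~a & b)),
        int(np.sum(~a & ~b)),
    )
    p, _ = fisher_exact(table, alternative)
    return table, p
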