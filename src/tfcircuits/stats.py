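"""Shared exact / nonparametric statistical primitives.

Every downstream screen in the pipeline (per-cohort mutation enrichment,
domain mutation-vs-variant contrast, target differential expression,
target-set overlaps) reduces to one of four primitives: Fisher's exact
test on a 2x2 contingency table, the Mann-Whitney rank-sum test,
Benjamini-Hochberg step-up adjustment, and the Jaccard index.  They are
centralized here with strict input validation so that each stage shares
a single, oracle-tested implementation.

Conventions
-----------
* Two-sided Fisher p uses the point-probability rule: the sum of the
  probabilities of all tables (with the observed margins) whose
  hypergeometric probability does not exceed that of the observed table.
* Mann-Whitney uses the exact permutation null when the pooled sample is
  small (<= 16) and tie-free, and a tie-corrected normal approximation
  with continuity correction otherwise; the path taken is recorded on
  the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "fisher_exact",
    "mann_whitney",
    "benjamini_hochberg",
    "jaccard",
    "overlap_significance",
]

#: largest pooled sample size for which the exact Mann-Whitney null is used
MANN_WHITNEY_EXACT_MAX_N = 16

_ALTERNATIVES = {"two_sided": "two-sided", "greater": "greater", "less": "less"}


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts ``[[a, b], [c, d]]``: row 1 = category of interest
    (inside / outside), row 2 = reference (inside / outside)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"contingency count {name}={v!r} must be a nonnegative integer")
        if self.total == 0:
            raise ValueError("degenerate contingency table: all four counts are zero")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    alternative: str
    method: str  # "exact" or "normal_approx"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def _check_alternative(alternative: str) -> str:
    if alternative not in _ALTERNATIVES:
        raise ValueError(
            f"alternative must be one of {sorted(_ALTERNATIVES)}, got {alternative!r}"
        )
    return _ALTERNATIVES[alternative]


def fisher_exact(
    table: ContingencyTable2x2 | Sequence[Sequence[int]],
    alternative: str = "two_sided",
) -> TestResult:
    """Fisher's exact test on a 2x2 table.

    Returns the odds ratio as the statistic and the exact hypergeometric
    p-value.  ``two_sided`` follows the point-probability convention.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(a, b, c, d)
    scipy_alt = _check_alternative(alternative)
    odds, p = _sps.fisher_exact(table.as_array(), alternative=scipy_alt)
    return TestResult(float(odds), float(min(p, 1.0)), alternative, "exact")


def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
) -> TestResult:
    """Mann-Whitney U test of ``x`` against ``y``.

    The U statistic is for ``x``.  Exact permutation null when the
    pooled sample is tie-free and of size <= 16; otherwise a
    tie-corrected normal approximation with continuity correction.  A
    fully degenerate null (every pooled value identical) returns p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney requires non-empty samples")
    scipy_alt = _check_alternative(alternative)
    pooled = np.concatenate([x, y])
    exact = (pooled.size <= MANN_WHITNEY_EXACT_MAX_N) and not _has_ties(pooled)
    if np.unique(pooled).size == 1:
        # all observations tied: sd(U) = 0, no evidence either way
        return TestResult(x.size * y.size / 2.0, 1.0, alternative, "normal_approx")
    res = _sps.mannwhitneyu(
        x, y, alternative=scipy_alt, method="exact" if exact else "asymptotic"
    )
    return TestResult(
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        alternative,
        "exact" if exact else "normal_approx",
    )


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def jaccard(set_a: Iterable, set_b: Iterable) -> float:
    """Jaccard index |A n B| / |A u B|; 0.0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def overlap_significance(
    set_a: Iterable,
    set_b: Iterable,
    universe: Iterable,
    alternative: str = "greater",
) -> TestResult:
    """Fisher test of the overlap of two sets within a finite universe.

    The table is ``[[|AnB|, |A\\B|], [|B\\A|, |U\\(AuB)|]]``; with
    ``alternative='greater'`` this is the hypergeometric enrichment
    p-value P(overlap >= observed).
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    if not a <= u:
        raise ValueError("set_a is not contained in the universe")
    if not b <= u:
        raise ValueError("set_b is not contained in the universe")
    if not u:
        raise ValueError("empty universe")
    inter = len(a & b)
    table = ContingencyTable2x2(inter, len(a) - inter, len(b) - inter, len(u - (a | b)))
    return fisher_exact(table, alternative=alternative)
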