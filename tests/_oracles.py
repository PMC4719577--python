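"""Independent brute-force oracles used only by the test suite.

These are written from the definitions (exact rational hypergeometric
enumeration, full rank-assignment enumeration, definitional BH step-up)
and deliberately share no code with the package implementation.
"""

from fractions import Fraction
from itertools import combinations
from math import comb


def fisher_oracle(a, b, c, d, alternative="two_sided"):
    """Exact Fisher p by enumeration over all tables with the observed
    margins, in rational arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = comb(n, c1)

    def pmf(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return Fraction(0)
        return Fraction(comb(r1, x) * comb(r2, c1 - x), denom)

    support = range(max(0, c1 - r2), min(r1, c1) + 1)
    if alternative == "greater":
        total = sum(pmf(x) for x in support if x >= a)
    elif alternative == "less":
        total = sum(pmf(x) for x in support if x <= a)
    else:  # point-probability rule
        p0 = pmf(a)
        total = sum(p for x in support if (p := pmf(x)) <= p0)
    return float(min(total, Fraction(1)))


def mann_whitney_u_distribution(n1, n2):
    """Exact null distribution of the U statistic of the first sample:
    {u: count} over all C(n1+n2, n1) rank assignments."""
    counts = {}
    for pos in combinations(range(n1 + n2), n1):
        u = sum(pos) + n1 - n1 * (n1 + 1) // 2  # ranks are pos+1
        counts[u] = counts.get(u, 0) + 1
    return counts, comb(n1 + n2, n1)


def mann_whitney_oracle_p(u, n1, n2, alternative="two_sided"):
    """Exact Mann-Whitney p for an observed tie-free U, from the full
    enumeration of rank assignments."""
    counts, total = mann_whitney_u_distribution(n1, n2)
    p_le = Fraction(sum(v for k, v in counts.items() if k <= u), total)
    p_ge = Fraction(sum(v for k, v in counts.items() if k >= u), total)
    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    else:
        p = min(Fraction(1), 2 * min(p_le, p_ge))
    return float(p)


def bh_oracle(pvals):
    """Definitional BH step-up: q_(i) = min_{j>=i} p_(j) * m / j, input order."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        q[i] = running
    return q
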