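"""Independent brute-force oracles used to check the statistical routines.

Everything here is deliberately naive and self-contained: midranks computed
by explicit sorting, null distributions by full enumeration.  These
routines must never share code with the package implementations they check.
"""

from __future__ import annotations

from itertools import combinations, product
from math import comb, sqrt


def midranks(values):
    """Average ranks (1-based) with ties sharing their mean rank."""
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        average = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = average
        i = j + 1
    return ranks


def pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / sqrt(vx * vy)


def spearman_oracle(x, y):
    """Rank-then-Pearson, the defining construction of Spearman's r."""
    return pearson(midranks(x), midranks(y))


def _two_sided(p_le, p_ge):
    return min(1.0, 2.0 * min(p_le, p_ge))


def signed_rank_enumeration_p(diffs):
    """Exact two-sided signed-rank p by enumerating all 2^n sign patterns
    of the nonzero differences (zeros dropped)."""
    nonzero = [d for d in diffs if d != 0]
    if not nonzero:
        return 1.0
    ranks = midranks([abs(d) for d in nonzero])
    observed = sum(r for r, d in zip(ranks, nonzero) if d > 0)
    n = len(nonzero)
    eps = 1e-9
    n_le = n_ge = 0
    for signs in product((False, True), repeat=n):
        w = sum(r for r, positive in zip(ranks, signs) if positive)
        if w <= observed + eps:
            n_le += 1
        if w >= observed - eps:
            n_ge += 1
    total = 2**n
    return _two_sided(n_le / total, n_ge / total)


def rank_sum_enumeration_p(group_x, group_y):
    """Exact two-sided rank-sum p by enumerating all C(n, n_x) assignments
    of the combined midranks to the first group."""
    combined = list(group_x) + list(group_y)
    ranks = midranks(combined)
    n_x = len(group_x)
    observed = sum(ranks[: n_x])
    eps = 1e-9
    n_le = n_ge = 0
    for subset in combinations(range(len(combined)), n_x):
        w = sum(ranks[i] for i in subset)
        if w <= observed + eps:
            n_le += 1
        if w >= observed - eps:
            n_ge += 1
    total = comb(len(combined), n_x)
    return _two_sided(n_le / total, n_ge / total)
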