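"""Independent reference implementations used only to check the package.

Everything here is deliberately written as plain loops / exhaustive
enumeration, sharing no code with the package under test.
"""

from __future__ import annotations

import math
from itertools import combinations


def topsis_reference(values, directions, weights=None):
    """Step-by-step TOPSIS on a list-of-lists matrix."""
    n_alt = len(values)
    n_crit = len(values[0])
    if weights is None:
        weights = [1.0 / n_crit] * n_crit
    total = sum(weights)
    weights = [w / total for w in weights]

    norm = []
    for j in range(n_crit):
        col = [values[i][j] for i in range(n_alt)]
        denom = math.sqrt(sum(x * x for x in col))
        norm.append([x / denom if denom else 0.0 for x in col])

    weighted = [[norm[j][i] * weights[j] for j in range(n_crit)] for i in range(n_alt)]

    ideal, anti = [], []
    for j in range(n_crit):
        col = [weighted[i][j] for i in range(n_alt)]
        if directions[j] == "benefit":
            ideal.append(max(col))
            anti.append(min(col))
        else:
            ideal.append(min(col))
            anti.append(max(col))

    out = []
    for i in range(n_alt):
        dp = math.sqrt(sum((weighted[i][j] - ideal[j]) ** 2 for j in range(n_crit)))
        dn = math.sqrt(sum((weighted[i][j] - anti[j]) ** 2 for j in range(n_crit)))
        out.append(0.5 if dp + dn == 0 else dn / (dp + dn))
    return out


def bh_reference(pvalues):
    """Textbook Benjamini-Hochberg step-up adjusted p-values."""
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        value = min(prev, pvalues[i] * m / rank)
        adjusted[i] = value
        prev = value
    return adjusted


def binom_upper_tail(k, n, p):
    """P(X >= k) for X ~ Binomial(n, p) by exact pmf summation."""
    if k <= 0:
        return 1.0
    total = 0.0
    for j in range(k, n + 1):
        total += math.comb(n, j) * (p**j) * ((1 - p) ** (n - j))
    return min(total, 1.0)


def quantile_linear(values, q):
    """Linear-interpolation quantile on the sorted order statistics."""
    xs = sorted(values)
    n = len(xs)
    if n == 1:
        return xs[0]
    pos = q * (n - 1)
    lo = math.floor(pos)
    hi = math.ceil(pos)
    frac = pos - lo
    return xs[lo] * (1 - frac) + xs[hi] * frac


def hypergeom_upper_tail(overlap, background, set_size, query_size):
    """P(X >= overlap) for the hypergeometric overlap, by direct counting."""
    total = math.comb(background, query_size)
    count = 0
    upper = min(set_size, query_size)
    for x in range(overlap, upper + 1):
        count += math.comb(set_size, x) * math.comb(background - set_size, query_size - x)
    return count / total


def gsea_es_reference(positions, scores):
    """Signed weighted-KS enrichment score by walking the full ranked list.

    ``positions``: 0-based hit positions; ``scores``: per-position scores of
    the ranked list (descending).
    """
    n = len(scores)
    hits = set(positions)
    k = len(hits)
    if k == n:
        return 1.0
    nr = sum(abs(scores[i]) for i in hits)
    running = 0.0
    best_pos, best_neg = 0.0, 0.0
    for i in range(n):
        if i in hits:
            running += (abs(scores[i]) / nr) if nr > 0 else 1.0 / k
        else:
            running -= 1.0 / (n - k)
        best_pos = max(best_pos, running)
        best_neg = min(best_neg, running)
    # positive sign wins analytic |max| == |min| ties (tolerance for float noise)
    return best_pos if best_pos >= -best_neg - 1e-12 else best_neg


def gsea_exact_pvalue(positions, scores):
    """Exact permutation p over all same-size position sets."""
    n = len(scores)
    k = len(positions)
    observed = gsea_es_reference(positions, scores)
    hits = 0
    total = 0
    for combo in combinations(range(n), k):
        es = gsea_es_reference(combo, scores)
        if observed >= 0:
            hits += es >= observed - 1e-9
        else:
            hits += es <= observed + 1e-9
        total += 1
    return hits / total
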