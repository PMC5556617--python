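"""Independent brute-force reference implementations used by the tests.

Everything here is written from the measure definitions with plain
Python loops and sets, deliberately avoiding the package's vectorized
code paths, so it can serve as an oracle for them.
"""

import math
from itertools import combinations


def pairwise_mean(sets, score):
    vals = [score(a, b) for a, b in combinations(sets, 2)]
    return sum(vals) / len(vals)


def jaccard(sets, p):
    return pairwise_mean(sets, lambda a, b: len(a & b) / len(a | b))


def dice(sets, p):
    return pairwise_mean(sets, lambda a, b: 2 * len(a & b) / (len(a) + len(b)))


def ochiai(sets, p):
    return pairwise_mean(
        sets, lambda a, b: len(a & b) / math.sqrt(len(a) * len(b))
    )


def lustgarten(sets, p):
    def score(a, b):
        den = min(len(a), len(b)) - max(0, len(a) + len(b) - p)
        return (len(a & b) - len(a) * len(b) / p) / den

    return pairwise_mean(sets, score)


def phi_from_table(a, b, p):
    """Phi coefficient from the 2x2 contingency table of two sets."""
    n11 = len(a & b)
    n10 = len(a - b)
    n01 = len(b - a)
    n00 = p - n11 - n10 - n01
    num = n11 * n00 - n10 * n01
    den = math.sqrt((n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00))
    return num / den


def correlation(sets, p):
    return pairwise_mean(sets, lambda a, b: phi_from_table(a, b, p))


def zucknick(sets, p, cor):
    """cor is a p x p array-like of Pearson correlations."""

    def score(a, b):
        union = sorted(a | b)
        if len(union) < 2:
            return len(a & b) / len(union)
        cors = [cor[x][y] for x, y in combinations(union, 2)]
        cors.sort()
        mid = len(cors) // 2
        r = cors[mid] if len(cors) % 2 else (cors[mid - 1] + cors[mid]) / 2
        c = sum(
            cor[x][y] for x in a for y in (b - a) if cor[x][y] > r
        ) / len(b)
        d = sum(
            cor[x][y] for x in b for y in (a - b) if cor[x][y] > r
        ) / len(a)
        return (len(a & b) + c + d) / len(a | b)

    return pairwise_mean(sets, score)


def counts(sets, p):
    h = [0] * p
    for s in sets:
        for j in s:
            h[j] += 1
    return h


def novovicova(sets, p):
    m = len(sets)
    h = counts(sets, p)
    q = sum(h)
    return sum(hj * math.log2(hj) for hj in h if hj > 0) / (q * math.log2(m))


def davis(sets, p, alpha):
    m = len(sets)
    h = counts(sets, p)
    union = set().union(*sets)
    sizes = sorted(len(s) for s in sets)
    mid = m // 2
    med = sizes[mid] if m % 2 else (sizes[mid - 1] + sizes[mid]) / 2
    return max(0.0, sum(hj / m for hj in h) / len(union) - alpha * med / p)


def somol(sets, p):
    m = len(sets)
    h = counts(sets, p)
    q = sum(h)
    D = sum((hj / q) * ((hj - 1) / (m - 1)) for hj in h if hj > 0)
    c_min = (q * q - p * (q - q % p) - (q % p) ** 2) / (p * q * (m - 1))
    c_max = ((q % m) ** 2 + q * (m - 1) - (q % m) * m) / (q * (m - 1))
    return (D - c_min) / (c_max - c_min)


def auc_by_pair_enumeration(x, y):
    """AUC as the fraction of (positive, negative) pairs ranked correctly,
    ties counting one half."""
    pos = [xi for xi, yi in zip(x, y) if yi == 1]
    neg = [xi for xi, yi in zip(x, y) if yi == 0]
    wins = sum(
        1.0 if a > b else 0.5 if a == b else 0.0 for a in pos for b in neg
    )
    return wins / (len(pos) * len(neg))


def pareto_front_bruteforce(vectors):
    """Indices of non-dominated vectors by exhaustive pairwise comparison."""

    def dom(y, z):
        return all(a <= b for a, b in zip(y, z)) and any(
            a < b for a, b in zip(y, z)
        )

    keep = []
    for i, v in enumerate(vectors):
        if not any(dom(w, v) for j, w in enumerate(vectors) if j != i):
            keep.append(i)
    return keep
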