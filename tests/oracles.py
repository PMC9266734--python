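"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive: explicit enumeration, scalar
loops, O(n^2) pair counting.  These routines must never share code with
the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def auc_pair_counting(scores, labels) -> float:
    """AUC as the probability a positive outscores a negative (ties 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def mwu_enumeration_p(x, y) -> float:
    """Exact two-sided Mann-Whitney p by enumerating all label assignments.

    p = P(|U - mu| >= |u_obs - mu|) over all C(n1+n2, n1) ways to assign
    the pooled values to the first sample.  Assumes no ties.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n1 = len(x)

    def u_of(subset):
        xs = [pooled[i] for i in subset]
        rest = [pooled[i] for i in range(len(pooled)) if i not in set(subset)]
        return sum(1.0 for a in xs for b in rest if a > b) + 0.5 * sum(
            1.0 for a in xs for b in rest if a == b
        )

    u_obs = sum(1.0 for a in x for b in y if a > b) + 0.5 * sum(
        1.0 for a in x for b in y if a == b
    )
    mu = n1 * len(y) / 2.0
    hits = 0
    total = 0
    for subset in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(u_of(subset) - mu) >= abs(u_obs - mu) - 1e-12:
            hits += 1
    return hits / total


def fisher_enumeration_p(table) -> float:
    """Two-sided Fisher p by full enumeration with exact rational arithmetic."""
    (a, b), (c, d) = [[int(v) for v in row] for row in table]
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0:
        return 1.0

    def prob(k):
        # hypergeometric pmf as an exact fraction
        from fractions import Fraction

        return Fraction(
            math.comb(r1, k) * math.comb(n - r1, c1 - k), math.comb(n, c1)
        )

    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    p_obs = prob(a)
    return float(sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs))


def km_no_censoring(times) -> dict[float, float]:
    """Closed-form empirical survival when every subject has an event."""
    times = sorted(map(float, times))
    n = len(times)
    out = {}
    for t in sorted(set(times)):
        out[t] = sum(1 for u in times if u > t) / n
    return out


def normfinder_bruteforce(z, groups) -> dict[str, float]:
    """Reference-gene stability values by scalar-loop evaluation of the
    variance-decomposition equations.

    ``z``: mapping candidate -> {sample: log-scale value} (or a DataFrame
    candidates x samples); ``groups``: mapping sample -> group label.
    Returns candidate -> stability value.
    """
    try:  # accept a DataFrame
        cands = list(z.index)
        samples = list(z.columns)
        zz = {i: {s: float(z.loc[i, s]) for s in samples} for i in cands}
    except AttributeError:
        zz = {i: dict(v) for i, v in z.items()}
        cands = list(zz)
        samples = list(next(iter(zz.values())))
    glabels = list(dict.fromkeys(groups[s] for s in samples))
    I, G = len(cands), len(glabels)

    sigma2, vsamp, m = {}, {}, {}
    for g in glabels:
        cols = [s for s in samples if groups[s] == g]
        n = len(cols)
        rowm = {i: sum(zz[i][c] for c in cols) / n for i in cands}
        colm = {c: sum(zz[i][c] for i in cands) / I for c in cols}
        grand = sum(zz[i][c] for i in cands for c in cols) / (I * n)
        S = {}
        for i in cands:
            ss = 0.0
            for c in cols:
                r = zz[i][c] - rowm[i] - colm[c] + grand
                ss += r * r
            S[i] = ss / (n - 1)
        Sbar = sum(S.values()) / I
        for i in cands:
            s2 = max((S[i] - Sbar / (I - 1)) * I / (I - 2), 0.0)
            sigma2[(i, g)] = s2
            vsamp[(i, g)] = s2 / n
            m[(i, g)] = rowm[i]

    d = {}
    for i in cands:
        mi = sum(m[(i, g)] for g in glabels) / G
        for g in glabels:
            d[(i, g)] = m[(i, g)] - mi
    for g in glabels:
        mg = sum(d[(i, g)] for i in cands) / I
        for i in cands:
            d[(i, g)] -= mg
    noise = sum(vsamp.values()) * (1 - 1 / I) * (1 - 1 / G)
    gamma2 = max(
        (sum(v * v for v in d.values()) - noise) / ((I - 1) * (G - 1)), 0.0
    )
    rho = {}
    for i in cands:
        tot = 0.0
        for g in glabels:
            v = vsamp[(i, g)]
            if gamma2 > 0:
                dt = d[(i, g)] * gamma2 / (gamma2 + v)
                vp = v * gamma2 / (gamma2 + v)
            else:
                dt, vp = 0.0, 0.0
            tot += abs(dt) + math.sqrt(v + vp)
        rho[i] = tot / G
    return rho
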