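"""Statistical primitives implemented from first principles.

Every routine here computes its statistic directly from the defining
formula; only the tail probabilities of standard distributions
(t, chi-square, normal, hypergeometric) come from :mod:`scipy.stats`.
Each primitive is cross-validated against independent oracles
(enumeration, closed forms, reference libraries) in the test suite.

Conventions: all tests are two-sided; p-values are never clipped except
to the [0, 1] interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as _sps

from .errors import InsufficientDataError

__all__ = [
    "TestResult",
    "RocCurve",
    "two_sample_t_test",
    "chi_square_test",
    "fisher_exact",
    "mann_whitney_u",
    "pearson_correlation",
    "roc_auc",
    "bh_adjust",
]


@dataclass
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    method: str
    df: float | None = None
    exact: bool = False
    degenerate: bool = False
    note: str = ""

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0 + 1e-12:
            raise ValueError(f"p-value out of range: {self.p_value}")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    arr = arr[np.isfinite(arr)] if np.isnan(arr).any() else arr
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values")
    return arr


def two_sample_t_test(x, y, variant: str = "pooled") -> TestResult:
    """Two-sided two-sample t-test on independent samples.

    ``variant="pooled"`` is the classical Student test (equal variances
    assumed); ``"welch"`` uses the Welch-Satterthwaite approximation.
    Degenerate zero-variance inputs yield t=0/p=1 when the means agree
    and p=0 (flagged) when they differ.
    """
    x = _as_float_array(x, "x")
    y = _as_float_array(y, "y")
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("t-test needs at least 2 values per group")
    m1, m2 = x.mean(), y.mean()
    v1 = x.var(ddof=1)
    v2 = y.var(ddof=1)
    if variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = float(n1 + n2 - 2)
        method = "t_pooled"
    elif variant == "welch":
        se2 = v1 / n1 + v2 / n2
        if se2 > 0:
            df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        else:
            df = float(n1 + n2 - 2)
        method = "t_welch"
    else:
        raise ValueError(f"unknown variant {variant!r}")
    if se2 <= 0.0:
        if m1 == m2:
            return TestResult(0.0, 1.0, method, df=df, degenerate=True,
                              note="zero variance, equal means")
        return TestResult(np.inf if m1 > m2 else -np.inf, 0.0, method, df=df,
                          degenerate=True, note="zero variance, unequal means")
    t = (m1 - m2) / np.sqrt(se2)
    p = 2.0 * _sps.t.sf(abs(t), df)
    return TestResult(float(t), float(min(p, 1.0)), method, df=df)


def chi_square_test(table, correction: bool = False) -> TestResult:
    """Pearson chi-square test of independence on an r x k count table.

    No continuity correction by default (``correction=True`` applies the
    Yates correction on 2x2 tables only).  Requires every row and column
    margin to be positive; degenerate margins should go to Fisher's exact
    test instead.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must contain nonnegative integer counts")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError(
            "zero row/column margin: chi-square undefined; use fisher_exact"
        )
    n = t.sum()
    expected = np.outer(rows, cols) / n
    diff = np.abs(t - expected)
    if correction and t.shape == (2, 2):
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff**2 / expected).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(_sps.chi2.sf(stat, df))
    return TestResult(stat, p, "chi_square", df=float(df))


def fisher_exact(table) -> TestResult:
    """Fisher's exact test on a 2x2 table (two-sided).

    The two-sided p-value sums the hypergeometric probabilities, under
    fixed margins, of every table whose probability does not exceed the
    observed one (with a 1e-12 relative tolerance for ties).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must be a 2x2 nonnegative integer table")
    a = int(round(t[0, 0]))
    r1 = int(round(t[0].sum()))
    c1 = int(round(t[:, 0].sum()))
    n = int(round(t.sum()))
    if n == 0:
        return TestResult(np.nan, 1.0, "fisher_exact", exact=True, degenerate=True)
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    ks = np.arange(lo, hi + 1)
    pmf = _sps.hypergeom.pmf(ks, n, r1, c1)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    # odds ratio as the conventional statistic (inf/0 allowed)
    with np.errstate(divide="ignore", invalid="ignore"):
        oddsratio = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return TestResult(float(oddsratio), min(p, 1.0), "fisher_exact", exact=True)


@lru_cache(maxsize=None)
def _u_count(n1: int, n2: int, u: int) -> int:
    """Number of arrangements of n1 vs n2 untied values with U statistic u."""
    if u < 0 or u > n1 * n2:
        return 0
    if n1 == 0 or n2 == 0:
        return 1 if u == 0 else 0
    # recursion on whether the largest observation belongs to sample 1 or 2
    return _u_count(n1 - 1, n2, u - n2) + _u_count(n1, n2 - 1, u)


def _u_exact_p(n1: int, n2: int, u: float) -> float:
    """Exact two-sided p for the U statistic (no ties): symmetric tail doubling."""
    from math import comb

    u_min = min(u, n1 * n2 - u)
    cum = sum(_u_count(n1, n2, k) for k in range(int(np.floor(u_min)) + 1))
    return min(1.0, 2.0 * cum / comb(n1 + n2, n1))


def _rankdata(a: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties)."""
    order = np.argsort(a, kind="mergesort")
    ranks = np.empty(len(a), dtype=float)
    sa = a[order]
    i = 0
    while i < len(a):
        j = i
        while j + 1 < len(a) and sa[j + 1] == sa[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def mann_whitney_u(x, y) -> TestResult:
    """Mann-Whitney U test (two-sided), ties counted one half.

    Exact enumeration of the permutation distribution when both samples
    have at most 8 observations and there are no ties; otherwise the
    normal approximation with tie correction and a 0.5 continuity
    correction.
    """
    x = _as_float_array(x, "x")
    y = _as_float_array(y, "y")
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise InsufficientDataError("mann_whitney_u needs >=1 value per group")
    pooled = np.concatenate([x, y])
    ranks = _rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0  # number of (x>y) pairs, ties 1/2
    n_ties = len(pooled) - len(np.unique(pooled))
    if n1 <= 8 and n2 <= 8 and n_ties == 0:
        p = _u_exact_p(n1, n2, u1)
        return TestResult(float(u1), p, "mann_whitney", exact=True)
    mu = n1 * n2 / 2.0
    nn = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n1 * n2 / 12.0 * ((nn + 1) - tie_term / (nn * (nn - 1.0)))
    if var <= 0:
        return TestResult(float(u1), 1.0, "mann_whitney", degenerate=True,
                          note="all values tied")
    z = (abs(u1 - mu) - 0.5) / np.sqrt(var)
    z = max(z, 0.0)
    p = float(min(1.0, 2.0 * _sps.norm.sf(z)))
    return TestResult(float(u1), p, "mann_whitney")


def pearson_correlation(x, y) -> TestResult:
    """Pearson product-moment correlation with two-sided t-based p-value.

    Pairs with a missing member are dropped (pairwise-complete); fewer
    than 3 complete pairs or zero variance in either variable yields an
    undefined (degenerate) result rather than an error, so that pair
    screens can record and exclude it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        return TestResult(np.nan, np.nan, "pearson", degenerate=True,
                          note=f"only {n} complete pairs")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0.0:
        return TestResult(np.nan, np.nan, "pearson", degenerate=True,
                          note="zero variance")
    r = float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))
    df = n - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = float(2.0 * _sps.t.sf(abs(t), df))
    return TestResult(r, min(p, 1.0), "pearson", df=float(df))


@dataclass
class RocCurve:
    """Empirical ROC curve with trapezoidal AUC.

    The stored AUC equals both the trapezoidal area of the curve and the
    Mann-Whitney probability that a random positive scores above a random
    negative (ties one half); construction asserts the two agree.
    """

    thresholds: np.ndarray
    tpr: np.ndarray  # sensitivity
    fpr: np.ndarray  # 1 - specificity
    auc: float
    positive_class: object
    orientation: str = "as_given"
    n_pos: int = 0
    n_neg: int = 0

    @property
    def auc_flipped(self) -> float:
        return 1.0 - self.auc


def roc_auc(scores, labels, positive_class=1) -> RocCurve:
    """Empirical ROC curve of ``scores`` against binary ``labels``.

    Higher scores are taken to indicate the positive class; the curve is
    reported as computed (no orientation flip), with the flipped AUC
    available as ``auc_flipped``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    mask = np.isfinite(scores)
    scores, labels = scores[mask], labels[mask]
    pos = labels == positive_class
    n_pos = int(pos.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise InsufficientDataError("roc_auc requires both classes present")
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    y = pos[order].astype(float)
    # group tied scores so the curve moves diagonally through ties
    distinct = np.r_[np.diff(s) != 0, True]
    tp = np.cumsum(y)[distinct]
    fp = np.cumsum(1.0 - y)[distinct]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    auc_trap = float(np.trapezoid(tpr, fpr))
    # Mann-Whitney identity: AUC = U / (n_pos * n_neg), ties one half
    ranks = _rankdata(scores)
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0
    auc_u = float(u / (n_pos * n_neg))
    if abs(auc_trap - auc_u) > 1e-12:
        raise AssertionError(
            f"trapezoid AUC {auc_trap!r} != U-statistic AUC {auc_u!r}"
        )
    return RocCurve(thresholds, tpr, fpr, auc_trap, positive_class,
                    n_pos=n_pos, n_neg=n_neg)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out
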