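"""Survival screen: median dichotomization, Kaplan-Meier estimation,
log-rank tests and Cox proportional-hazards fits.

All estimators are implemented directly: the product-limit estimator with
the standard censored-at-event-time-still-at-risk convention, the
two-group log-rank chi-square (df=1, hypergeometric variance), and Cox
partial-likelihood maximisation by Newton-Raphson with Breslow tie
handling.  A fitted coefficient wandering beyond |beta| > 10 is reported
as a monotone-likelihood regime (a covariate perfectly ordering events);
its Wald interval is still printed but flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .datatypes import ExpressionMatrix, SampleAnnotation
from .errors import InsufficientDataError
from .stats import TestResult

__all__ = [
    "dichotomize_by_median",
    "KmCurve",
    "kaplan_meier",
    "logrank_test",
    "CoxFit",
    "cox_ph_fit",
    "SurvivalResult",
    "survival_marker_screen",
    "DEFAULT_ADJUSTMENT",
]

#: default Cox adjustment covariates per endpoint
DEFAULT_ADJUSTMENT = {
    "css": ("lymph_node_metastasis", "perineural_invasion"),
    "os": (),
}

MONOTONE_BETA = 10.0


def dichotomize_by_median(values: pd.Series) -> tuple[pd.Series, bool]:
    """Split values at their median into 'high' (> median) and 'low'.

    Values equal to the median go to 'low', so at odd n exactly
    ceil(n/2) samples are low.  Missing values get no label.  Returns
    (labels, degenerate); degenerate is True when all non-missing values
    are identical (no split possible).
    """
    v = values.dropna()
    if len(v) < 2:
        raise InsufficientDataError("need >=2 non-missing values to dichotomize")
    med = float(np.median(v))
    labels = pd.Series(pd.NA, index=values.index, dtype="object")
    labels[v.index] = np.where(v > med, "high", "low")
    degenerate = bool(v.nunique() == 1 or (labels[v.index] == "low").all()
                      or (labels[v.index] == "high").all())
    return labels, degenerate


@dataclass
class KmCurve:
    """Kaplan-Meier product-limit curve (right-continuous step function)."""

    times: np.ndarray        # distinct event times, ascending
    at_risk: np.ndarray      # number at risk just before each event time
    n_events: np.ndarray     # events at each event time
    survival: np.ndarray     # S(t) just after each event time
    censor_times: np.ndarray  # censoring marks

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def kaplan_meier(times, events) -> KmCurve:
    """Product-limit estimator of the survival function.

    Subjects censored exactly at an event time count as at risk for that
    time (standard convention).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise InsufficientDataError("kaplan_meier: empty input")
    if (t < 0).any() or not set(np.unique(e)) <= {0, 1}:
        raise ValueError("times must be >=0 and events 0/1")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    ev_times = np.unique(t[e == 1])
    n = len(t)
    at_risk = np.array([(t >= u).sum() for u in ev_times], dtype=float)
    d = np.array([((t == u) & (e == 1)).sum() for u in ev_times], dtype=float)
    with np.errstate(invalid="ignore"):
        surv = np.cumprod(1.0 - d / at_risk)
    return KmCurve(
        times=ev_times,
        at_risk=at_risk,
        n_events=d,
        survival=surv,
        censor_times=np.sort(t[e == 0]),
    )


def logrank_test(times, events, groups) -> TestResult:
    """Two-group log-rank test (chi-square, df=1, two-sided).

    With no events at all the statistic is 0 and p = 1 (flagged
    degenerate).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError("logrank_test requires exactly two groups")
    if e.sum() == 0:
        return TestResult(0.0, 1.0, "logrank", df=1.0, degenerate=True,
                          note="no events")
    in1 = g == labels[0]
    ev_times = np.unique(t[e == 1])
    o_minus_e = 0.0
    var = 0.0
    for u in ev_times:
        at = t >= u
        n_at = at.sum()
        n1 = (at & in1).sum()
        d = ((t == u) & (e == 1)).sum()
        d1 = ((t == u) & (e == 1) & in1).sum()
        o_minus_e += d1 - d * n1 / n_at
        if n_at > 1:
            var += d * (n1 / n_at) * (1 - n1 / n_at) * (n_at - d) / (n_at - 1)
    if var <= 0:
        return TestResult(0.0, 1.0, "logrank", df=1.0, degenerate=True,
                          note="zero variance")
    stat = o_minus_e**2 / var
    return TestResult(float(stat), float(_sps.chi2.sf(stat, 1)), "logrank", df=1.0)


@dataclass
class CoxFit:
    """Cox proportional-hazards fit (Breslow ties, Wald inference)."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    n: int
    n_events: int
    convergence: str  # converged | monotone_likelihood | failed
    n_iter: int

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.beta)

    def ci(self, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
        z = _sps.norm.ppf(0.5 + level / 2.0)
        with np.errstate(over="ignore"):
            return np.exp(self.beta - z * self.se), np.exp(self.beta + z * self.se)

    @property
    def p_values(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            z = self.beta / self.se
        return 2.0 * _sps.norm.sf(np.abs(z))

    def summary(self) -> pd.DataFrame:
        lo, hi = self.ci()
        return pd.DataFrame(
            {
                "covariate": self.names,
                "beta": self.beta,
                "hr": self.hr,
                "ci_low": lo,
                "ci_high": hi,
                "p_value": self.p_values,
                "convergence": self.convergence,
            }
        )


def _cox_loglik_grad_hess(beta, t, e, X):
    """Breslow partial log-likelihood and derivatives.

    Samples sorted by descending time so the risk set at an event time is
    a prefix; tied event times share one denominator evaluated at the
    full risk set.
    """
    eta = X @ beta
    eta = np.clip(eta, -200.0, 200.0)
    w = np.exp(eta)
    wx = X * w[:, None]
    wxx = np.einsum("ij,ik->ijk", X, X) * w[:, None, None]
    cw = np.cumsum(w)
    cwx = np.cumsum(wx, axis=0)
    cwxx = np.cumsum(wxx, axis=0)
    ll = 0.0
    grad = np.zeros(X.shape[1])
    hess = np.zeros((X.shape[1], X.shape[1]))
    i = 0
    n = len(t)
    while i < n:
        j = i
        while j + 1 < n and t[j + 1] == t[i]:
            j += 1
        # risk set = all indices 0..j (times >= t[i])
        ev = [k for k in range(i, j + 1) if e[k] == 1]
        if ev:
            d = len(ev)
            S0 = cw[j]
            S1 = cwx[j]
            S2 = cwxx[j]
            xsum = X[ev].sum(axis=0)
            ll += eta[ev].sum() - d * np.log(S0)
            grad += xsum - d * S1 / S0
            hess -= d * (S2 / S0 - np.outer(S1, S1) / S0**2)
        i = j + 1
    return ll, grad, hess


def cox_ph_fit(
    times,
    events,
    covariates,
    names: list[str] | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> CoxFit:
    """Fit a Cox model by Newton-Raphson with Breslow tie handling.

    Requires at least one event and no constant covariate.  Convergence
    is declared when the coefficient update falls below ``tol``;
    |beta| > 10 marks the monotone-likelihood regime (estimates and Wald
    intervals still reported, flagged).
    """
    if isinstance(covariates, pd.DataFrame):
        names = names or list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(covariates, dtype=float))
        if X.shape[0] == 1 and len(np.asarray(times)) != 1:
            X = X.T
        names = names or [f"x{i}" for i in range(X.shape[1])]
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if e.sum() == 0:
        raise InsufficientDataError("cox_ph_fit: no events")
    if not np.isfinite(X).all():
        raise ValueError("covariates must be finite")
    if (X.std(axis=0) == 0).any():
        const = [names[i] for i in range(X.shape[1]) if X[:, i].std() == 0]
        raise ValueError(f"constant covariate(s): {const}")

    order = np.argsort(-t, kind="mergesort")
    t_s, e_s, X_s = t[order], e[order], X[order]
    p = X.shape[1]
    beta = np.zeros(p)
    ll, grad, hess = _cox_loglik_grad_hess(beta, t_s, e_s, X_s)
    convergence = "failed"
    it = 0
    for it in range(1, max_iter + 1):
        try:
            delta = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            convergence = "failed"
            break
        # step-halving to guarantee likelihood ascent
        step = 1.0
        for _ in range(30):
            new_beta = beta + step * delta
            new_ll, new_grad, new_hess = _cox_loglik_grad_hess(
                new_beta, t_s, e_s, X_s
            )
            if new_ll >= ll - 1e-12:
                break
            step /= 2.0
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
        if np.max(np.abs(step * delta)) < tol:
            convergence = "converged"
            break
        if np.max(np.abs(beta)) > MONOTONE_BETA * 1.5:
            convergence = "monotone_likelihood"
            break
    else:
        convergence = (
            "monotone_likelihood"
            if np.max(np.abs(beta)) > MONOTONE_BETA
            else "failed"
        )
    if convergence == "converged" and np.max(np.abs(beta)) > MONOTONE_BETA:
        convergence = "monotone_likelihood"
    with np.errstate(invalid="ignore"):
        try:
            cov = np.linalg.inv(-hess)
            se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
        except np.linalg.LinAlgError:
            se = np.full(p, np.nan)
            convergence = "failed"
    return CoxFit(
        names=list(names),
        beta=beta,
        se=se,
        loglik=float(ll),
        n=len(t),
        n_events=int(e.sum()),
        convergence=convergence,
        n_iter=it,
    )


@dataclass
class SurvivalResult:
    """One marker's row of the survival screen (log-rank + adjusted Cox)."""

    marker: str
    endpoint: str
    logrank_p: float
    hr: float
    ci_low: float
    ci_high: float
    cox_p: float
    adjusted_for: tuple = ()
    convergence: str = "converged"
    n_high: int = 0
    n_low: int = 0
    skipped: bool = False
    reason: str = ""
    km_high: KmCurve | None = field(default=None, repr=False)
    km_low: KmCurve | None = field(default=None, repr=False)


def survival_marker_screen(
    expr: ExpressionMatrix,
    ann: SampleAnnotation,
    endpoint: str = "css",
    adjustment: list[str] | None = None,
) -> list[SurvivalResult]:
    """Median-dichotomized survival screen over all targets.

    Per marker: split samples at the median -dCT, estimate KM curves per
    stratum, test high vs low with the (unadjusted) log-rank test, then
    fit a Cox model on the high/low indicator plus the adjustment
    covariates.  Default adjustment: lymph-node metastasis and perineural
    invasion for CSS, none for OS.  Markers whose dichotomization is
    degenerate are skipped with a reason.
    """
    endpoint = endpoint.lower()
    if endpoint not in ("os", "css"):
        raise ValueError("endpoint must be 'os' or 'css'")
    if adjustment is None:
        adjustment = list(DEFAULT_ADJUSTMENT[endpoint])
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    results: list[SurvivalResult] = []
    for marker in expr.targets:
        vals = expr.values[marker]
        try:
            labels, degenerate = dichotomize_by_median(vals)
        except InsufficientDataError as exc:
            results.append(SurvivalResult(
                marker, endpoint.upper(), np.nan, np.nan, np.nan, np.nan,
                np.nan, tuple(adjustment), "failed", skipped=True,
                reason=str(exc)))
            continue
        if degenerate:
            results.append(SurvivalResult(
                marker, endpoint.upper(), np.nan, np.nan, np.nan, np.nan,
                np.nan, tuple(adjustment), "failed", skipped=True,
                reason="degenerate dichotomization (all values on one side)"))
            continue
        mask = labels.notna()
        sub_ann = ann.data.reindex(labels.index)[mask]
        lab = labels[mask]
        t = sub_ann[tcol].to_numpy(dtype=float)
        e = sub_ann[ecol].to_numpy(dtype=int)
        high = (lab == "high").to_numpy().astype(float)
        km_high = kaplan_meier(t[high == 1], e[high == 1])
        km_low = kaplan_meier(t[high == 0], e[high == 0])
        lr = logrank_test(t, e, lab.to_numpy())
        covs = pd.DataFrame({f"{marker}_high": high}, index=sub_ann.index)
        for adj in adjustment:
            covs[adj] = sub_ann[adj].to_numpy(dtype=float)
        try:
            fit = cox_ph_fit(t, e, covs)
            lo, hi = fit.ci()
            results.append(SurvivalResult(
                marker, endpoint.upper(), lr.p_value,
                float(fit.hr[0]), float(lo[0]), float(hi[0]),
                float(fit.p_values[0]), tuple(adjustment), fit.convergence,
                n_high=int(high.sum()), n_low=int((1 - high).sum()),
                km_high=km_high, km_low=km_low))
        except (InsufficientDataError, ValueError) as exc:
            results.append(SurvivalResult(
                marker, endpoint.upper(), lr.p_value, np.nan, np.nan, np.nan,
                np.nan, tuple(adjustment), "failed", skipped=True,
                reason=str(exc), km_high=km_high, km_low=km_low))
    return results


def survival_results_table(results: list[SurvivalResult]) -> pd.DataFrame:
    """Flatten screen results into a Table-4-shaped frame."""
    return pd.DataFrame(
        [
            {
                "marker": r.marker,
                "endpoint": r.endpoint,
                "logrank_p": r.logrank_p,
                "hr": r.hr,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "cox_p": r.cox_p,
                "adjusted_for": ",".join(r.adjusted_for),
                "convergence": r.convergence,
                "skipped": r.skipped,
                "reason": r.reason,
            }
            for r in results
        ]
    )
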