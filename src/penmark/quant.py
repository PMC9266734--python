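"""Comparative-CT quantification: replicate aggregation, detection
filtering, reference-gene stability selection and -dCT computation.

The reference-gene stability model is the two-group variance decomposition
of Andersen-style reference selection: within each sample group, candidate
CT values are decomposed into gene effect + sample effect + residual; a
candidate's stability combines its bias-corrected intragroup residual
variance with the (shrunken) systematic difference of its level between
groups.  Lower stability value = more stable.  See docs/methods.md for the
exact estimators.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CtTable, ExpressionMatrix, SampleAnnotation
from .errors import InsufficientDataError
from .stats import two_sample_t_test  # noqa: F401  (re-exported convenience)

__all__ = [
    "aggregate_replicates",
    "apply_ct_filter",
    "StabilityResult",
    "StabilityAnalysis",
    "normfinder_stability",
    "select_reference_genes",
    "compute_neg_delta_ct",
    "fold_change_between_groups",
]


def aggregate_replicates(ct: CtTable, outlier_mode: str = "none") -> CtTable:
    """Collapse replicate wells to one row per (sample, assay).

    The aggregate CT is the arithmetic mean of the available (determined)
    replicates; replicate count and SD are kept as quality fields.  If all
    replicates are undetermined the aggregate is undetermined (NaN).

    ``outlier_mode="drop_worst_if_sd_gt_0.5"`` drops the replicate farthest
    from the median when the replicate SD exceeds 0.5 cycles and at least
    three replicates are available; the default applies no rejection.
    """
    if outlier_mode not in ("none", "drop_worst_if_sd_gt_0.5"):
        raise ValueError(f"unknown outlier_mode {outlier_mode!r}")

    grouped = ct.data.groupby(["sample_id", "assay_id", "assay_class"], sort=True)
    agg = grouped["ct"].agg(ct="mean", ct_sd="std", n_replicates="count")

    if outlier_mode == "drop_worst_if_sd_gt_0.5":
        flagged = agg.index[(agg["ct_sd"] > 0.5) & (agg["n_replicates"] >= 3)]
        redo = {}
        for key in flagged:
            v = grouped.get_group(key)["ct"].dropna().to_numpy(dtype=float)
            worst = np.argmax(np.abs(v - np.median(v)))
            v = np.delete(v, worst)
            redo[key] = (v.mean(), v.std(ddof=1) if len(v) > 1 else np.nan, len(v))
        for key, (mean, sd, n) in redo.items():
            agg.loc[key, ["ct", "ct_sd", "n_replicates"]] = (mean, sd, n)

    out = agg.reset_index()
    out["replicate_index"] = 1
    out = out[
        ["sample_id", "assay_id", "assay_class", "replicate_index",
         "ct", "ct_sd", "n_replicates"]
    ]
    return CtTable(out, aggregated=True)


def apply_ct_filter(
    ct: CtTable,
    threshold: float = 24.0,
    scope: set[str] | None = None,
) -> CtTable:
    """Mark low-abundance reactions as excluded.

    An aggregated entry is excluded when its CT is ``>= threshold``
    (strict "lower than threshold" keeps it) or undetermined, for assays
    whose class lies in ``scope`` (default: the mRNA target panel only).
    Exclusions are flags, not row drops; the exclusion log is attached to
    the returned table as ``.exclusion_log``.
    """
    if scope is None:
        scope = {"mrna_target"}
    df = ct.data.copy()
    in_scope = df["assay_class"].isin(scope)
    fails = in_scope & (~(df["ct"] < threshold) | df["ct"].isna())
    prior = (
        df["excluded"].astype(bool)
        if "excluded" in df.columns
        else pd.Series(False, index=df.index)
    )
    df["excluded"] = (prior | fails).to_numpy()
    out = CtTable(df, aggregated=ct.aggregated)
    log = df.loc[fails, ["sample_id", "assay_id", "ct"]].copy()
    log["reason"] = np.where(
        log["ct"].isna(), "undetermined", f"ct >= {threshold:g}"
    )
    out.exclusion_log = log.reset_index(drop=True)
    return out


@dataclass
class StabilityResult:
    """Stability of one candidate reference assay (lower = more stable)."""

    assay_id: str
    stability_value: float
    intragroup_variance: float
    intergroup_component: float
    rank: int = 0


@dataclass
class StabilityAnalysis:
    """Ranked candidate stabilities plus the best k=2 combination."""

    results: list[StabilityResult]
    best_pair: tuple[str, str]
    best_pair_stability: float
    excluded: list[str] = field(default_factory=list)
    # per-candidate intermediates used for combination scoring
    _d_tilde: pd.DataFrame | None = None
    _var_term: pd.DataFrame | None = None

    def ranked_ids(self) -> list[str]:
        return [r.assay_id for r in self.results]


def _stability_components(
    z: pd.DataFrame, groups: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Core variance decomposition.

    ``z``: candidates x samples CT matrix (complete); ``groups``: sample
    group labels.  Returns (sigma2, d_tilde, var_post), each candidates x
    groups:

    * sigma2 -- bias-corrected intragroup residual variance of the
      candidate (gene- and sample-effects removed within group);
    * d_tilde -- shrunken gene-by-group interaction effect (systematic
      deviation of the candidate's level in that group);
    * var_term -- uncertainty attached to that candidate/group:
      sampling variance of the group mean (sigma2/n_g) plus the
      posterior variance of the shrunken interaction estimate.

    The stability value of a candidate set combines bias and noise as
    mean over groups of |d_tilde| + sqrt(var_term); a candidate constant
    in every sample and group scores exactly 0.
    """
    cands = list(z.index)
    I = len(cands)
    glabels = list(pd.unique(groups))
    G = len(glabels)
    sigma2 = pd.DataFrame(index=cands, columns=glabels, dtype=float)
    v_samp = pd.DataFrame(index=cands, columns=glabels, dtype=float)  # sigma2/n_g
    m = pd.DataFrame(index=cands, columns=glabels, dtype=float)  # group means

    for g in glabels:
        sub = z.loc[:, groups[groups == g].index].to_numpy(dtype=float)
        n_g = sub.shape[1]
        row_m = sub.mean(axis=1, keepdims=True)
        col_m = sub.mean(axis=0, keepdims=True)
        grand = sub.mean()
        resid = sub - row_m - col_m + grand
        S = (resid**2).sum(axis=1) / (n_g - 1)
        # unbiased per-candidate residual variance under heteroscedasticity:
        # E[S_i] = sigma_i^2 (1 - 2/I) + mean(sigma^2)/I
        s2 = np.maximum((S - S.mean() / (I - 1)) * I / (I - 2), 0.0)
        sigma2[g] = s2
        v_samp[g] = s2 / n_g
        m[g] = row_m.ravel()

    # doubly centred gene-by-group deviations
    d = m.sub(m.mean(axis=1), axis=0)
    d = d.sub(d.mean(axis=0), axis=1)
    # common interaction variance, corrected for sampling noise in the means
    if G > 1 and I > 1:
        noise = v_samp.to_numpy().sum() * (1 - 1 / I) * (1 - 1 / G)
        gamma2 = max(
            ((d.to_numpy() ** 2).sum() - noise) / ((I - 1) * (G - 1)), 0.0
        )
    else:
        gamma2 = 0.0
    denom = gamma2 + v_samp
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = (gamma2 / denom).fillna(0.0) if gamma2 > 0 else denom * 0.0
    d_tilde = d * shrink
    var_post = (v_samp * gamma2 / denom).fillna(0.0) if gamma2 > 0 else v_samp * 0.0
    var_term = v_samp + var_post
    return sigma2, d_tilde, var_term


def _combo_stability(
    combo: tuple[str, ...], d_tilde: pd.DataFrame, var_term: pd.DataFrame
) -> float:
    """Stability of a reference combination: the averaged candidate."""
    k = len(combo)
    d = d_tilde.loc[list(combo)].mean(axis=0)
    v = var_term.loc[list(combo)].sum(axis=0) / k**2
    return float((d.abs() + np.sqrt(v)).mean())


def normfinder_stability(
    ct: CtTable,
    candidates: list[str],
    grouping: SampleAnnotation,
    max_missing_fraction: float = 0.2,
) -> StabilityAnalysis:
    """Rank candidate reference assays by expression stability.

    Works on aggregated CT values of ``candidates``; samples missing any
    retained candidate are dropped (the decomposition needs a complete
    matrix), candidates missing in more than ``max_missing_fraction`` of
    samples are excluded with a warning.  Requires at least 3 usable
    candidates and 2 samples per group.

    Returns a :class:`StabilityAnalysis` with candidates sorted ascending
    by stability value (rank 1 = most stable; ties broken by assay id)
    and the best two-candidate combination.
    """
    if len(candidates) < 3:
        raise InsufficientDataError("need >=3 candidate reference assays")
    wide = ct.pivot_ct()
    missing_cols = [c for c in candidates if c not in wide.columns]
    if missing_cols:
        raise InsufficientDataError(f"candidates absent from CT table: {missing_cols}")
    z = wide[candidates]
    excluded = [
        c for c in candidates if z[c].isna().mean() > max_missing_fraction
    ]
    if excluded:
        warnings.warn(
            f"reference candidates excluded for missingness: {excluded}",
            stacklevel=2,
        )
    usable = [c for c in candidates if c not in excluded]
    if len(usable) < 3:
        raise InsufficientDataError(
            f"fewer than 3 usable candidates after missingness filter ({usable})"
        )
    z = z[usable].dropna(axis=0)
    groups = grouping.group.reindex(z.index).dropna()
    z = z.loc[groups.index]
    counts = groups.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise InsufficientDataError(
            "stability analysis needs >=2 complete samples in each group"
        )
    zt = z.T  # candidates x samples
    sigma2, d_tilde, var_term = _stability_components(zt, groups)

    results = []
    for c in usable:
        rho = _combo_stability((c,), d_tilde, var_term)
        results.append(
            StabilityResult(
                assay_id=c,
                stability_value=rho,
                intragroup_variance=float(sigma2.loc[c].mean()),
                intergroup_component=float(d_tilde.loc[c].abs().mean()),
            )
        )
    results.sort(key=lambda r: (r.stability_value, r.assay_id))
    for i, r in enumerate(results, start=1):
        r.rank = i

    pairs = sorted(itertools.combinations(sorted(usable), 2))
    pair_scores = [(p, _combo_stability(p, d_tilde, var_term)) for p in pairs]
    best_pair, best_score = min(pair_scores, key=lambda ps: (ps[1], ps[0]))
    return StabilityAnalysis(
        results=results,
        best_pair=best_pair,
        best_pair_stability=best_score,
        excluded=excluded,
        _d_tilde=d_tilde,
        _var_term=var_term,
    )


def select_reference_genes(stability: StabilityAnalysis, k: int = 2) -> list[str]:
    """Best reference combination of size ``k`` by combination stability.

    ``k=1`` returns the rank-1 candidate; ``k=2`` the precomputed best
    pair; larger ``k`` evaluates all combinations.  Ties break
    lexicographically on the sorted assay-id tuple.
    """
    ids = stability.ranked_ids()
    if k > len(ids):
        raise InsufficientDataError(f"k={k} exceeds {len(ids)} candidates")
    if k == 1:
        return [ids[0]]
    if k == 2:
        return list(stability.best_pair)
    combos = sorted(itertools.combinations(sorted(ids), k))
    scored = [
        (c, _combo_stability(c, stability._d_tilde, stability._var_term))
        for c in combos
    ]
    best, _ = min(scored, key=lambda cs: (cs[1], cs[0]))
    return list(best)


def compute_neg_delta_ct(ct: CtTable, refs: list[str]) -> ExpressionMatrix:
    """Normalise CT to -dCT: ``mean(CT of refs) - CT(target)`` per sample.

    Target cells excluded by the CT filter or undetermined become missing.
    Samples lacking any reference value are dropped with a warning
    (normalisation is undefined for them).  Reference assays do not appear
    among the targets.
    """
    if not refs:
        raise ValueError("refs must be non-empty")
    wide = ct.pivot_ct()
    missing_refs = [r for r in refs if r not in wide.columns]
    if missing_refs:
        raise InsufficientDataError(f"reference assay(s) not in table: {missing_refs}")
    ref_ct = wide[refs]
    ok = ref_ct.notna().all(axis=1)
    if (~ok).any():
        warnings.warn(
            f"samples dropped for missing reference values: {list(wide.index[~ok])}",
            stacklevel=2,
        )
    wide = wide.loc[ok]
    ref_mean = wide[refs].mean(axis=1)
    targets = [c for c in wide.columns if c not in refs]
    # -dCT = mean(CT_refs) - CT_target
    neg_dct = wide[targets].rsub(ref_mean, axis=0)
    return ExpressionMatrix(neg_dct, normalization_refs=list(refs))


def fold_change_between_groups(
    expr: ExpressionMatrix,
    grouping: SampleAnnotation | pd.Series,
    target: str,
    numerator: str = "metastatic",
    denominator: str = "localized",
) -> float:
    """Comparative-CT fold change ``2**(ddCT)`` between two groups.

    FC = 2^(mean -dCT in numerator group - mean -dCT in denominator
    group); FC > 1 means the target is up in the numerator (metastatic)
    group.  Requires at least two non-missing values per group.
    """
    groups = grouping.group if isinstance(grouping, SampleAnnotation) else grouping
    vals = expr.values[target]
    groups = groups.reindex(vals.index)
    x = vals[groups == numerator].dropna()
    y = vals[groups == denominator].dropna()
    if len(x) < 2 or len(y) < 2:
        raise InsufficientDataError(
            f"{target}: need >=2 values per group (got {len(x)}/{len(y)})"
        )
    return float(2.0 ** (x.mean() - y.mean()))
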