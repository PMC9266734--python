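"""mRNA-miRNA pair screen: per-group correlations, candidate selection,
pair-score discrimination AUC, and regulation-disruption classification.

The screen enumerates every (gene, miRNA) combination, computes Pearson
correlations separately in the localized and metastatic groups, keeps
pairs significant (p <= alpha, default 0.1, inclusive) in at least one
group, scores each sample by the pair's expression log-ratio
(-dCT_gene - -dCT_miRNA by default) and measures how well that score
separates the groups (ROC AUC; "top" pairs exceed the cutoff strictly).
A pair is *disrupted* when its correlation class (positive / negative /
none at the class alpha) differs between groups; the pattern
none-or-positive in localized turning significantly negative in
metastatic is additionally flagged *repression-gain*.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, SampleAnnotation
from .errors import InsufficientDataError
from .stats import pearson_correlation, roc_auc

__all__ = [
    "pairwise_group_correlations",
    "select_candidate_pairs",
    "pair_score",
    "pair_discrimination_auc",
    "classify_disruption",
    "screen_pairs",
]

_GROUPS = ("localized", "metastatic")


def _group_series(grouping) -> pd.Series:
    return grouping.group if isinstance(grouping, SampleAnnotation) else grouping


def pairwise_group_correlations(
    gene_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    grouping,
) -> pd.DataFrame:
    """Pearson r and two-sided p per (gene, miRNA) pair and group.

    One row per pair (n_genes x n_mirnas rows), on pairwise-complete
    -dCT values within each group; groups with fewer than 3 complete
    pairs yield undefined (NaN) entries for that group.
    """
    samples = [s for s in gene_expr.samples if s in set(mirna_expr.samples)]
    if not samples:
        raise InsufficientDataError("matrices share no samples")
    groups = _group_series(grouping).reindex(samples)
    gvals = gene_expr.values.loc[samples]
    mvals = mirna_expr.values.loc[samples]
    rows = []
    masks = {g: (groups == g).to_numpy() for g in _GROUPS}
    for gene in gene_expr.targets:
        gv = gvals[gene].to_numpy()
        for mirna in mirna_expr.targets:
            mv = mvals[mirna].to_numpy()
            row = {"gene": gene, "mirna": mirna}
            for g in _GROUPS:
                res = pearson_correlation(gv[masks[g]], mv[masks[g]])
                tag = "localized" if g == "localized" else "metastatic"
                row[f"r_{tag}"] = res.statistic
                row[f"p_{tag}"] = res.p_value
                row[f"n_{tag}"] = (res.df + 2) if res.df is not None else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def select_candidate_pairs(pairs: pd.DataFrame, alpha: float = 0.10) -> pd.DataFrame:
    """Flag pairs significant in at least one group (inclusive threshold).

    ``selected`` is true when min(p_localized, p_metastatic) <= alpha,
    NaN-safe (a pair undefined in both groups is never selected).
    """
    out = pairs.copy()
    pmin = out[["p_localized", "p_metastatic"]].min(axis=1, skipna=True)
    out["p_min"] = pmin
    out["selected"] = pmin.notna() & (pmin <= alpha)
    return out


def pair_score(gene_vals, mirna_vals, mode: str = "difference") -> np.ndarray:
    """Per-sample pair score from -dCT values.

    ``difference`` (default): -dCT_gene - -dCT_miRNA, the log2 ratio of
    gene to miRNA relative expression.  ``quotient``: the literal
    arithmetic ratio, with samples whose denominator is within 1e-9 of
    zero set undefined (NaN).
    """
    g = np.asarray(gene_vals, dtype=float)
    m = np.asarray(mirna_vals, dtype=float)
    if g.shape != m.shape:
        raise ValueError("gene and miRNA vectors must have equal length")
    if mode == "difference":
        return g - m
    if mode == "quotient":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = g / m
        out[np.abs(m) < 1e-9] = np.nan
        return out
    raise ValueError(f"unknown pair score mode {mode!r}")


def pair_discrimination_auc(
    pairs: pd.DataFrame,
    gene_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    grouping,
    auc_cutoff: float = 0.8,
    mode: str = "difference",
) -> pd.DataFrame:
    """ROC AUC of each selected pair's score for metastatic vs localized.

    The AUC is reported as computed (metastatic = positive, higher score
    = positive) together with its flipped value; discrimination ability
    is orientation-free, so ``top_pair`` requires the orientation-
    corrected AUC max(a, 1-a) to exceed ``auc_cutoff`` strictly.
    Non-selected pairs get NaN AUC and are never top pairs.
    """
    samples = [s for s in gene_expr.samples if s in set(mirna_expr.samples)]
    groups = _group_series(grouping).reindex(samples)
    labels = (groups == "metastatic").astype(int).to_numpy()
    gvals = gene_expr.values.loc[samples]
    mvals = mirna_expr.values.loc[samples]
    out = pairs.copy()
    aucs = np.full(len(out), np.nan)
    flipped = np.full(len(out), np.nan)
    for i, row in enumerate(out.itertuples(index=False)):
        if not getattr(row, "selected", True):
            continue
        score = pair_score(
            gvals[row.gene].to_numpy(), mvals[row.mirna].to_numpy(), mode=mode
        )
        mask = np.isfinite(score)
        if mask.sum() == 0:
            raise InsufficientDataError(
                f"pair {row.gene}/{row.mirna}: all samples undefined"
            )
        if len(np.unique(labels[mask])) < 2:
            continue
        curve = roc_auc(score[mask], labels[mask], positive_class=1)
        aucs[i] = curve.auc
        flipped[i] = curve.auc_flipped
    out["pair_score_auc"] = aucs
    out["pair_score_auc_flipped"] = flipped
    oriented = np.fmax(aucs, flipped)
    out["pair_score_auc_oriented"] = oriented
    out["top_pair"] = out.get("selected", True) & (oriented > auc_cutoff)
    return out


def _corr_class(r: float, p: float, class_alpha: float) -> str:
    if not (np.isfinite(r) and np.isfinite(p)):
        return "unknown"
    if p <= class_alpha:
        return "positive" if r > 0 else ("negative" if r < 0 else "none")
    return "none"


def classify_disruption(
    pairs: pd.DataFrame, class_alpha: float = 0.05
) -> pd.DataFrame:
    """Assign per-group correlation classes and disruption flags.

    A group's class is *positive*/*negative* when its correlation is
    significant at ``class_alpha`` with that sign, else *none*; undefined
    correlations are *unknown* and excluded from disruption counts.
    ``disrupted`` = classes differ; ``repression_gain`` = localized class
    in {none, positive} and metastatic class negative.
    """
    out = pairs.copy()
    out["class_localized"] = [
        _corr_class(r, p, class_alpha)
        for r, p in zip(out["r_localized"], out["p_localized"])
    ]
    out["class_metastatic"] = [
        _corr_class(r, p, class_alpha)
        for r, p in zip(out["r_metastatic"], out["p_metastatic"])
    ]
    known = (out["class_localized"] != "unknown") & (
        out["class_metastatic"] != "unknown"
    )
    out["disrupted"] = known & (out["class_localized"] != out["class_metastatic"])
    out["repression_gain"] = (
        known
        & out["class_localized"].isin(["none", "positive"])
        & (out["class_metastatic"] == "negative")
    )
    return out


def screen_pairs(
    gene_expr: ExpressionMatrix,
    mirna_expr: ExpressionMatrix,
    grouping,
    alpha: float = 0.10,
    auc_cutoff: float = 0.8,
    class_alpha: float = 0.05,
    mode: str = "difference",
) -> pd.DataFrame:
    """Full pair screen: correlations, selection, AUC, disruption classes."""
    pairs = pairwise_group_correlations(gene_expr, mirna_expr, grouping)
    pairs = select_candidate_pairs(pairs, alpha=alpha)
    pairs = pair_discrimination_auc(
        pairs, gene_expr, mirna_expr, grouping, auc_cutoff=auc_cutoff, mode=mode
    )
    pairs = classify_disruption(pairs, class_alpha=class_alpha)
    return pairs
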