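"""Two-group differential expression, clinicopathological associations,
per-marker ROC tables and the cohort-comparability report.

Per target the contrast is a fold change via the comparative-CT method
(2^ddCT on group means of -dCT) and a two-sided t-test on the -dCT
values; FC > 1 means up in the first (metastatic) group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, SampleAnnotation
from .errors import ConfigError
from .quant import fold_change_between_groups
from .stats import (
    chi_square_test,
    fisher_exact,
    mann_whitney_u,
    roc_auc,
    two_sample_t_test,
)

__all__ = [
    "differential_expression",
    "clinicopath_association",
    "marker_auc_table",
    "cohort_comparability",
]


def _binary_series(
    ann: SampleAnnotation, spec, samples
) -> tuple[pd.Series, str]:
    """Resolve a contrast spec into a 0/1 series aligned to ``samples``.

    A spec is either a column name (column must be 0/1 or a group label)
    or ``(column, positive_levels)`` with an explicit level mapping.
    """
    if isinstance(spec, str):
        col, positive = spec, None
    else:
        col, positive = spec
    if col == "group":
        s = (ann.group == "metastatic").astype(int)
        label = "group (metastatic vs localized)"
    else:
        if col not in ann.data.columns:
            raise ConfigError(f"unknown annotation variable {col!r}")
        raw = ann.data[col]
        if positive is None:
            uniq = set(raw.dropna().unique())
            if not uniq <= {0, 1}:
                raise ConfigError(
                    f"variable {col!r} is not binary; supply (column, positive_levels)"
                )
            s = raw.astype(int)
            label = f"{col} (yes vs no)"
        else:
            positive = set(positive if isinstance(positive, (set, list, tuple)) else [positive])
            s = raw.isin(positive).astype(int)
            label = f"{col} ({'+'.join(map(str, sorted(positive)))} vs rest)"
    return s.reindex(samples), label


def differential_expression(
    expr: ExpressionMatrix,
    grouping: SampleAnnotation | pd.Series,
    alpha: float = 0.05,
    variant: str = "pooled",
) -> pd.DataFrame:
    """Per-target two-group contrast (metastatic vs localized).

    Returns one row per target with ``fc``, ``log2fc``, ``p_value``,
    ``direction`` and a ``significant`` flag (p < alpha), sorted by
    p-value; targets with fewer than two usable values in either group
    are reported as untestable rather than dropped.
    """
    groups = grouping.group if isinstance(grouping, SampleAnnotation) else grouping
    groups = groups.reindex(expr.values.index)
    rows = []
    for target in expr.targets:
        vals = expr.values[target]
        x = vals[groups == "metastatic"].dropna()
        y = vals[groups == "localized"].dropna()
        row = {
            "target": target,
            "n_metastatic": len(x),
            "n_localized": len(y),
        }
        if len(x) < 2 or len(y) < 2:
            row.update(
                fc=np.nan, log2fc=np.nan, p_value=np.nan, direction="",
                significant=False, untestable=True,
                reason=f"insufficient data ({len(x)}/{len(y)})",
            )
        else:
            fc = fold_change_between_groups(expr, groups, target)
            res = two_sample_t_test(x, y, variant=variant)
            row.update(
                fc=fc,
                log2fc=float(np.log2(fc)),
                p_value=res.p_value,
                direction="up" if fc > 1 else "down",
                significant=bool(res.p_value < alpha),
                untestable=False,
                reason="",
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["untestable", "p_value", "target"], na_position="last"
    ).reset_index(drop=True)


def clinicopath_association(
    expr: ExpressionMatrix,
    ann: SampleAnnotation,
    variables: list,
    alpha: float = 0.05,
    variant: str = "pooled",
) -> pd.DataFrame:
    """Associate each target with each clinicopathological contrast.

    ``variables`` entries are contrast specs (see module docstring of the
    binary resolver): a binary column name or ``(column, positive_levels)``.
    Output is one row per (variable, target) shaped like a long-format
    association table; contrasts leaving fewer than two samples on a side
    are flagged untestable.
    """
    frames = []
    for spec in variables:
        s, label = _binary_series(ann, spec, expr.values.index)
        groups = s.map({1: "metastatic", 0: "localized"})
        de = differential_expression(expr, groups, alpha=alpha, variant=variant)
        de.insert(0, "variable", label)
        frames.append(de)
    return pd.concat(frames, ignore_index=True)


def marker_auc_table(
    expr: ExpressionMatrix,
    labels: SampleAnnotation | pd.Series,
    positive: str = "metastatic",
) -> pd.DataFrame:
    """Per-target ROC AUC for discriminating the positive class.

    AUC is reported as computed from the -dCT scores (higher expression
    scores toward the positive class) together with the flipped value;
    sorted descending by AUC.
    """
    groups = labels.group if isinstance(labels, SampleAnnotation) else labels
    groups = groups.reindex(expr.values.index)
    rows = []
    for target in expr.targets:
        vals = expr.values[target]
        mask = vals.notna() & groups.notna()
        y = (groups[mask] == positive).astype(int)
        if y.nunique() < 2 or mask.sum() < 3:
            rows.append(
                {"target": target, "auc": np.nan, "auc_flipped": np.nan,
                 "n_pos": int(y.sum()), "n_neg": int((1 - y).sum()),
                 "untestable": True}
            )
            continue
        curve = roc_auc(vals[mask].to_numpy(), y.to_numpy(), positive_class=1)
        rows.append(
            {"target": target, "auc": curve.auc, "auc_flipped": curve.auc_flipped,
             "n_pos": curve.n_pos, "n_neg": curve.n_neg, "untestable": False}
        )
    out = pd.DataFrame(rows)
    return out.sort_values(
        ["untestable", "auc"], ascending=[True, False], na_position="last"
    ).reset_index(drop=True)


@dataclass
class VariableSpec:
    """How to summarise/test one annotation variable in the comparability report."""

    column: str
    kind: str = "binary"  # binary | categorical | continuous
    positive_levels: tuple = ()


def cohort_comparability(
    ann: SampleAnnotation,
    split: pd.Series,
    variables: list[VariableSpec],
    expected_min: float = 2.0,
) -> pd.DataFrame:
    """Compare the two sides of a sample partition variable by variable.

    Binary/categorical variables are tested with the Pearson chi-square
    test (no continuity correction); a 2x2 table with any expected cell
    below ``expected_min`` switches to Fisher's exact test.  The default
    threshold of 2 reproduces the chi-square/Fisher choices of the
    reference cohort report (chi-square was retained down to expected
    cells of ~2.75; only a table with a 1.83 expected cell fell back to
    Fisher); the textbook value 5 is available via the parameter.
    Continuous variables use the Mann-Whitney test.  The report carries
    per-side counts (or medians) and the p-value, one row per variable.
    """
    split = split.reindex(ann.data.index)
    sides = list(pd.unique(split.dropna()))
    if len(sides) != 2:
        raise ConfigError("split must have exactly two levels")
    a_mask = split == sides[0]
    b_mask = split == sides[1]
    rows = []
    for spec in variables:
        if spec.column not in ann.data.columns:
            raise ConfigError(f"unknown annotation variable {spec.column!r}")
        col = ann.data[spec.column]
        row: dict = {"variable": spec.column, "kind": spec.kind,
                     "side_a": str(sides[0]), "side_b": str(sides[1])}
        if spec.kind == "continuous":
            x = col[a_mask].dropna().to_numpy(dtype=float)
            y = col[b_mask].dropna().to_numpy(dtype=float)
            res = mann_whitney_u(x, y)
            row.update(
                summary_a=f"median {np.median(x):.3g}",
                summary_b=f"median {np.median(y):.3g}",
                test=res.method, p_value=res.p_value,
            )
        elif spec.kind in ("binary", "categorical"):
            if spec.kind == "binary":
                pos = set(spec.positive_levels) or {1}
                ca = [int(col[a_mask].isin(pos).sum()),
                      int((~col[a_mask].isin(pos)).sum())]
                cb = [int(col[b_mask].isin(pos).sum()),
                      int((~col[b_mask].isin(pos)).sum())]
                table = np.array([ca, cb])
                row.update(
                    summary_a=f"{ca[0]}/{sum(ca)}", summary_b=f"{cb[0]}/{sum(cb)}"
                )
            else:
                levels = sorted(col.dropna().unique())
                table = np.array(
                    [[int((col[m] == lv).sum()) for lv in levels]
                     for m in (a_mask, b_mask)]
                )
                row.update(
                    summary_a="/".join(str(v) for v in table[0]),
                    summary_b="/".join(str(v) for v in table[1]),
                )
            table = table[:, table.sum(axis=0) > 0]  # drop empty levels
            if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
                row.update(test="none", p_value=np.nan)
            else:
                expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
                if table.shape == (2, 2) and (expected < expected_min).any():
                    res = fisher_exact(table)
                else:
                    res = chi_square_test(table)
                row.update(test=res.method, p_value=res.p_value)
        else:
            raise ConfigError(f"unknown variable kind {spec.kind!r}")
        rows.append(row)
    return pd.DataFrame(rows)
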