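"""Figures: pairwise-correlation dot matrix, pair-AUC scatter, KM curves."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .surv import KmCurve

__all__ = ["correlation_dot_matrix", "pair_auc_scatter", "km_plot"]


def correlation_dot_matrix(pairs: pd.DataFrame, group: str = "metastatic", ax=None):
    """Dot matrix of per-pair Pearson r in one group: dot size and colour
    encode |r| and sign (genes on x, miRNAs on y)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(12, 3))
    genes = sorted(pairs["gene"].unique())
    mirnas = sorted(pairs["mirna"].unique())
    gi = {g: i for i, g in enumerate(genes)}
    mi = {m: i for i, m in enumerate(mirnas)}
    r = pairs[f"r_{group}"].to_numpy()
    x = pairs["gene"].map(gi)
    y = pairs["mirna"].map(mi)
    sc = ax.scatter(x, y, s=120 * np.abs(np.nan_to_num(r)), c=r,
                    cmap="RdBu_r", vmin=-1, vmax=1)
    ax.set_xticks(range(len(genes)))
    ax.set_xticklabels(genes, rotation=90, fontsize=5)
    ax.set_yticks(range(len(mirnas)))
    ax.set_yticklabels(mirnas, fontsize=7)
    ax.set_title(f"Pearson r ({group})")
    ax.figure.colorbar(sc, ax=ax, label="r")
    return ax


def pair_auc_scatter(pairs: pd.DataFrame, auc_cutoff: float = 0.8, ax=None):
    """Scatter of per-pair group correlations coloured by pair-score AUC."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    sel = pairs[pairs.get("selected", True)]
    sc = ax.scatter(sel["r_localized"], sel["r_metastatic"],
                    c=sel["pair_score_auc"], cmap="viridis", vmin=0.5, vmax=1.0)
    top = sel[sel["pair_score_auc"] > auc_cutoff]
    for row in top.itertuples(index=False):
        ax.annotate(f"{row.mirna}/{row.gene}",
                    (row.r_localized, row.r_metastatic), fontsize=6)
    ax.set_xlabel("r (localized)")
    ax.set_ylabel("r (metastatic)")
    ax.figure.colorbar(sc, ax=ax, label="pair score AUC")
    return ax


def km_plot(curves: dict[str, KmCurve], title: str = "", ax=None):
    """Step plot of one or more KM curves with censoring marks."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for label, km in curves.items():
        t = np.repeat(np.r_[0.0, km.times], 2)[1:]
        s = np.repeat(np.r_[1.0, km.survival], 2)[:-1]
        line, = ax.plot(t, s, label=label)
        for ct in km.censor_times:
            ax.plot(ct, km.survival_at(ct), marker="|", color=line.get_color())
    ax.set_ylim(0, 1.05)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("survival probability")
    if title:
        ax.set_title(title)
    ax.legend()
    return ax
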