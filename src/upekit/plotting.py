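"""Manhattan plots for per-phenotype summary statistics."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def manhattan_plot(
    table: pd.DataFrame,
    phenotype_id: str | None = None,
    p_gw: float = 5e-8,
    p_sw: float | None = None,
    ax=None,
    path=None,
):
    """-log10(p) against cumulative genomic position, coloured by chromosome."""
    t = table
    if phenotype_id is not None:
        t = t[t["phenotype_id"] == phenotype_id]
    t = t.dropna(subset=["p"]).copy()
    chrom_key = t["chrom"].astype(str).str.replace("chr", "", regex=False)
    numeric = pd.to_numeric(chrom_key, errors="coerce")
    t["_chrom_order"] = numeric.fillna(99)
    t = t.sort_values(["_chrom_order", "pos"])
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(t.groupby("_chrom_order", sort=True)):
        x = grp["pos"].to_numpy() + offset
        ax.scatter(x, -np.log10(grp["p"]), s=4, color=["#2b6a99", "#888888"][i % 2])
        ticks.append(x.mean())
        labels.append(str(grp["chrom"].iloc[0]))
        offset = x.max() + 1
    ax.axhline(-np.log10(p_gw), color="red", lw=0.8, ls="--")
    if p_sw is not None:
        ax.axhline(-np.log10(p_sw), color="purple", lw=0.8, ls=":")
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(P)$")
    if phenotype_id:
        ax.set_title(phenotype_id, fontsize=9)
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(str(path), dpi=120)
        plt.close(ax.figure)
    return ax
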