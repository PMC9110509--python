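"""Matplotlib renderings of the stratified Q-Q curves and Manhattan tables."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from pleiocfdr.annotate import REFERENCE_NEGLOG_FDR
from pleiocfdr.cfdr import QqStrata


def plot_stratified_qq(strata: QqStrata, path) -> None:
    """Stratified conditional Q-Q plot; identity line marks no enrichment."""
    fig, ax = plt.subplots(figsize=(5, 5))
    lim = float(strata.grid.max())
    ax.plot([0, lim], [0, lim], "k--", lw=1, label="null (x = y)")
    for t in strata.thresholds:
        ax.plot(strata.grid, strata.curves[t], lw=1.2, label=f"p < {t:g} (n={strata.sizes[t]})")
    ax.set_xlabel(r"empirical $-\log_{10}(q)$")
    ax.set_ylabel(r"nominal $-\log_{10}(p)$")
    ax.set_title(f"{strata.principal_label} | {strata.conditional_label}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_manhattan(table: pd.DataFrame, meta: dict, path) -> None:
    """Manhattan plot of -log10 FDR with the 1.3 significance guide line."""
    fig, ax = plt.subplots(figsize=(9, 3.2))
    colors = np.array(["#3b5b92", "#8aa8c9"])
    ax.scatter(
        table["x"], table["neglog10_fdr"], s=4, c=colors[table["color_index"] % 2], lw=0
    )
    ax.axhline(meta.get("reference_line", REFERENCE_NEGLOG_FDR), color="red", lw=1)
    ax.set_xlabel("genomic position")
    ax.set_ylabel(r"$-\log_{10}$ FDR")
    ax.set_title(meta.get("mode", ""))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_finemap(table: pd.DataFrame, path) -> None:
    """Posterior probability of causality against position within the locus."""
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.scatter(table["pos"], table["posterior"], s=10)
    best = table.loc[table["posterior"].idxmax()]
    ax.annotate(best["snp_id"], (best["pos"], best["posterior"]), fontsize=8)
    ax.set_xlabel("position (bp)")
    ax.set_ylabel("posterior probability")
    ax.set_ylim(0, 1.05)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
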