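"""Rendered volcano and MA plots for enrichment tables."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from turboprox.enrichment import EnrichmentTable, ma_table, volcano_table


def _scatter(ax, df, x, y, xlabel, ylabel):
    hit = df[df["significant"]]
    rest = df[~df["significant"]]
    ax.scatter(rest[x], rest[y], s=8, c="0.6", label="not significant")
    ax.scatter(hit[x], hit[y], s=12, c="crimson", label="significant")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False, fontsize=8)


def plot_volcano(table: EnrichmentTable, path: str | Path) -> None:
    """-log10 p against log2 fold change (sample/control), hits highlighted."""
    df = volcano_table(table)
    fig, ax = plt.subplots(figsize=(5, 4))
    _scatter(ax, df, "log2_fc", "neg_log10_p",
             "log2 fold change (sample/control)", "-log10 p-value")
    ax.axvline(table.thresholds.min_log2_fc, ls="--", lw=0.8, c="0.4")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ma(table: EnrichmentTable, path: str | Path) -> None:
    """Average log2 sample intensity against log2 fold change."""
    df = ma_table(table)
    fig, ax = plt.subplots(figsize=(5, 4))
    _scatter(ax, df, "mean_log2_sample", "log2_fc",
             "mean log2 LFQ intensity (sample)", "log2 fold change")
    ax.axhline(table.thresholds.min_log2_fc, ls="--", lw=0.8, c="0.4")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
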