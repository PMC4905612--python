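"""Basic renderings of the three pattern plots and the correlation circle.

These are intentionally simple matplotlib renderings of the plot-ready
tables the analysis modules emit; the tables themselves are the primary
output for anyone who wants publication-grade figures.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["periodobar_plot", "clustergram_plot", "chromogram_plot", "correlation_circle_plot"]


def periodobar_plot(table: pd.DataFrame, alpha: float, path: str | Path) -> None:
    """-log10 corrected p versus period (log axis), threshold dashed."""
    fig, ax = plt.subplots(figsize=(8, 3.5))
    finite = table.replace(np.inf, table.loc[np.isfinite(table.neg_log10_p), "neg_log10_p"].max())
    ax.plot(finite.period, finite.neg_log10_p, lw=0.5, color="0.4")
    sig = finite[finite.significant]
    if len(sig):
        ax.vlines(sig.period, 0, sig.neg_log10_p, color="tab:red", lw=1.5)
    ax.axhline(-np.log10(alpha), ls="--", color="0.2", lw=0.8)
    ax.set_xscale("log")
    ax.set_xlabel("period (bp)")
    ax.set_ylabel("-log10 corrected p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def clustergram_plot(table: pd.DataFrame, period: float, path: str | Path) -> None:
    """Features unrolled along the phase axis, coloured by cluster."""
    fig, ax = plt.subplots(figsize=(7, max(2.5, 0.18 * len(table))))
    cmap = plt.get_cmap("tab10")
    for i, row in table.reset_index(drop=True).iterrows():
        color = "0.6" if row.cluster == 0 else cmap((int(row.cluster) - 1) % 10)
        ax.plot([row.phase], [i], "o", color=color, ms=5)
        ax.hlines(i, 0, period, color="0.9", lw=0.5, zorder=0)
    ax.set_yticks(range(len(table)))
    ax.set_yticklabels([f"{n} ({p})" for n, p in zip(table.name, table.position)], fontsize=6)
    sec = ax.secondary_yaxis("right")
    sec.set_yticks(range(len(table)))
    sec.set_yticklabels([f"{s:.2f}" for s in table.positional_score], fontsize=6)
    ax.set_xlim(0, period)
    ax.set_xlabel("phase (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def chromogram_plot(
    table: pd.DataFrame, genome_length: int, path: str | Path,
    boundaries: list[int] | None = None,
) -> None:
    """Horizontal bars for periodic regions along the genome axis."""
    fig, ax = plt.subplots(figsize=(9, max(2.0, 0.4 * (len(table) + 1))))
    if len(table):
        pvals = -np.log10(np.maximum(table.p_corrected.to_numpy(float), 1e-300))
        norm = plt.Normalize(pvals.min(), max(pvals.max(), pvals.min() + 1))
        cmap = plt.get_cmap("viridis")
        for i, (row, nlp) in enumerate(zip(table.itertuples(), pvals)):
            ax.barh(
                i,
                row.end - row.start + 1,
                left=row.start,
                height=0.3 + 0.05 * min(row.n_features, 10),
                color=cmap(norm(nlp)),
            )
            ax.text(row.start, i + 0.35, f"p={row.period:.0f}, g={row.n_features}", fontsize=6)
    for b in boundaries or []:
        ax.axvline(b, ls="--", color="0.3", lw=0.8)
    ax.set_xlim(1, genome_length)
    ax.set_yticks([])
    ax.set_xlabel("genome position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def correlation_circle_plot(cca, path: str | Path) -> None:
    """First-two-variate loadings of both blocks on the unit circle."""
    fig, ax = plt.subplots(figsize=(5, 5))
    theta = np.linspace(0, 2 * np.pi, 200)
    ax.plot(np.cos(theta), np.sin(theta), color="0.8", lw=0.8)
    for loadings, color, label in (
        (cca.x_loadings, "tab:red", "position"),
        (cca.y_loadings, "tab:blue", "sequence"),
    ):
        first = True
        for name, row in loadings.iterrows():
            ax.plot(row.variate1, row.variate2, "o", color=color,
                    label=label if first else None)
            ax.annotate(str(name), (row.variate1, row.variate2), fontsize=6)
            first = False
    ax.axhline(0, color="0.9", lw=0.5)
    ax.axvline(0, color="0.9", lw=0.5)
    ax.set_xlim(-1.1, 1.1)
    ax.set_ylim(-1.1, 1.1)
    ax.set_xlabel("variate 1")
    ax.set_ylabel("variate 2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
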