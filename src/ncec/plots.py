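"""Optional diagnostic plots (correlation heatmaps, rank-binned profiles)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .category_stats import CorrelationMatrix, ModifiedHistogram

__all__ = ["plot_correlation_heatmap", "plot_modified_histogram"]


def plot_correlation_heatmap(
    corr: CorrelationMatrix, path: str | Path, scaled: bool = True
) -> None:
    mat = corr.scaled if scaled else corr.raw
    fig, ax = plt.subplots(figsize=(5.5, 4.8))
    im = ax.imshow(mat.to_numpy(), vmin=0 if scaled else -1, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(mat.columns)), mat.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(mat.index)), mat.index, fontsize=7)
    ax.set_title(f"{corr.category} ({'scaled' if scaled else 'raw'})")
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_modified_histogram(hist: ModifiedHistogram, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    x = hist.table["start_rank"] if "start_rank" in hist.table else hist.table.index
    for mutant in hist.denominators:
        ax.plot(x, hist.table[f"norm_{mutant}"], marker="o", label=mutant)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("wildtype expression rank")
    ax.set_ylabel("normalized correlation coefficient")
    ax.set_title(hist.category)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
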