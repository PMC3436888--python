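"""Optional matplotlib figures; numbers (TSV), not pixels, are the test surface."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errorsim import ORSurface


def concordance_heatmap(matrix: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Render a pairwise concordance matrix as a heatmap PNG."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    from matplotlib.figure import Figure

    fig = Figure(figsize=(max(4, 0.3 * len(matrix)), max(3.5, 0.3 * len(matrix))))
    ax = fig.add_subplot(111)
    im = ax.imshow(matrix.to_numpy(), vmin=matrix.to_numpy().min(), vmax=1.0, cmap="viridis")
    ax.set_xticks(range(len(matrix.columns)), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(matrix.index)), matrix.index, fontsize=6)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="concordance")
    fig.tight_layout()
    fig.savefig(path, dpi=150)


def surface_plot(surface: ORSurface, path: str | Path) -> None:
    """Top-percentile OR vs concordance, one curve per minor allele frequency."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    from matplotlib.figure import Figure

    fig = Figure(figsize=(6, 4))
    ax = fig.add_subplot(111)
    for i, maf in enumerate(surface.maf_grid):
        ax.plot(surface.concordance_grid, surface.values[i], label=f"MAF {maf:g}")
    ax.set_xlabel("genotype concordance")
    ax.set_ylabel(f"top {100 * (1 - surface.percentile):g}% odds ratio")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
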