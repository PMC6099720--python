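"""MA-plot and motif-displacement barcode rendering (matplotlib, Agg)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .differential import DifferentialRecord, ma_table
from .mdscore import DisplacementHistogram

__all__ = ["barcode_plot", "ma_plot"]

# strong/weak increased follow the red/maroon convention; decreased is purple
_CLASS_STYLE = {
    "up_strong": ("red", 18, 3),
    "up_weak": ("maroon", 14, 2),
    "down_strong": ("purple", 18, 3),
    "down_weak": ("mediumorchid", 14, 2),
    "ns": ("0.6", 8, 1),
}


def ma_plot(records: Sequence[DifferentialRecord], path: str | Path) -> Path:
    """Scatter delta MD-score against log10 motif abundance near peaks."""
    table = ma_table(records)
    fig, ax = plt.subplots(figsize=(5, 4))
    for sig_class, group in table.groupby("sig_class"):
        color, size, zorder = _CLASS_STYLE.get(sig_class, ("0.6", 8, 1))
        ax.scatter(
            group["x"],
            group["delta_md"],
            s=size,
            c=color,
            label=sig_class,
            zorder=zorder,
            linewidths=0,
        )
    ax.axhline(0.0, color="0.8", lw=0.8, zorder=0)
    ax.set_xlabel("log10(motifs within large window + 1)")
    ax.set_ylabel("Δ MD-score (B − A)")
    ax.legend(fontsize=7, frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def barcode_plot(hist: DisplacementHistogram, path: str | Path) -> Path:
    """Render a displacement histogram as bar panel plus heatmap strip.

    The strip is the 'barcode' view: one row of bins colored by motif-instance
    count (darker blue = more instances near the peak midpoint).
    """
    centers = (hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2.0
    fig, (ax_bar, ax_strip) = plt.subplots(
        2,
        1,
        figsize=(5, 3),
        sharex=True,
        gridspec_kw={"height_ratios": [4, 1], "hspace": 0.08},
    )
    width = hist.bin_edges[1] - hist.bin_edges[0]
    ax_bar.bar(centers, hist.counts, width=width, color="steelblue")
    ax_bar.set_ylabel("motif instances")
    ax_bar.set_title(hist.motif_id, fontsize=9)
    ax_strip.imshow(
        hist.counts[None, :],
        aspect="auto",
        cmap="Blues",
        extent=(hist.bin_edges[0], hist.bin_edges[-1], 0, 1),
    )
    ax_strip.set_yticks([])
    ax_strip.set_xlabel("distance from peak midpoint (bp)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
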