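"""Small matplotlib helpers shared by the CLI stages.

All figure output is made byte-deterministic (fixed svg hashsalt,
stripped date metadata) so reruns on identical inputs reproduce
identical files.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "metaomix"
import matplotlib.pyplot as plt
import pandas as pd

__all__ = ["composition_barplot", "save_deterministic"]


def save_deterministic(fig, path) -> None:
    meta = {"Date": None} if str(path).endswith(".svg") else None
    fig.savefig(path, metadata=meta)
    plt.close(fig)


def composition_barplot(plot_data: pd.DataFrame, path, title: str = "Taxonomic composition"):
    """Stacked relative-abundance barplot from long-format
    (sample, taxon, abundance) composition data."""
    wide = plot_data.pivot(index="sample", columns="taxon", values="abundance").fillna(0.0)
    # keep taxon order of first appearance, "Other" last
    order = list(dict.fromkeys(plot_data["taxon"]))
    if "Other" in order:
        order = [t for t in order if t != "Other"] + ["Other"]
    wide = wide[order]
    fig, ax = plt.subplots(figsize=(max(6, 0.45 * len(wide)), 4.5))
    bottom = pd.Series(0.0, index=wide.index)
    cmap = plt.get_cmap("tab20")
    for i, taxon in enumerate(wide.columns):
        color = "#bdbdbd" if taxon == "Other" else cmap(i % 20)
        ax.bar(wide.index, wide[taxon], bottom=bottom, label=taxon, color=color, width=0.8)
        bottom += wide[taxon]
    ax.set_ylabel("relative abundance")
    ax.set_ylim(0, 1)
    ax.set_title(title, fontsize=10)
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    ax.legend(fontsize=7, bbox_to_anchor=(1.02, 1), loc="upper left")
    fig.tight_layout()
    save_deterministic(fig, path)
    return path
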