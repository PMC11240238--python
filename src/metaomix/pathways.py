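"""Cross-omics pathway-level integration via split-node tables.

Each omics layer's features are aggregated to shared functional
identifiers (KEGG Orthology / Enzyme Commission numbers), each layer is
total-sum scaled per sample, and the log2 ratio of mean abundance
between two phenotype groups is computed per identifier. Matched
identifiers then populate a pathway's nodes, one column per layer: the
"split node" view, where the same enzymatic step can show, say, lower
gene abundance but higher protein abundance between groups.

A feature annotated with k identifiers contributes its full abundance
to each of them (KEGG-mapper convention); fractional splitting is
available via ``split_weights=True``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AbundanceMatrix, MetaomixError, PathwayDefinition, SampleMetadata, ValidationError

__all__ = [
    "LayerRatios",
    "SplitNodeTable",
    "aggregate_to_function",
    "layer_log2_ratio",
    "assemble_split_nodes",
    "export_split_heatmap",
]


def aggregate_to_function(
    m: AbundanceMatrix, split_weights: bool = False
) -> tuple[AbundanceMatrix, pd.Series, int]:
    """Sum feature abundances into their annotated KO/EC identifiers.

    Returns (function-level matrix, per-id supporting-feature counts,
    number of unannotated features dropped). With ``split_weights`` a
    feature's abundance is divided evenly among its identifiers instead
    of contributing fully to each.
    """
    if m.feature_annotations is None:
        raise MetaomixError("matrix has no feature annotations")
    sums: dict[str, np.ndarray] = {}
    support: dict[str, int] = {}
    dropped = 0
    for feat in m.features:
        ann = m.feature_annotations.loc[feat]
        ids = sorted(set(ann.get("ko", frozenset()) or ()) | set(ann.get("ec", frozenset()) or ()))
        if not ids:
            dropped += 1
            continue
        row = m.values.loc[feat].to_numpy(dtype=float)
        weight = 1.0 / len(ids) if split_weights else 1.0
        for fid in ids:
            if fid in sums:
                sums[fid] = sums[fid] + row * weight
            else:
                sums[fid] = row * weight
            support[fid] = support.get(fid, 0) + 1
    if not sums:
        raise MetaomixError("no annotated features to aggregate")
    df = pd.DataFrame.from_dict(sums, orient="index", columns=m.samples).sort_index()
    return (
        AbundanceMatrix(df, layer=m.layer),
        pd.Series(support).sort_index(),
        dropped,
    )


@dataclass
class LayerRatios:
    """Per-identifier log2 group-B/group-A abundance ratios for one layer."""

    layer: str
    ratios: pd.Series  # id -> log2 ratio
    group_a: str
    group_b: str
    support: pd.Series | None = None
    pseudocount: float = 0.0

    def __contains__(self, fid: str) -> bool:
        return fid in self.ratios.index


def layer_log2_ratio(
    m_fn: AbundanceMatrix,
    meta: SampleMetadata,
    group_a: str,
    group_b: str,
    pseudocount: float | None = None,
    support: pd.Series | None = None,
) -> LayerRatios:
    """log2 of (mean group-B abundance + eps) / (mean group-A + eps).

    The matrix is total-sum scaled per sample first, making the ratios
    library-size invariant. ``pseudocount`` defaults to half the
    smallest nonzero normalized value in the layer, which keeps every
    ratio finite.
    """
    if meta.phenotype is None:
        raise ValidationError("metadata needs a designated phenotype column")
    meta = meta.aligned_to(m_fn.samples)
    pheno = meta.table[meta.phenotype].astype(str)
    for g in (group_a, group_b):
        if g not in set(pheno):
            raise MetaomixError(f"group {g!r} not present in phenotype column")
    totals = m_fn.values.sum(axis=0)
    zero = totals[totals <= 0].index.tolist()
    if zero:
        raise ValidationError(f"samples with zero total abundance: {zero}")
    rel = m_fn.values.div(totals, axis=1)
    if pseudocount is None:
        nonzero = rel.to_numpy()[rel.to_numpy() > 0]
        pseudocount = float(nonzero.min()) / 2.0 if nonzero.size else 0.5
    mean_a = rel.loc[:, pheno[pheno == group_a].index].mean(axis=1)
    mean_b = rel.loc[:, pheno[pheno == group_b].index].mean(axis=1)
    # difference-of-logs form keeps group-swap antisymmetry bitwise exact
    ratios = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)
    layer = m_fn.layer or "layer"
    return LayerRatios(
        layer=layer,
        ratios=ratios,
        group_a=group_a,
        group_b=group_b,
        support=support,
        pseudocount=pseudocount,
    )


@dataclass
class SplitNodeTable:
    """Pathway node x omics layer matrix of log2 ratios.

    A cell is present (non-NaN) iff at least one of the node's KO/EC
    identifiers has a ratio in that layer.
    """

    pathway_id: str
    values: pd.DataFrame  # nodes x layers, NaN = absent
    labels: pd.Series  # node -> label
    matched_ids: dict = field(default_factory=dict)  # (node, layer) -> tuple of ids

    def to_tsv(self, path: str | os.PathLike) -> None:
        df = self.values.copy()
        df.insert(0, "label", self.labels)
        df.index.name = "node"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, pathway_id: str = "") -> "SplitNodeTable":
        df = pd.read_csv(path, sep="\t", index_col=0)
        labels = df.pop("label")
        return cls(pathway_id=pathway_id, values=df, labels=labels)


def assemble_split_nodes(
    pathway: PathwayDefinition,
    layers: list[LayerRatios],
    combine: str = "mean",
) -> SplitNodeTable:
    """Fill each pathway node with per-layer combined ratios.

    ``combine`` is "mean" (average over the node's identifiers matched
    in that layer) or "max_abs" (the matched ratio of largest
    magnitude).
    """
    if not pathway.nodes:
        raise MetaomixError(f"pathway {pathway.id!r} has no nodes")
    if not layers:
        raise MetaomixError("need at least one layer of ratios")
    if combine not in ("mean", "max_abs"):
        raise ValueError(f"unknown combine rule {combine!r}")
    layer_names = [lr.layer for lr in layers]
    if len(set(layer_names)) != len(layer_names):
        raise MetaomixError(f"duplicate layer labels: {layer_names}")
    values = pd.DataFrame(
        np.nan, index=list(pathway.nodes), columns=layer_names, dtype=float
    )
    labels = pd.Series({nid: node.label for nid, node in pathway.nodes.items()})
    matched: dict = {}
    for nid, node in pathway.nodes.items():
        for lr in layers:
            hits = sorted(fid for fid in node.ids if fid in lr.ratios.index)
            if not hits:
                continue
            vals = lr.ratios.loc[hits]
            if combine == "mean":
                cell = float(vals.mean())
            else:
                cell = float(vals.iloc[int(np.argmax(np.abs(vals.to_numpy())))])
            values.loc[nid, lr.layer] = cell
            matched[(nid, lr.layer)] = tuple(hits)
    return SplitNodeTable(
        pathway_id=pathway.id, values=values, labels=labels, matched_ids=matched
    )


def export_split_heatmap(
    table: SplitNodeTable, path: str | os.PathLike, tsv_path: str | os.PathLike | None = None
):
    """Render the split-node table as a node x layer heatmap.

    Diverging palette centred at zero, red = higher in group B, green =
    lower (matching the KEGG-map colouring convention). Writes a
    bit-exact TSV companion next to the figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if tsv_path is None:
        tsv_path = os.path.splitext(str(path))[0] + ".tsv"
    table.to_tsv(tsv_path)

    data = table.values.to_numpy(dtype=float)
    span = np.nanmax(np.abs(data)) if np.isfinite(data).any() else 1.0
    span = span if span > 0 else 1.0
    fig, ax = plt.subplots(
        figsize=(2 + 0.9 * len(table.values.columns), 1 + 0.35 * len(table.values))
    )
    masked = np.ma.masked_invalid(data)
    cmap = plt.get_cmap("RdYlGn_r").copy()
    cmap.set_bad("#d9d9d9")
    im = ax.imshow(masked, cmap=cmap, vmin=-span, vmax=span, aspect="auto")
    ax.set_xticks(range(len(table.values.columns)), table.values.columns)
    ax.set_yticks(
        range(len(table.values)),
        [f"{nid} ({table.labels[nid]})" for nid in table.values.index],
        fontsize=7,
    )
    ax.set_title(f"Pathway {table.pathway_id}: log2 ratio by omics layer", fontsize=9)
    fig.colorbar(im, ax=ax, label="log2 ratio (B vs A)")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)
    return path
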