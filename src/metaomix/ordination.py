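"""Joint multi-block ordination of omics layers.

Places samples from two or more omics layers on a single ordination
plot together with metadata covariates. Each block (layer) is CLR
transformed (by default), feature-centred, scaled to unit total
variance so no layer dominates, then the blocks are concatenated and
decomposed by SVD. Sample scores are shared across blocks; loadings
split back per block; numeric covariates project as correlation arrows
and categorical covariates as level centroids.

This is a transparent multi-block principal-component ordination; it
deliberately is not a model-based compositional integration method,
but serves the same joint-visualization role.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core import AbundanceMatrix, MetaomixError, SampleMetadata

__all__ = ["OrdinationResult", "multiblock_ordinate", "biplot_data", "plot_biplot"]


@dataclass
class OrdinationResult:
    """Result of a multi-block ordination."""

    scores: pd.DataFrame  # samples x d
    loadings: dict  # block name -> features x d DataFrame
    block_weights: dict  # block name -> scaling applied
    explained: np.ndarray  # variance fractions per axis, nonincreasing
    covariate_arrows: pd.DataFrame  # numeric covariates x d (correlations)
    level_centroids: pd.DataFrame  # (covariate, level) x d mean scores
    processed: pd.DataFrame | None = None  # concatenated pre-SVD matrix

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]


def _clr(values: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-sample centred log-ratio (base 2); pseudocount added on the
    raw scale when zeros are present."""
    v = values.copy()
    if (v.to_numpy() == 0).any():
        v = v + pseudocount
    totals = v.sum(axis=0)
    if (totals <= 0).any():
        raise MetaomixError("samples with nonpositive totals in CLR")
    rel = v.div(totals, axis=1)
    logged = np.log2(rel)
    return logged.sub(logged.mean(axis=0), axis=1)


def multiblock_ordinate(
    layers: Mapping[str, AbundanceMatrix | pd.DataFrame],
    meta: SampleMetadata | None = None,
    d: int = 2,
    transform: str = "clr",
    scale_blocks: bool = True,
) -> OrdinationResult:
    """Joint SVD ordination of several feature blocks sharing samples.

    Sample sets are intersected across blocks (with a warning when they
    differ); fewer than 3 shared samples is an error. ``transform`` is
    "clr" or "none". The deterministic sign convention makes the
    largest-magnitude loading entry of each axis positive.
    """
    if not layers:
        raise MetaomixError("need at least one layer")
    frames = {
        name: (m.values if isinstance(m, AbundanceMatrix) else m)
        for name, m in layers.items()
    }
    for name, df in frames.items():
        if df.shape[0] < 2:
            raise MetaomixError(f"block {name!r} needs at least 2 features")
    shared = None
    for df in frames.values():
        cols = list(df.columns)
        shared = cols if shared is None else [s for s in shared if s in cols]
    if any(set(shared) != set(df.columns) for df in frames.values()):
        warnings.warn("layers have differing sample sets; using the intersection")
    if len(shared) < 3:
        raise MetaomixError(f"only {len(shared)} shared samples; need at least 3")

    blocks = {}
    weights = {}
    for name, df in frames.items():
        sub = df.loc[:, shared]
        if transform == "clr":
            sub = _clr(sub)
        elif transform != "none":
            raise ValueError(f"unknown transform {transform!r}")
        # samples x features, feature-centred
        X = sub.T.to_numpy(dtype=float)
        X = X - X.mean(axis=0, keepdims=True)
        total_var = (X**2).sum() / max(len(shared) - 1, 1)
        if scale_blocks and total_var > 0:
            w = 1.0 / np.sqrt(total_var)
        else:
            w = 1.0
        weights[name] = w
        blocks[name] = pd.DataFrame(X * w, index=shared, columns=sub.index)

    concat = pd.concat(blocks.values(), axis=1)
    U, S, Vt = np.linalg.svd(concat.to_numpy(), full_matrices=False)
    d = min(d, len(S))
    explained = (S**2) / (S**2).sum() if (S**2).sum() > 0 else np.zeros_like(S)

    # sign convention: largest-|loading| entry per axis made positive
    for k in range(d):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1

    axes = [f"axis{k + 1}" for k in range(d)]
    scores = pd.DataFrame(U[:, :d] * S[:d], index=shared, columns=axes)
    loadings = {}
    offset = 0
    for name, block in blocks.items():
        nfeat = block.shape[1]
        loadings[name] = pd.DataFrame(
            Vt[:d, offset : offset + nfeat].T, index=block.columns, columns=axes
        )
        offset += nfeat

    arrows = pd.DataFrame(columns=axes, dtype=float)
    centroids = pd.DataFrame(columns=axes, dtype=float)
    if meta is not None:
        mt = meta.table.loc[shared]
        cols = ([meta.phenotype] if meta.phenotype else []) + list(meta.covariates)
        for col in cols:
            series = mt[col]
            if pd.api.types.is_numeric_dtype(series):
                vals = series.astype(float).to_numpy()
                if np.std(vals) == 0:
                    continue
                arrows.loc[col] = [
                    float(np.corrcoef(vals, scores[a])[0, 1]) for a in axes
                ]
            else:
                for level in sorted(series.astype(str).unique()):
                    sel = series.astype(str) == level
                    centroids.loc[f"{col}={level}"] = scores.loc[sel.values].mean().to_numpy()

    return OrdinationResult(
        scores=scores,
        loadings=loadings,
        block_weights=weights,
        explained=explained[:d],
        covariate_arrows=arrows,
        level_centroids=centroids,
        processed=concat,
    )


def biplot_data(
    result: OrdinationResult, top_k: int = 10, phenotype: pd.Series | None = None
) -> dict:
    """Long tables for a biplot: samples, top-k features per block by
    loading norm, covariate arrows, and categorical centroids."""
    samples = result.scores.reset_index(names="sample")
    if phenotype is not None:
        samples["group"] = phenotype.loc[samples["sample"]].to_numpy()
    feat_rows = []
    for block, load in result.loadings.items():
        norms = np.sqrt((load.to_numpy() ** 2).sum(axis=1))
        order = sorted(
            zip(load.index, norms), key=lambda kv: (-kv[1], kv[0])
        )[: min(top_k, len(load))]
        for feat, norm in order:
            row = {"block": block, "feature": feat, "norm": float(norm)}
            row.update({a: float(load.loc[feat, a]) for a in load.columns})
            feat_rows.append(row)
    features = pd.DataFrame(feat_rows)
    return {
        "samples": samples,
        "features": features,
        "arrows": result.covariate_arrows.reset_index(names="covariate"),
        "centroids": result.level_centroids.reset_index(names="level"),
    }


def plot_biplot(
    result: OrdinationResult,
    path,
    top_k: int = 10,
    phenotype: pd.Series | None = None,
):
    """Render a 2-D biplot: sample scores coloured by phenotype, top-k
    feature loadings per block, covariate arrows and level centroids."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = biplot_data(result, top_k=top_k, phenotype=phenotype)
    fig, ax = plt.subplots(figsize=(7, 6))
    samples = data["samples"]
    if "group" in samples:
        for i, (grp, sub) in enumerate(sorted(samples.groupby("group"))):
            ax.scatter(sub["axis1"], sub["axis2"], s=25, label=str(grp), zorder=3)
        ax.legend(title="group", fontsize=8)
    else:
        ax.scatter(samples["axis1"], samples["axis2"], s=25, zorder=3)
    span = max(samples["axis1"].abs().max(), samples["axis2"].abs().max(), 1e-9)
    colors = {b: c for b, c in zip(result.loadings, ["tab:blue", "tab:green", "tab:purple", "tab:orange"])}
    feats = data["features"]
    if len(feats):
        scale = 0.8 * span / max(feats["norm"].max(), 1e-9)
        for _, row in feats.iterrows():
            ax.annotate(
                row["feature"],
                (row["axis1"] * scale, row["axis2"] * scale),
                color=colors.get(row["block"], "gray"),
                fontsize=7,
            )
    for _, row in data["arrows"].iterrows():
        ax.annotate(
            "",
            xy=(row["axis1"] * span, row["axis2"] * span),
            xytext=(0, 0),
            arrowprops=dict(arrowstyle="->", color="black"),
        )
        ax.annotate(row["covariate"], (row["axis1"] * span, row["axis2"] * span), fontsize=8)
    ev = result.explained
    ax.set_xlabel(f"axis 1 ({100 * ev[0]:.1f}% var)" if len(ev) > 0 else "axis 1")
    ax.set_ylabel(f"axis 2 ({100 * ev[1]:.1f}% var)" if len(ev) > 1 else "axis 2")
    ax.axhline(0, lw=0.5, color="gray")
    ax.axvline(0, lw=0.5, color="gray")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
    plt.close(fig)
    return path
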