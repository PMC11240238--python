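"""Amplicon community profiling: rank-level aggregation and top-n taxa.

Takes an ASV (amplicon sequence variant) count table plus a taxonomy and
produces taxon-level abundance tables at a user-chosen rank, a ranked
top-n taxon list (the input to protein-database construction), and
stacked-barplot composition data.

"Most abundant" is scored by mean per-sample relative abundance by
default, which is robust to library-size differences; ranking by summed
raw counts is available as an alternative. ASVs whose lineage does not
pass through the requested rank are pooled under the reserved feature
name "Unclassified", which never enters the top-n ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .core import AbundanceMatrix, MetaomixError, TaxonomyTree, ValidationError

__all__ = [
    "UNCLASSIFIED",
    "RankedTaxa",
    "aggregate_to_rank",
    "relative_abundance",
    "rank_taxa",
    "composition_plot_data",
]

UNCLASSIFIED = "Unclassified"
OTHER = "Other"


@dataclass
class RankedTaxa:
    """Top-n taxa at a rank, ordered by mean relative abundance.

    ``entries`` is an ordered list of (taxon name, score); ties are
    broken lexicographically by name for determinism.
    """

    rank: str
    entries: list
    n: int

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.entries]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["taxon", "score"])


def aggregate_to_rank(
    m: AbundanceMatrix,
    tax: TaxonomyTree,
    rank: str,
    feature_taxa: Mapping[str, str] | None = None,
) -> AbundanceMatrix:
    """Sum feature counts into taxa at ``rank``.

    ``feature_taxa`` maps each feature id to its taxonomy node; when
    omitted, feature ids are assumed to be node ids themselves. Features
    whose lineage lacks the requested rank go to "Unclassified".
    Per-sample totals are conserved exactly.
    """
    if feature_taxa is None:
        feature_taxa = {f: f for f in m.features}
    unknown = [f for f in m.features if feature_taxa.get(f) not in tax.nodes]
    if unknown:
        raise MetaomixError(
            f"features with no taxonomy node: {sorted(unknown)}"
        )
    target = {}
    for feat in m.features:
        node = tax.ancestor_at_rank(feature_taxa[feat], rank)
        target[feat] = tax.nodes[node].name if node is not None else UNCLASSIFIED
    grouped = m.values.groupby(pd.Series(target), sort=True).sum()
    # keep Unclassified last for readability
    if UNCLASSIFIED in grouped.index:
        order = [i for i in grouped.index if i != UNCLASSIFIED] + [UNCLASSIFIED]
        grouped = grouped.loc[order]
    return AbundanceMatrix(grouped, layer=m.layer)


def relative_abundance(m: AbundanceMatrix) -> AbundanceMatrix:
    """Total-sum scaling: every sample (column) sums to 1."""
    totals = m.values.sum(axis=0)
    zero = totals[totals <= 0].index.tolist()
    if zero:
        raise ValidationError(f"samples with zero total abundance: {zero}")
    return m.copy_with(m.values.div(totals, axis=1))


def _scores(m: AbundanceMatrix, by: str) -> pd.Series:
    if by == "mean_relative":
        return relative_abundance(m).values.mean(axis=1)
    if by == "total_count":
        return m.values.sum(axis=1)
    raise ValueError(f"unknown ranking mode {by!r}")


def rank_taxa(
    m: AbundanceMatrix, n: int, by: str = "mean_relative", rank: str = "unknown"
) -> RankedTaxa:
    """Top-n taxa scored by mean per-sample relative abundance.

    "Unclassified" is excluded from ranking (no proteomes exist for it).
    Exact ties are broken lexicographically. If n exceeds the number of
    taxa, all taxa are returned with a warning.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    scores = _scores(m, by).drop(index=UNCLASSIFIED, errors="ignore")
    if n > len(scores):
        warnings.warn(
            f"requested top {n} taxa but only {len(scores)} available; returning all"
        )
        n = len(scores)
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return RankedTaxa(rank=rank, entries=[(k, float(v)) for k, v in ordered[:n]], n=n)


def composition_plot_data(m: AbundanceMatrix, n: int, by: str = "mean_relative") -> pd.DataFrame:
    """Long-format (sample, taxon, abundance) table for a stacked barplot.

    Relative abundances of the top-n taxa, with all remaining taxa
    (including "Unclassified") pooled as "Other". Per-sample values sum
    to 1 including the "Other" row.
    """
    rel = relative_abundance(m).values
    top = rank_taxa(m, n, by=by).names
    rows = []
    for sample in rel.columns:
        col = rel[sample]
        running = 0.0
        for taxon in top:
            v = float(col.get(taxon, 0.0))
            rows.append({"sample": sample, "taxon": taxon, "abundance": v})
            running += v
        other = 1.0 - running
        if other > 1e-12:
            rows.append({"sample": sample, "taxon": OTHER, "abundance": other})
    return pd.DataFrame(rows, columns=["sample", "taxon", "abundance"])
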