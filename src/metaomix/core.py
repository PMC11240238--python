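"""Shared domain types for the multi-omics pipeline.

The pipeline moves four kinds of objects between stages: protein records
(the metaproteomics search space), a rooted taxonomy (backbone for
aggregation and lowest-common-ancestor assignment), abundance matrices
(features x samples for any omics layer), sample metadata (phenotype and
covariates for the linear models), and pathway definitions (node -> KO/EC
maps for cross-omics integration).

All taxon identifiers are opaque strings; no NCBI taxid semantics are
assumed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "RANKS",
    "MetaomixError",
    "ParseError",
    "ValidationError",
    "ProteinRecord",
    "TaxonomyTree",
    "AbundanceMatrix",
    "SampleMetadata",
    "PathwayDefinition",
    "PathwayNode",
]

#: Canonical amino-acid alphabet; X is allowed as an unknown residue.
AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: Ordered taxonomic ranks, most to least inclusive. "unranked" is allowed
#: for nodes that do not sit at a named level (e.g. the root).
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_EC_RE = re.compile(r"^\d+\.(?:\d+|-)\.(?:\d+|-)\.(?:n?\d+|-)$")


class MetaomixError(Exception):
    """Base class for all package errors."""


class ParseError(MetaomixError):
    """Raised when an input file violates its format contract."""


class ValidationError(MetaomixError):
    """Raised when an object violates a domain-type invariant."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with taxon provenance and functional annotation.

    Parameters
    ----------
    id : str
        Unique identifier within a database.
    taxon : str
        Taxon identifier of the source organism.
    sequence : str
        Amino-acid sequence, uppercase, alphabet ACDEFGHIKLMNPQRSTVWY + X.
    ec : frozenset of str
        Enzyme Commission numbers (4 dotted fields, trailing dashes allowed).
    ko : frozenset of str
        KEGG Orthology identifiers.
    """

    id: str
    taxon: str
    sequence: str
    ec: frozenset = frozenset()
    ko: frozenset = frozenset()

    def __post_init__(self):
        if not self.id:
            raise ValidationError("protein record id must be nonempty")
        if not self.sequence:
            raise ValidationError(f"protein record {self.id!r}: empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            raise ValidationError(
                f"protein record {self.id!r}: invalid residues {sorted(bad)}"
            )
        for ec in self.ec:
            if not _EC_RE.match(ec):
                raise ValidationError(
                    f"protein record {self.id!r}: malformed EC number {ec!r}"
                )
        object.__setattr__(self, "ec", frozenset(self.ec))
        object.__setattr__(self, "ko", frozenset(self.ko))


@dataclass(frozen=True)
class TaxonNode:
    name: str
    rank: str
    parent: str


class TaxonomyTree:
    """Rooted tree of taxa with named ranks.

    The root is its own parent. Every node must reach the root by
    following parent links (acyclicity is checked at construction).
    """

    def __init__(self, nodes: Mapping[str, TaxonNode]):
        self.nodes = dict(nodes)
        roots = [tid for tid, n in self.nodes.items() if n.parent == tid]
        if len(roots) != 1:
            raise ValidationError(
                f"taxonomy must have exactly one root, found {len(roots)}"
            )
        self.root = roots[0]
        for tid, node in self.nodes.items():
            if node.rank not in RANKS and node.rank != "unranked":
                raise ValidationError(f"node {tid!r}: unknown rank {node.rank!r}")
            # walk to root, detecting cycles and dangling parents
            seen = {tid}
            cur = tid
            while cur != self.root:
                parent = self.nodes[cur].parent
                if parent not in self.nodes:
                    raise ValidationError(
                        f"node {cur!r}: parent {parent!r} not in taxonomy"
                    )
                if parent in seen:
                    raise ValidationError(f"cycle in taxonomy at node {cur!r}")
                seen.add(parent)
                cur = parent
        self._depth_cache: dict[str, int] = {}

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    def parent(self, taxon_id: str) -> str:
        return self.nodes[taxon_id].parent

    def depth(self, taxon_id: str) -> int:
        """Number of edges from the node up to the root."""
        if taxon_id not in self._depth_cache:
            d = 0
            cur = taxon_id
            while cur != self.root:
                cur = self.nodes[cur].parent
                d += 1
            self._depth_cache[taxon_id] = d
        return self._depth_cache[taxon_id]

    def path_to_root(self, taxon_id: str) -> list[str]:
        """Node ids from ``taxon_id`` (inclusive) up to the root (inclusive)."""
        if taxon_id not in self.nodes:
            raise KeyError(taxon_id)
        path = [taxon_id]
        while path[-1] != self.root:
            path.append(self.nodes[path[-1]].parent)
        return path

    def ancestor_at_rank(self, taxon_id: str, rank: str) -> str | None:
        """Ancestor-or-self of ``taxon_id`` at ``rank``, or None if the
        lineage does not pass through that rank."""
        for node_id in self.path_to_root(taxon_id):
            if self.nodes[node_id].rank == rank:
                return node_id
        return None

    def lca(self, taxon_ids: Iterable[str]) -> str:
        """Lowest common ancestor: the deepest node that is an
        ancestor-or-self of every given taxon.

        Implemented by pairwise depth-equalising walks (tests check it
        against a root-path-intersection brute force).
        """
        ids = list(taxon_ids)
        if not ids:
            raise ValidationError("lca of an empty taxon set is undefined")
        cur = ids[0]
        for other in ids[1:]:
            cur = self._lca_pair(cur, other)
            if cur == self.root:
                break
        return cur

    def _lca_pair(self, a: str, b: str) -> str:
        da, db = self.depth(a), self.depth(b)
        while da > db:
            a = self.nodes[a].parent
            da -= 1
        while db > da:
            b = self.nodes[b].parent
            db -= 1
        while a != b:
            a = self.nodes[a].parent
            b = self.nodes[b].parent
        return a

    def node_by_name(self, name: str, rank: str | None = None) -> str | None:
        """First node id (in insertion order) whose name matches."""
        for tid, node in self.nodes.items():
            if node.name == name and (rank is None or node.rank == rank):
                return tid
        return None


class AbundanceMatrix:
    """Features x samples abundance table for one omics layer.

    Wraps a dense pandas DataFrame (rows = features, columns = samples)
    plus an optional feature-annotation side table with columns
    ``taxon`` (str or None), ``ec`` and ``ko`` (frozensets).
    """

    LAYERS = ("AS", "MG", "MT", "MP")

    def __init__(
        self,
        values: pd.DataFrame,
        feature_annotations: pd.DataFrame | None = None,
        layer: str | None = None,
    ):
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate feature ids: {dups}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        arr = values.to_numpy(dtype=float)
        if np.isnan(arr).any():
            raise ValidationError("abundance matrix contains missing values")
        if (arr < 0).any():
            feats = values.index[(arr < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative abundances for features: {feats}")
        if layer is not None and layer not in self.LAYERS:
            raise ValidationError(f"unknown layer label {layer!r}")
        self.values = values.astype(float)
        self.layer = layer
        if feature_annotations is not None:
            missing = set(values.index) - set(feature_annotations.index)
            if missing:
                raise ValidationError(
                    f"annotations missing for features: {sorted(missing)}"
                )
            feature_annotations = feature_annotations.loc[values.index]
        self.feature_annotations = feature_annotations

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy_with(self, values: pd.DataFrame, annotations: pd.DataFrame | None = None):
        return AbundanceMatrix(values, annotations, layer=self.layer)

    def __repr__(self):  # pragma: no cover - debugging aid
        lay = f", layer={self.layer}" if self.layer else ""
        return f"<AbundanceMatrix {self.shape[0]}x{self.shape[1]}{lay}>"


class SampleMetadata:
    """Per-sample metadata with a designated phenotype and covariates."""

    def __init__(
        self,
        table: pd.DataFrame,
        phenotype: str | None = None,
        covariates: Sequence[str] = (),
    ):
        if table.index.has_duplicates:
            dups = table.index[table.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dups}")
        for col in ([phenotype] if phenotype else []) + list(covariates):
            if col not in table.columns:
                raise ValidationError(f"metadata column {col!r} does not exist")
        self.table = table
        self.phenotype = phenotype
        self.covariates = list(covariates)

    @property
    def samples(self) -> list[str]:
        return list(self.table.index)

    def aligned_to(self, samples: Sequence[str]) -> "SampleMetadata":
        missing = set(samples) - set(self.table.index)
        if missing:
            raise ValidationError(f"samples absent from metadata: {sorted(missing)}")
        return SampleMetadata(self.table.loc[list(samples)], self.phenotype, self.covariates)


@dataclass(frozen=True)
class PathwayNode:
    label: str
    kos: frozenset = frozenset()
    ecs: frozenset = frozenset()

    def __post_init__(self):
        if not self.kos and not self.ecs:
            raise ValidationError(
                f"pathway node {self.label!r} has neither KO nor EC ids"
            )

    @property
    def ids(self) -> frozenset:
        return self.kos | self.ecs


@dataclass
class PathwayDefinition:
    """A pathway as a map from node id to its label and KO/EC identifiers."""

    id: str
    nodes: dict = field(default_factory=dict)

    def __post_init__(self):
        if not isinstance(self.nodes, dict):
            self.nodes = dict(self.nodes)
        for node in self.nodes.values():
            if not isinstance(node, PathwayNode):
                raise ValidationError("pathway nodes must be PathwayNode objects")
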