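"""Readers and writers for the pipeline's plain-text formats.

Formats
-------
* Protein FASTA with a self-describing header dialect::

      >prot_id taxon=<taxon>[ ec=<ec;ec>][ ko=<ko;ko>]

  The taxon tag is mandatory (databases must carry provenance for the
  LCA stage); ec/ko tags are optional semicolon-separated lists.
* Abundance matrices as TSV, features in rows, samples in columns,
  first column = feature id.
* Sample metadata as TSV, first column = sample id.
* Taxonomy either as a 4-column TSV (taxon, parent, name, rank; header
  row required) or as rank-prefixed lineage strings
  (``d__Bacteria;g__Veillonella``).
* Pathway node maps as TSV (node, label, ko, ec; ko/ec are
  semicolon-separated lists, either may be empty but not both).

Every reader validates domain-type invariants and raises a typed error
rather than silently coercing.
"""

from __future__ import annotations

import os
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import (
    AbundanceMatrix,
    MetaomixError,
    ParseError,
    PathwayDefinition,
    PathwayNode,
    ProteinRecord,
    SampleMetadata,
    TaxonNode,
    TaxonomyTree,
    ValidationError,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_matrix",
    "write_matrix",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "taxonomy_from_lineages",
    "read_pathway",
    "write_pathway",
    "read_feature_annotations",
]

_LINEAGE_PREFIXES = {
    "d": "domain",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}


def _parse_header(description: str) -> tuple[str, str, frozenset, frozenset]:
    tokens = description.split()
    if not tokens:
        raise ParseError("empty FASTA header")
    rec_id = tokens[0]
    taxon = None
    ec: frozenset = frozenset()
    ko: frozenset = frozenset()
    for tok in tokens[1:]:
        if "=" not in tok:
            continue
        key, _, value = tok.partition("=")
        if key == "taxon":
            taxon = value
        elif key == "ec":
            ec = frozenset(v for v in value.split(";") if v)
        elif key == "ko":
            ko = frozenset(v for v in value.split(";") if v)
    if taxon is None:
        raise ParseError(f"record {rec_id!r}: header lacks the required taxon= tag")
    return rec_id, taxon, ec, ko


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read protein records from a FASTA file with the taxon=/ec=/ko= dialect."""
    records = []
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        rec_id, taxon, ec, ko = _parse_header(seq_rec.description)
        seq = str(seq_rec.seq).upper()
        if not seq:
            raise ParseError(f"record {rec_id!r}: empty sequence")
        try:
            records.append(ProteinRecord(rec_id, taxon, seq, ec, ko))
        except ValidationError as exc:
            raise ParseError(str(exc)) from exc
    return records


def _record_description(rec: ProteinRecord) -> str:
    parts = [f"taxon={rec.taxon}"]
    if rec.ec:
        parts.append("ec=" + ";".join(sorted(rec.ec)))
    if rec.ko:
        parts.append("ko=" + ";".join(sorted(rec.ko)))
    return " ".join(parts)


def write_fasta(records: Sequence[ProteinRecord], path: str | os.PathLike) -> None:
    """Write records in input order; sequences wrapped at 60 columns."""
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        counts = pd.Series(ids).value_counts()
        dups = sorted(counts[counts > 1].index)
        raise ValidationError(f"duplicate record ids: {dups}")
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=_record_description(r))
        for r in records
    ]
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "fasta")  # Biopython wraps at 60


def read_matrix(path: str | os.PathLike, layer: str | None = None) -> AbundanceMatrix:
    """Read a features x samples TSV into an AbundanceMatrix."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        arr = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-numeric values in matrix") from exc
    if np.isnan(arr).any():
        raise ParseError(f"{path}: missing values in matrix")
    return AbundanceMatrix(df, layer=layer)


def write_matrix(m: AbundanceMatrix, path: str | os.PathLike) -> None:
    df = m.values.copy()
    df.index.name = df.index.name or "feature"
    df.to_csv(path, sep="\t")


def read_metadata(
    path: str | os.PathLike,
    phenotype: str | None = None,
    covariates: Sequence[str] = (),
) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return SampleMetadata(df, phenotype=phenotype, covariates=covariates)


def write_metadata(meta: SampleMetadata, path: str | os.PathLike) -> None:
    df = meta.table.copy()
    df.index.name = df.index.name or "sample"
    df.to_csv(path, sep="\t")


def read_taxonomy(path: str | os.PathLike) -> TaxonomyTree:
    """Read a taxonomy TSV: columns taxon, parent, name, rank (header row)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"taxon", "parent", "name", "rank"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: taxonomy TSV needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    if df["taxon"].duplicated().any():
        dups = df.loc[df["taxon"].duplicated(), "taxon"].tolist()
        raise ParseError(f"{path}: duplicated taxon ids {dups}")
    nodes = {
        row["taxon"]: TaxonNode(name=row["name"], rank=row["rank"], parent=row["parent"])
        for _, row in df.iterrows()
    }
    try:
        return TaxonomyTree(nodes)
    except ValidationError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_taxonomy(tree: TaxonomyTree, path: str | os.PathLike) -> None:
    rows = [
        {"taxon": tid, "parent": n.parent, "name": n.name, "rank": n.rank}
        for tid, n in tree.nodes.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def taxonomy_from_lineages(
    lineages: Mapping[str, str], root_name: str = "root"
) -> tuple[TaxonomyTree, dict[str, str]]:
    """Build a taxonomy from rank-prefixed lineage strings.

    ``lineages`` maps a feature id (e.g. an ASV) to a string like
    ``"d__Bacteria;g__Veillonella"``. Node ids keep their rank prefix so
    identical names at different ranks cannot collide. Returns the tree
    and a feature -> deepest-node mapping.
    """
    nodes: dict[str, TaxonNode] = {root_name: TaxonNode(root_name, "unranked", root_name)}
    feature_taxa: dict[str, str] = {}
    for feature, lineage in lineages.items():
        parent = root_name
        deepest = root_name
        for part in [p.strip() for p in lineage.split(";") if p.strip()]:
            prefix, sep, name = part.partition("__")
            if not sep or prefix not in _LINEAGE_PREFIXES:
                raise ParseError(
                    f"feature {feature!r}: malformed lineage component {part!r}"
                )
            node_id = part
            rank = _LINEAGE_PREFIXES[prefix]
            if node_id in nodes:
                if nodes[node_id].parent != parent:
                    raise ParseError(
                        f"lineage conflict: node {node_id!r} has parents "
                        f"{nodes[node_id].parent!r} and {parent!r}"
                    )
            else:
                nodes[node_id] = TaxonNode(name=name, rank=rank, parent=parent)
            parent = node_id
            deepest = node_id
        feature_taxa[feature] = deepest
    return TaxonomyTree(nodes), feature_taxa


def read_feature_annotations(path: str | os.PathLike) -> pd.DataFrame:
    """Read a feature annotation TSV (feature, ko, ec; semicolon lists,
    optional taxon column) into the side-table format AbundanceMatrix
    expects: frozenset-valued ``ko``/``ec`` columns plus ``taxon``."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str).fillna("")
    out = pd.DataFrame(index=df.index.astype(str), columns=["taxon", "ec", "ko"], dtype=object)
    for feat in df.index:
        out.at[feat, "taxon"] = df.at[feat, "taxon"] if "taxon" in df.columns and df.at[feat, "taxon"] else None
        for col in ("ec", "ko"):
            raw = df.at[feat, col] if col in df.columns else ""
            out.at[feat, col] = frozenset(v for v in str(raw).split(";") if v)
    return out


def read_pathway(path: str | os.PathLike, pathway_id: str | None = None) -> PathwayDefinition:
    """Read a pathway node map TSV: columns node, label, ko, ec."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"node", "label", "ko", "ec"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: pathway TSV needs columns {sorted(required)}, got {list(df.columns)}"
        )
    if df["node"].duplicated().any():
        dups = df.loc[df["node"].duplicated(), "node"].tolist()
        raise ParseError(f"{path}: duplicated node ids {dups}")
    nodes = {}
    for row in df.itertuples(index=False):
        kos = frozenset(v for v in row.ko.split(";") if v)
        ecs = frozenset(v for v in row.ec.split(";") if v)
        try:
            nodes[row.node] = PathwayNode(label=row.label, kos=kos, ecs=ecs)
        except ValidationError as exc:
            raise ParseError(f"{path}: node {row.node!r}: {exc}") from exc
    if pathway_id is None:
        pathway_id = os.path.splitext(os.path.basename(str(path)))[0]
    return PathwayDefinition(id=pathway_id, nodes=nodes)


def write_pathway(pathway: PathwayDefinition, path: str | os.PathLike) -> None:
    rows = [
        {
            "node": nid,
            "label": node.label,
            "ko": ";".join(sorted(node.kos)),
            "ec": ";".join(sorted(node.ecs)),
        }
        for nid, node in pathway.nodes.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
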