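"""Protein-database construction for metaproteomics searches.

Given the top-n most abundant taxa from the amplicon profile, collect
every available proteome for those taxa from a proteome source, remove
exact-sequence redundancy, optionally merge in a host proteome, and
write a search-ready FASTA plus a build report.

Deduplication keeps the first record (in deterministic collection
order) of each distinct amino-acid sequence, unions its EC/KO
annotations over all duplicates, and records the full set of source
taxa per kept record in a sidecar map — discarding duplicate taxa would
corrupt downstream lowest-common-ancestor assignment. Identity means
exact full-length sequence equality; there is no sub-100%-identity
clustering.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import pandas as pd

from .core import MetaomixError, ProteinRecord, TaxonomyTree, ValidationError
from .io import read_fasta, write_fasta
from .profile import RankedTaxa, aggregate_to_rank, rank_taxa

__all__ = [
    "ProteomeSource",
    "LocalProteomeSource",
    "RemoteProteomeSource",
    "BuildReport",
    "ProteinDatabase",
    "collect_proteomes",
    "deduplicate",
    "add_host",
    "build_database",
]


class ProteomeSource(Protocol):
    """Contract for proteome providers.

    ``lookup(taxon)`` returns an iterable of ``(genome_id, records)``
    pairs, deterministically ordered (genomes sorted by id, records in
    file order). A taxon with no genomes yields an empty iterable.
    """

    def lookup(self, taxon: str) -> list[tuple[str, list[ProteinRecord]]]: ...


class LocalProteomeSource:
    """Proteomes laid out on disk as ``<root>/<taxon>/<genome_id>.faa``."""

    def __init__(self, root: str | os.PathLike):
        self.root = Path(root)
        if not self.root.is_dir():
            raise MetaomixError(f"proteome source directory not found: {self.root}")

    def lookup(self, taxon: str) -> list[tuple[str, list[ProteinRecord]]]:
        taxon_dir = self.root / taxon
        if not taxon_dir.is_dir():
            return []
        out = []
        for faa in sorted(taxon_dir.glob("*.faa")):
            out.append((faa.stem, read_fasta(faa)))
        return out


class RemoteProteomeSource:
    """Interface stub for fetching proteomes from a remote archive.

    Real deployments would resolve a taxon name to assembly accessions
    and download complete-genome proteomes. Network access is outside
    this package's tested scope; subclasses must implement ``lookup``
    honouring the ProteomeSource ordering contract.
    """

    def lookup(self, taxon: str):  # pragma: no cover - contract stub
        raise NotImplementedError(
            "remote proteome fetching is an integration point; provide a "
            "subclass or use LocalProteomeSource"
        )


@dataclass
class BuildReport:
    """Counts produced while building a database."""

    genomes_per_taxon: dict = field(default_factory=dict)
    missing_taxa: list = field(default_factory=list)
    raw_proteins: int = 0
    nonredundant_proteins: int = 0
    host_proteins_raw: int = 0
    total_proteins: int = 0
    invalid_removed: int = 0

    def validate(self) -> None:
        if self.nonredundant_proteins > self.raw_proteins:
            raise ValidationError("nonredundant count exceeds raw count")

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def to_tsv(self, path: str | os.PathLike) -> None:
        rows = [
            {"metric": "raw_proteins", "value": self.raw_proteins},
            {"metric": "nonredundant_proteins", "value": self.nonredundant_proteins},
            {"metric": "host_proteins_raw", "value": self.host_proteins_raw},
            {"metric": "total_proteins", "value": self.total_proteins},
            {"metric": "invalid_removed", "value": self.invalid_removed},
        ]
        for taxon, count in self.genomes_per_taxon.items():
            rows.append({"metric": f"genomes:{taxon}", "value": count})
        for taxon in self.missing_taxa:
            rows.append({"metric": f"missing:{taxon}", "value": 0})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class ProteinDatabase:
    """Deduplicated protein records plus the per-record source-taxon map."""

    records: list
    taxon_map: dict  # record id -> frozenset of source taxa
    report: BuildReport | None = None

    def __len__(self) -> int:
        return len(self.records)

    def taxa_of(self, record_id: str) -> frozenset:
        return self.taxon_map[record_id]

    def write(self, fasta_path: str | os.PathLike, sidecar_path: str | os.PathLike | None = None) -> None:
        write_fasta(self.records, fasta_path)
        if sidecar_path is not None:
            rows = [
                {"protein": r.id, "taxa": ";".join(sorted(self.taxon_map[r.id]))}
                for r in self.records
            ]
            pd.DataFrame(rows).to_csv(sidecar_path, sep="\t", index=False)

    @classmethod
    def read(cls, fasta_path: str | os.PathLike, sidecar_path: str | os.PathLike | None = None) -> "ProteinDatabase":
        records = read_fasta(fasta_path)
        taxon_map = {r.id: frozenset({r.taxon}) for r in records}
        if sidecar_path is not None and Path(sidecar_path).exists():
            side = pd.read_csv(sidecar_path, sep="\t", dtype=str)
            for row in side.itertuples(index=False):
                taxon_map[row.protein] = frozenset(row.taxa.split(";"))
        return cls(records=records, taxon_map=taxon_map)


def collect_proteomes(
    taxa: RankedTaxa | Sequence[str], source: ProteomeSource
) -> tuple[list[ProteinRecord], dict[str, int], list[str]]:
    """Gather proteomes for the ranked taxa in deterministic order.

    Returns (records, per-taxon genome counts, taxa missing from the
    source). Order is ranked-taxon order, then genome order, then record
    order; every record is re-tagged with the taxon it was collected
    under.
    """
    names = taxa.names if isinstance(taxa, RankedTaxa) else list(taxa)
    records: list[ProteinRecord] = []
    genome_counts: dict[str, int] = {}
    missing: list[str] = []
    for taxon in names:
        genomes = source.lookup(taxon)
        if not genomes:
            warnings.warn(f"no proteomes found for taxon {taxon!r}; skipping")
            missing.append(taxon)
            continue
        genome_counts[taxon] = len(genomes)
        for _genome_id, recs in genomes:
            for rec in recs:
                if rec.taxon != taxon:
                    rec = ProteinRecord(rec.id, taxon, rec.sequence, rec.ec, rec.ko)
                records.append(rec)
    return records, genome_counts, missing


def deduplicate(
    records: Iterable[ProteinRecord],
    taxon_map: dict | None = None,
) -> tuple[list[ProteinRecord], dict]:
    """Collapse exact-sequence duplicates, keeping the first occurrence.

    The survivor's EC/KO annotations become the union over all its
    duplicates; the returned sidecar map gives every source taxon seen
    for each kept record id (survivor's own taxon included). An existing
    sidecar map may be passed to seed the taxon sets (used for the
    second pass after a host merge).
    """
    by_seq: dict[str, int] = {}
    kept: list[ProteinRecord] = []
    taxa: list[set] = []
    ecs: list[set] = []
    kos: list[set] = []
    for rec in records:
        seed = set(taxon_map.get(rec.id, ())) if taxon_map else set()
        if rec.sequence in by_seq:
            i = by_seq[rec.sequence]
            taxa[i].add(rec.taxon)
            taxa[i] |= seed
            ecs[i] |= rec.ec
            kos[i] |= rec.ko
        else:
            by_seq[rec.sequence] = len(kept)
            kept.append(rec)
            taxa.append({rec.taxon} | seed)
            ecs.append(set(rec.ec))
            kos.append(set(rec.ko))
    out_records = []
    out_map = {}
    for rec, t, e, k in zip(kept, taxa, ecs, kos):
        out_records.append(
            ProteinRecord(rec.id, rec.taxon, rec.sequence, frozenset(e), frozenset(k))
        )
        out_map[rec.id] = frozenset(t)
    return out_records, out_map


def add_host(
    records: Sequence[ProteinRecord],
    host_proteome: Sequence[ProteinRecord],
    taxon_map: dict | None = None,
) -> tuple[list[ProteinRecord], dict]:
    """Append host proteins and re-deduplicate the merged set.

    Microbial records win ties by the first-in-order rule; a host
    protein identical to a microbial one leaves a single record whose
    sidecar taxon set contains both taxa.
    """
    merged = list(records) + list(host_proteome)
    return deduplicate(merged, taxon_map=taxon_map)


def _clean(records: Sequence[ProteinRecord]) -> tuple[list[ProteinRecord], int]:
    """Drop records with empty or non-amino-acid sequences."""
    ok, removed = [], 0
    for rec in records:
        try:
            ProteinRecord(rec.id, rec.taxon, rec.sequence, rec.ec, rec.ko)
        except ValidationError:
            removed += 1
            continue
        ok.append(rec)
    return ok, removed


def build_database(
    asv,
    taxonomy: TaxonomyTree,
    rank: str,
    n: int,
    source: ProteomeSource,
    host: Sequence[ProteinRecord] | None = None,
    feature_taxa=None,
    out_fasta: str | os.PathLike | None = None,
    out_report: str | os.PathLike | None = None,
) -> ProteinDatabase:
    """End-to-end database build from an ASV table.

    Aggregates to ``rank``, picks the top-n taxa, collects their
    proteomes, removes exact redundancy, merges the host proteome (if
    given) with a second dedup pass, and optionally writes the FASTA
    (with taxon sidecar) and TSV+JSON report.
    """
    agg = aggregate_to_rank(asv, taxonomy, rank, feature_taxa=feature_taxa)
    ranked = rank_taxa(agg, n, rank=rank)
    raw, genome_counts, missing = collect_proteomes(ranked, source)
    raw, invalid_removed = _clean(raw)
    nonred, taxon_map = deduplicate(raw)
    host = list(host or [])
    if host:
        host_clean, invalid_host = _clean(host)
        invalid_removed += invalid_host
        final, taxon_map = add_host(nonred, host_clean, taxon_map=taxon_map)
    else:
        final = nonred
    report = BuildReport(
        genomes_per_taxon=genome_counts,
        missing_taxa=missing,
        raw_proteins=len(raw),
        nonredundant_proteins=len(nonred),
        host_proteins_raw=len(host),
        total_proteins=len(final),
        invalid_removed=invalid_removed,
    )
    report.validate()
    db = ProteinDatabase(records=final, taxon_map=taxon_map, report=report)
    if out_fasta is not None:
        sidecar = Path(str(out_fasta)).with_suffix(".taxa.tsv")
        db.write(out_fasta, sidecar)
    if out_report is not None:
        report.to_tsv(out_report)
        report.to_json(Path(str(out_report)).with_suffix(".json"))
    return db
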