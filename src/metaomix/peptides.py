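"""In-silico tryptic digestion, peptide indexing, and LCA taxonomy.

Peptides identified by a database search inherit their taxonomy from
the proteins that could have produced them: a peptide found in proteins
from several taxa is assigned to the lowest common ancestor (LCA) of
those taxa. Assignment here runs against the constructed protein
database itself, so taxonomy is always consistent with the search
space that produced the identifications.

Trypsin cleaves after K or R except when the next residue is P.
Defaults (2 missed cleavages, length 7-45, I/L equated) follow common
mass-spectrometry practice; isoleucine and leucine are isobaric and
indistinguishable by mass, hence the I/L collapse of index keys.

EC/KO annotation of a peptide is the union over all proteins containing
it (an intersection would be empty too often on sparsely annotated
databases).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

from .core import AbundanceMatrix, TaxonomyTree, ValidationError
from .dbbuild import ProteinDatabase

__all__ = [
    "UNMAPPED",
    "DigestParams",
    "PeptideIndex",
    "PeptideTable",
    "digest",
    "build_index",
    "assign_lca",
    "aggregate_peptides",
    "taxon_table_from_peptides",
    "unique_peptide_count",
]

#: Marker used for peptides not present in the index.
UNMAPPED = "unmapped"


@dataclass(frozen=True)
class DigestParams:
    """Tryptic digestion settings."""

    enzyme: str = "trypsin"
    missed_cleavages: int = 2
    min_len: int = 7
    max_len: int = 45
    equate_il: bool = True

    def __post_init__(self):
        if self.enzyme != "trypsin":
            raise ValidationError(f"unsupported enzyme {self.enzyme!r}")
        if self.missed_cleavages < 0:
            raise ValidationError("missed_cleavages must be >= 0")
        if self.min_len > self.max_len:
            raise ValidationError("min_len must be <= max_len")

    def collapse(self, peptide: str) -> str:
        return peptide.replace("I", "L") if self.equate_il else peptide


def digest(sequence: str, params: DigestParams = DigestParams()) -> list[str]:
    """Tryptic peptides of ``sequence``.

    Cleaves after K/R unless followed by P. Emits every product with at
    most ``missed_cleavages`` internal sites and length within bounds,
    ordered by start position then by increasing missed cleavages.
    Duplicate sequences are retained. No I/L collapsing here — that is
    an indexing concern.
    """
    # fully cleaved fragments
    cuts = [0]
    for i in range(len(sequence) - 1):
        if sequence[i] in "KR" and sequence[i + 1] != "P":
            cuts.append(i + 1)
    cuts.append(len(sequence))
    fragments = [sequence[cuts[i] : cuts[i + 1]] for i in range(len(cuts) - 1)]
    out = []
    for start in range(len(fragments)):
        for mc in range(params.missed_cleavages + 1):
            end = start + mc + 1
            if end > len(fragments):
                break
            pep = "".join(fragments[start:end])
            if params.min_len <= len(pep) <= params.max_len:
                out.append(pep)
    return out


@dataclass
class PeptideIndex:
    """Peptide -> provenance lookup over a protein database.

    Keys are I/L-collapsed when ``params.equate_il``. Each entry carries
    the protein ids, source taxa (including deduplication-sidecar taxa),
    and the union of EC/KO annotations of all containing proteins.
    """

    params: DigestParams
    entries: dict = field(default_factory=dict)  # key -> dict of sets

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, peptide: str) -> bool:
        return self.params.collapse(peptide) in self.entries

    def get(self, peptide: str) -> dict | None:
        return self.entries.get(self.params.collapse(peptide))

    def to_tsv(self, path: str | os.PathLike) -> None:
        rows = [
            {
                "peptide": pep,
                "proteins": ";".join(sorted(e["proteins"])),
                "taxa": ";".join(sorted(e["taxa"])),
                "ec": ";".join(sorted(e["ec"])),
                "ko": ";".join(sorted(e["ko"])),
            }
            for pep, e in sorted(self.entries.items())
        ]
        pd.DataFrame(rows, columns=["peptide", "proteins", "taxa", "ec", "ko"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | os.PathLike, params: DigestParams = DigestParams()) -> "PeptideIndex":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        entries = {}
        for row in df.itertuples(index=False):
            entries[row.peptide] = {
                "proteins": set(v for v in row.proteins.split(";") if v),
                "taxa": set(v for v in row.taxa.split(";") if v),
                "ec": set(v for v in row.ec.split(";") if v),
                "ko": set(v for v in row.ko.split(";") if v),
            }
        return cls(params=params, entries=entries)


def build_index(db: ProteinDatabase, params: DigestParams = DigestParams()) -> PeptideIndex:
    """Digest every database protein and merge provenance per peptide."""
    if not db.records:
        raise ValidationError("cannot index an empty database")
    entries: dict[str, dict] = {}
    for rec in db.records:
        taxa = set(db.taxon_map.get(rec.id, {rec.taxon}))
        for pep in set(digest(rec.sequence, params)):
            key = params.collapse(pep)
            e = entries.setdefault(
                key, {"proteins": set(), "taxa": set(), "ec": set(), "ko": set()}
            )
            e["proteins"].add(rec.id)
            e["taxa"] |= taxa
            e["ec"] |= rec.ec
            e["ko"] |= rec.ko
    return PeptideIndex(params=params, entries=entries)


def assign_lca(peptide: str, index: PeptideIndex, tax: TaxonomyTree) -> str:
    """LCA taxon of a peptide, or the "unmapped" marker if absent.

    The LCA is the deepest taxonomy node that is an ancestor-or-self of
    every taxon whose proteins contain the peptide.
    """
    entry = index.get(peptide)
    if entry is None:
        return UNMAPPED
    return tax.lca(entry["taxa"])


class PeptideTable:
    """Peptide x sample spectral counts with LCA/EC/KO annotations."""

    def __init__(self, matrix: AbundanceMatrix, annotations: pd.DataFrame):
        # annotations: index = peptide, columns lca (str), ec, ko (frozenset), mapped (bool)
        self.matrix = matrix
        self.annotations = annotations.loc[matrix.features]

    @property
    def peptides(self) -> list[str]:
        return self.matrix.features

    @property
    def samples(self) -> list[str]:
        return self.matrix.samples

    def write(self, counts_path, annotations_path) -> None:
        df = self.matrix.values.copy()
        df.index.name = "peptide"
        df.to_csv(counts_path, sep="\t")
        ann = self.annotations.copy()
        ann["ec"] = ann["ec"].map(lambda s: ";".join(sorted(s)))
        ann["ko"] = ann["ko"].map(lambda s: ";".join(sorted(s)))
        ann.index.name = "peptide"
        ann.to_csv(annotations_path, sep="\t")


def aggregate_peptides(
    per_sample_ids: Iterable[tuple[str, str, int]],
    index: PeptideIndex | None = None,
    taxonomy: TaxonomyTree | None = None,
) -> PeptideTable:
    """Build the peptide abundance table from per-sample identifications.

    ``per_sample_ids`` yields (sample, peptide, spectral count) rows;
    duplicate (sample, peptide) rows are summed with a warning. Missing
    combinations are zero. When an index and taxonomy are supplied, LCA
    and EC/KO columns are attached; peptides absent from the index are
    kept and flagged unmapped.
    """
    rows = list(per_sample_ids)
    if not rows:
        raise ValidationError("no peptide identifications supplied")
    df = pd.DataFrame(rows, columns=["sample", "peptide", "count"])
    if (df["count"] <= 0).any() or (df["count"] != df["count"].astype(int)).any():
        raise ValidationError("spectral counts must be positive integers")
    if df.duplicated(subset=["sample", "peptide"]).any():
        warnings.warn("duplicate (sample, peptide) rows summed")
    samples = list(dict.fromkeys(df["sample"]))
    peptides = list(dict.fromkeys(df["peptide"]))
    pivot = (
        df.groupby(["peptide", "sample"], sort=False)["count"].sum().unstack(fill_value=0)
    )
    pivot = pivot.reindex(index=peptides, columns=samples, fill_value=0).astype(float)
    matrix = AbundanceMatrix(pivot, layer="MP")

    ann_rows = {}
    for pep in peptides:
        if index is not None and taxonomy is not None:
            entry = index.get(pep)
            if entry is None:
                ann_rows[pep] = {
                    "lca": UNMAPPED, "ec": frozenset(), "ko": frozenset(), "mapped": False,
                }
            else:
                ann_rows[pep] = {
                    "lca": taxonomy.lca(entry["taxa"]),
                    "ec": frozenset(entry["ec"]),
                    "ko": frozenset(entry["ko"]),
                    "mapped": True,
                }
        else:
            ann_rows[pep] = {
                "lca": UNMAPPED, "ec": frozenset(), "ko": frozenset(), "mapped": False,
            }
    annotations = pd.DataFrame.from_dict(ann_rows, orient="index")
    return PeptideTable(matrix, annotations)


def taxon_table_from_peptides(
    pt: PeptideTable, tax: TaxonomyTree, rank: str
) -> AbundanceMatrix:
    """Credit each peptide's counts to the rank-level ancestor of its LCA.

    Peptides whose LCA sits above the requested rank — and unmapped
    peptides — are pooled under "Unclassified" so per-sample totals are
    conserved exactly.
    """
    from .profile import UNCLASSIFIED

    target = {}
    for pep in pt.peptides:
        lca = pt.annotations.loc[pep, "lca"]
        if lca == UNMAPPED or lca not in tax.nodes:
            target[pep] = UNCLASSIFIED
            continue
        node = tax.ancestor_at_rank(lca, rank)
        target[pep] = tax.nodes[node].name if node is not None else UNCLASSIFIED
    grouped = pt.matrix.values.groupby(pd.Series(target), sort=True).sum()
    if UNCLASSIFIED in grouped.index:
        order = [i for i in grouped.index if i != UNCLASSIFIED] + [UNCLASSIFIED]
        grouped = grouped.loc[order]
    return AbundanceMatrix(grouped, layer="MP")


def unique_peptide_count(index: PeptideIndex) -> int:
    """Number of index peptides attributable to exactly one taxon.

    Merging additional proteomes into a database can only convert
    previously taxon-unique peptides into shared ones (while adding new
    peptides of its own), which is why database composition shifts the
    unique-peptide yield of a search.
    """
    return sum(1 for e in index.entries.values() if len(e["taxa"]) == 1)
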