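"""Deterministic synthetic fixtures for every pipeline stage.

Generates toy taxonomies, per-taxon proteome directories, host
proteomes, Dirichlet-multinomial ASV count tables with planted group
effects, per-sample peptide identifications drawn from in-silico
digests proportionally to taxon abundance, and annotated multi-layer
(MG/MT/MP) matrices with planted KO-level fold changes — everything the
pipeline needs to run end to end with no downloads. Each generator is
fully determined by its seed and writes a machine-readable truth record
so downstream checks are self-scoring.

Modelling choices
-----------------
* Taxon counts follow a Dirichlet-multinomial (the standard
  overdispersed compositional count model); concentration defaults
  to 50 for ASV tables. Function-level (KO) layer matrices use a much
  higher concentration (600) because functional profiles aggregate many
  genes and are far less overdispersed than taxon profiles.
* Planted multiplicative effects live on a simplex, so they perturb
  every proportion (closure); truth records therefore store the log2
  ratio of *renormalized expected proportions*, which is what any
  compositional analysis can recover.
* Protein sequences are uniform random over the 20 amino acids with
  planted cross-taxon duplicates — adequate for digestion/LCA logic; no
  biological realism is claimed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import digamma

from .core import AbundanceMatrix, ProteinRecord, SampleMetadata, TaxonNode, TaxonomyTree
from .dbbuild import LocalProteomeSource
from .io import write_fasta, write_matrix, write_metadata, write_pathway, write_taxonomy
from .core import PathwayDefinition, PathwayNode
from .peptides import DigestParams, digest

__all__ = [
    "CommunitySpec",
    "EffectSpec",
    "Community",
    "make_taxonomy",
    "make_community",
    "make_asv_counts",
    "make_peptide_ids",
    "make_layer_matrices",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class CommunitySpec:
    """Shape of a synthetic community and its proteomes."""

    seed: int = 0
    n_genera: int = 12
    genomes_per_taxon: int = 2
    proteins_per_genome: int = 20
    protein_length: tuple = (60, 240)
    duplicate_fraction: float = 0.1
    host: bool = True
    host_proteins: int = 30

    def __post_init__(self):
        if min(self.n_genera, self.genomes_per_taxon, self.proteins_per_genome) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0 <= self.duplicate_fraction < 1:
            raise ValueError("duplicate_fraction must be in [0, 1)")


@dataclass(frozen=True)
class EffectSpec:
    """Two-group experiment design with planted effects.

    ``effects`` maps a taxon (or KO) identifier to a log2 fold change
    applied multiplicatively to group B before renormalization.
    """

    seed: int = 0
    n_per_group: int = 20
    effects: dict = field(default_factory=dict)
    concentration: float = 50.0
    depth_range: tuple = (10_000, 30_000)
    group_labels: tuple = ("A", "B")
    with_covariates: bool = True

    def __post_init__(self):
        if any(not np.isfinite(v) for v in self.effects.values()):
            raise ValueError("effect sizes must be finite")
        if min(self.depth_range) <= 0:
            raise ValueError("depths must be positive")


@dataclass
class Community:
    spec: CommunitySpec
    tree: TaxonomyTree
    genera: list
    proteome_dir: Path
    host_records: list
    truth: dict

    @property
    def source(self) -> LocalProteomeSource:
        return LocalProteomeSource(self.proteome_dir)


def make_taxonomy(n_genera: int, genera_per_family: int = 3) -> tuple[TaxonomyTree, list[str]]:
    """Rooted toy taxonomy: root -> Bacteria -> families -> genera."""
    nodes = {
        "root": TaxonNode("root", "unranked", "root"),
        "Bacteria": TaxonNode("Bacteria", "domain", "root"),
    }
    genera = []
    for g in range(n_genera):
        fam = f"Family_{g // genera_per_family + 1:02d}"
        if fam not in nodes:
            nodes[fam] = TaxonNode(fam, "family", "Bacteria")
        gid = f"Genus_{g + 1:02d}"
        nodes[gid] = TaxonNode(gid, "genus", fam)
        genera.append(gid)
    nodes["Eukaryota"] = TaxonNode("Eukaryota", "domain", "root")
    nodes["Host"] = TaxonNode("Host", "species", "Eukaryota")
    return TaxonomyTree(nodes), genera


def _random_protein(rng: np.random.Generator, length_range: tuple) -> str:
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    return "".join(_AA[i] for i in rng.integers(0, len(_AA), size=length))


def make_community(spec: CommunitySpec, out_dir: str | Path) -> Community:
    """Write a proteome directory layout, taxonomy, host FASTA and truth
    file under ``out_dir``; fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    out = Path(out_dir)
    proteome_dir = out / "proteomes"
    proteome_dir.mkdir(parents=True, exist_ok=True)
    tree, genera = make_taxonomy(spec.n_genera)

    ko_pool = [f"K{i:05d}" for i in range(1, 41)]
    ec_pool = [f"{a}.{b}.{c}.{d}" for a, b, c, d in rng.integers(1, 8, size=(20, 4))]

    records_flat: list[ProteinRecord] = []
    by_taxon_genome: dict[str, dict[str, list[ProteinRecord]]] = {}
    for genus in genera:
        by_taxon_genome[genus] = {}
        for g in range(spec.genomes_per_taxon):
            genome_id = f"{genus}_genome_{g + 1}"
            recs = []
            for p in range(spec.proteins_per_genome):
                rid = f"{genome_id}_p{p + 1:03d}"
                seq = _random_protein(rng, spec.protein_length)
                ko = frozenset({str(rng.choice(ko_pool))}) if rng.random() < 0.5 else frozenset()
                ec = frozenset({str(rng.choice(ec_pool))}) if rng.random() < 0.3 else frozenset()
                rec = ProteinRecord(rid, genus, seq, ec, ko)
                recs.append(rec)
                records_flat.append(rec)
            by_taxon_genome[genus][genome_id] = recs

    # plant exact duplicates by overwriting sequences with earlier ones
    n_dup = int(spec.duplicate_fraction * len(records_flat))
    dup_pairs = []
    if n_dup:
        targets = rng.choice(np.arange(1, len(records_flat)), size=n_dup, replace=False)
        for t in sorted(int(x) for x in targets):
            s = int(rng.integers(0, t))
            src, tgt = records_flat[s], records_flat[t]
            new = ProteinRecord(tgt.id, tgt.taxon, src.sequence, tgt.ec, tgt.ko)
            records_flat[t] = new
            genome_id = "_".join(tgt.id.split("_")[:-1])
            recs = by_taxon_genome[tgt.taxon][genome_id]
            recs[[r.id for r in recs].index(tgt.id)] = new
            dup_pairs.append({"copy": tgt.id, "source": src.id})

    for genus, genomes in by_taxon_genome.items():
        gdir = proteome_dir / genus
        gdir.mkdir(exist_ok=True)
        for genome_id, recs in genomes.items():
            write_fasta(recs, gdir / f"{genome_id}.faa")

    host_records = []
    if spec.host:
        for p in range(spec.host_proteins):
            host_records.append(
                ProteinRecord(
                    f"Host_p{p + 1:03d}",
                    "Host",
                    _random_protein(rng, spec.protein_length),
                )
            )
        write_fasta(host_records, out / "host.faa")
    write_taxonomy(tree, out / "taxonomy.tsv")

    distinct = len({r.sequence for r in records_flat})
    truth = {
        "seed": spec.seed,
        "n_records": len(records_flat),
        "n_distinct_sequences": distinct,
        "planted_duplicates": dup_pairs,
        "n_planted_duplicates": len(dup_pairs),
        "genera": genera,
    }
    with open(out / "community_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return Community(
        spec=spec,
        tree=tree,
        genera=genera,
        proteome_dir=proteome_dir,
        host_records=host_records,
        truth=truth,
    )


def _expected_group_proportions(
    base: pd.Series, feature_taxa: dict, effects: dict
) -> tuple[pd.Series, pd.Series]:
    """Expected renormalized per-feature proportions in groups A and B."""
    props_a = base / base.sum()
    mult = pd.Series(
        [2.0 ** effects.get(feature_taxa[f], 0.0) for f in base.index], index=base.index
    )
    scaled = props_a * mult
    props_b = scaled / scaled.sum()
    return props_a, props_b


def make_asv_counts(
    tree: TaxonomyTree,
    feature_taxa: dict,
    effects: EffectSpec,
    base: pd.Series | None = None,
    out_dir: str | Path | None = None,
) -> tuple[AbundanceMatrix, SampleMetadata, dict]:
    """Dirichlet-multinomial ASV counts for a two-group design.

    ``feature_taxa`` maps ASV ids to taxonomy nodes; planted effects in
    ``effects.effects`` are keyed by taxonomy node (all its ASVs get the
    multiplier in group B). ``base`` supplies per-ASV base weights
    (drawn log-normally when omitted). The truth record stores, per
    affected taxon, the expected log2 ratio of renormalized group
    proportions — the compositionally recoverable effect.
    """
    rng = np.random.default_rng(effects.seed)
    asvs = list(feature_taxa)
    if base is None:
        base = pd.Series(np.exp(rng.normal(0.0, 1.0, size=len(asvs))), index=asvs)
    base = base.loc[asvs]
    unknown = sorted(set(effects.effects) - {feature_taxa[a] for a in asvs})
    if unknown:
        raise ValueError(f"effects reference taxa with no ASVs: {unknown}")
    props_a, props_b = _expected_group_proportions(base, feature_taxa, effects.effects)

    la, lb = effects.group_labels
    samples, groups = [], []
    for g, label in ((la, la), (lb, lb)):
        for i in range(effects.n_per_group):
            samples.append(f"{label}{i + 1:02d}")
            groups.append(label)
    counts = np.zeros((len(asvs), len(samples)), dtype=float)
    conc = effects.concentration
    for j, label in enumerate(groups):
        props = props_a if label == la else props_b
        p = rng.dirichlet(conc * props.to_numpy())
        depth = int(rng.integers(effects.depth_range[0], effects.depth_range[1] + 1))
        counts[:, j] = rng.multinomial(depth, p)
    matrix = AbundanceMatrix(pd.DataFrame(counts, index=asvs, columns=samples), layer="AS")

    meta = pd.DataFrame(index=pd.Index(samples, name="sample"))
    meta["group"] = groups
    covariates = []
    if effects.with_covariates:
        meta["age"] = np.round(rng.normal(45, 12, size=len(samples)), 1)
        meta["sex"] = rng.choice(["F", "M"], size=len(samples))
        covariates = ["age", "sex"]
    metadata = SampleMetadata(meta, phenotype="group", covariates=covariates)

    taxon_truth = {}
    for taxon, fc in effects.effects.items():
        in_taxon = [a for a in asvs if feature_taxa[a] == taxon]
        pa = float(props_a.loc[in_taxon].sum())
        pb = float(props_b.loc[in_taxon].sum())
        # a linear model on log abundances estimates the difference of
        # *expected log* proportions; a summed subset of a Dirichlet is
        # Beta(conc*p, conc*(1-p)), so E[ln p_S] = psi(conc*p) - psi(conc)
        log_scale = (digamma(conc * pb) - digamma(conc * pa)) / np.log(2.0)
        taxon_truth[taxon] = {
            "planted_log2fc": fc,
            "expected_log2_ratio": float(np.log2(pb / pa)),
            "expected_log2_ratio_log_scale": float(log_scale),
            "base_proportion": pa,
        }
    truth = {
        "seed": effects.seed,
        "effects": taxon_truth,
        "depth_range": list(effects.depth_range),
        "concentration": conc,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_matrix(matrix, out / "asv_counts.tsv")
        write_metadata(metadata, out / "metadata.tsv")
        pd.Series(feature_taxa, name="taxon").rename_axis("feature").to_csv(
            out / "asv_taxa.tsv", sep="\t"
        )
        with open(out / "asv_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return matrix, metadata, truth


def make_peptide_ids(
    community: Community,
    taxon_abundance: pd.DataFrame,
    n_psms: int = 2000,
    seed: int = 0,
    params: DigestParams = DigestParams(),
    out_dir: str | Path | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Per-sample peptide identifications sampled from taxon digests.

    ``taxon_abundance`` is taxa x samples (relative or raw); for each
    sample, ``n_psms`` peptide-spectrum matches are drawn, each from a
    taxon chosen proportionally to its abundance, then a tryptic
    peptide uniformly from that taxon's digest pool. Returns
    ``{sample: [(peptide, count), ...]}`` plus a truth table of the
    generating taxon per (sample, peptide) draw.
    """
    rng = np.random.default_rng(seed)
    pools = {}
    for genus in community.genera:
        peps = []
        for _genome, recs in community.source.lookup(genus):
            for rec in recs:
                peps.extend(digest(rec.sequence, params))
        pools[genus] = sorted(set(peps))
    taxa = [t for t in taxon_abundance.index if t in pools and pools[t]]
    if not taxa:
        raise ValueError("no taxa with digestible proteomes in the abundance table")

    per_sample: dict[str, list] = {}
    truth_rows = []
    for sample in taxon_abundance.columns:
        weights = taxon_abundance.loc[taxa, sample].to_numpy(dtype=float)
        if weights.sum() <= 0:
            raise ValueError(f"sample {sample!r} has zero taxon abundance")
        probs = weights / weights.sum()
        draws = rng.multinomial(n_psms, probs)
        tallies: dict[str, int] = {}
        for taxon, k in zip(taxa, draws):
            if k == 0:
                continue
            picks = rng.integers(0, len(pools[taxon]), size=k)
            for i in picks:
                pep = pools[taxon][int(i)]
                tallies[pep] = tallies.get(pep, 0) + 1
                truth_rows.append({"sample": sample, "peptide": pep, "taxon": taxon})
        per_sample[sample] = sorted(tallies.items())
    truth = pd.DataFrame(truth_rows, columns=["sample", "peptide", "taxon"])
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sample, rows in per_sample.items():
            pd.DataFrame(rows, columns=["peptide", "count"]).to_csv(
                out / f"{sample}.tsv", sep="\t", index=False
            )
        truth.to_csv(out / "psm_truth.tsv", sep="\t", index=False)
    return per_sample, truth


def make_layer_matrices(
    effects: EffectSpec | None = None,
    n_kos: int = 30,
    features_per_ko: dict | None = None,
    layer_effects: dict | None = None,
    planted_base_share: float = 0.05,
    out_dir: str | Path | None = None,
) -> tuple[dict, SampleMetadata, PathwayDefinition, dict]:
    """Annotated MG/MT/MP feature matrices with planted KO-level ratios.

    ``layer_effects`` maps layer -> {KO id: log2 fold change in group B}.
    Every feature carries exactly one KO; half the KOs also map to an EC
    number, shared across layers so pathway nodes can match either id.
    Each planted KO's base weight is pinned to ``planted_base_share`` of
    the layer total so its abundance sits well above the sampling-noise
    floor; truth records the exact expected post-renormalization log2
    ratio per (layer, KO). Returns (layers, metadata, pathway
    definition, truth).
    """
    if effects is None:
        effects = EffectSpec(concentration=600.0, n_per_group=16)
    layer_effects = layer_effects or {}
    features_per_ko = features_per_ko or {"MG": 3, "MT": 2, "MP": 2}
    rng = np.random.default_rng(effects.seed)

    kos = [f"K{i:05d}" for i in range(1, n_kos + 1)]
    ko_to_ec = {
        ko: f"{(i % 6) + 1}.{(i % 5) + 1}.{(i % 9) + 1}.{i + 1}"
        for i, ko in enumerate(kos)
        if i % 2 == 0
    }

    la, lb = effects.group_labels
    samples = [f"{la}{i + 1:02d}" for i in range(effects.n_per_group)] + [
        f"{lb}{i + 1:02d}" for i in range(effects.n_per_group)
    ]
    groups = [la] * effects.n_per_group + [lb] * effects.n_per_group

    layers: dict[str, AbundanceMatrix] = {}
    truth: dict = {"seed": effects.seed, "layers": {}}
    for layer, per_ko in features_per_ko.items():
        feats, feat_ko = [], {}
        for ko in kos:
            for r in range(per_ko):
                fid = f"{layer}_{ko}_f{r + 1}"
                feats.append(fid)
                feat_ko[fid] = ko
        # a few unannotated features that must be dropped with a tally
        for u in range(3):
            feats.append(f"{layer}_unann_f{u + 1}")
        base = pd.Series(np.exp(rng.normal(0.0, 0.8, size=len(feats))), index=feats)
        eff = layer_effects.get(layer, {})
        for ko in eff:
            members = [f for f in feats if feat_ko.get(f) == ko]
            if members:
                rest = float(base.drop(members).sum())
                target = planted_base_share * rest / (1.0 - planted_base_share)
                base.loc[members] *= target / float(base.loc[members].sum())
        feature_effect = {f: eff.get(feat_ko.get(f), 0.0) for f in feats}
        props_a, props_b = _expected_group_proportions(
            base, {f: f for f in feats}, feature_effect
        )
        counts = np.zeros((len(feats), len(samples)))
        for j, g in enumerate(groups):
            props = props_a if g == la else props_b
            p = rng.dirichlet(effects.concentration * props.to_numpy())
            depth = int(rng.integers(effects.depth_range[0], effects.depth_range[1] + 1))
            counts[:, j] = rng.multinomial(depth, p)
        ann = pd.DataFrame(index=feats, columns=["taxon", "ec", "ko"], dtype=object)
        for f in feats:
            ko = feat_ko.get(f)
            ann.at[f, "taxon"] = None
            ann.at[f, "ko"] = frozenset({ko}) if ko else frozenset()
            ann.at[f, "ec"] = (
                frozenset({ko_to_ec[ko]}) if ko in ko_to_ec else frozenset()
            )
        layers[layer] = AbundanceMatrix(
            pd.DataFrame(counts, index=feats, columns=samples),
            feature_annotations=ann,
            layer=layer if layer in AbundanceMatrix.LAYERS else None,
        )
        ko_truth = {}
        annotated = [f for f in feats if f in feat_ko]
        # function aggregation credits a feature to its KO and, when one
        # exists, also to its EC, so the function-level total weights
        # EC-mapped features twice; the truth must use the same totals
        w = pd.Series(
            {f: 2.0 if feat_ko.get(f) in ko_to_ec else 1.0 for f in annotated}
        )
        tot_a = float((props_a.loc[annotated] * w).sum())
        tot_b = float((props_b.loc[annotated] * w).sum())
        for ko in kos:
            members = [f for f in annotated if feat_ko[f] == ko]
            pa = float(props_a.loc[members].sum())
            pb = float(props_b.loc[members].sum())
            pa_n = pa / tot_a
            pb_n = pb / tot_b
            ko_truth[ko] = {
                "planted_log2fc": eff.get(ko, 0.0),
                "expected_log2_ratio": float(np.log2(pb_n / pa_n)),
            }
        truth["layers"][layer] = ko_truth

    meta = pd.DataFrame(index=pd.Index(samples, name="sample"))
    meta["group"] = groups
    metadata = SampleMetadata(meta, phenotype="group")

    # 12-node pathway over the KO pool; nodes carry 1-3 KOs plus their ECs
    nodes = {}
    ko_cycle = list(kos)
    idx = 0
    for n in range(12):
        take = 1 + (n % 3)
        node_kos = []
        for _ in range(take):
            node_kos.append(ko_cycle[idx % len(ko_cycle)])
            idx += 1
        ecs = frozenset(ko_to_ec[k] for k in node_kos if k in ko_to_ec)
        nodes[f"node_{n + 1:02d}"] = PathwayNode(
            label=f"step {n + 1}", kos=frozenset(node_kos), ecs=ecs
        )
    pathway = PathwayDefinition(id="toy_pathway", nodes=nodes)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for layer, m in layers.items():
            write_matrix(m, out / f"{layer.lower()}_counts.tsv")
            ann = m.feature_annotations.copy()
            ann["ko"] = ann["ko"].map(lambda s: ";".join(sorted(s)))
            ann["ec"] = ann["ec"].map(lambda s: ";".join(sorted(s)))
            ann.drop(columns=["taxon"]).rename_axis("feature").to_csv(
                out / f"{layer.lower()}_annotations.tsv", sep="\t"
            )
        write_metadata(metadata, out / "layer_metadata.tsv")
        write_pathway(pathway, out / "pathway.tsv")
        with open(out / "layer_truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return layers, metadata, pathway, truth
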