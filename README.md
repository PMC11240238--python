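# metaomix

A toolkit for integrated multi-omics analysis of microbial communities
across four layers: amplicon sequencing (AS), metagenomics (MG),
metatranscriptomics (MT) and metaproteomics (MP). It targets the
bespoke computational core of such studies — the stages between the
standard read-processing tools and the biological interpretation:

* **Amplicon-driven protein-database construction.** Aggregate an ASV
  count table to a chosen taxonomic rank, pick the top-*n* most
  abundant taxa, collect their proteomes from a local source, remove
  exact-sequence redundancy (first occurrence kept, annotations
  unioned, all source taxa retained in a sidecar), and merge an
  optional host proteome — producing the search space for MS/MS
  peptide identification.
* **Peptide-level taxonomy and function.** In-silico tryptic digestion
  (cleave after K/R unless before P; configurable missed cleavages,
  length bounds, I/L equivalence) indexes every peptide of the database
  with its proteins, source taxa and EC/KO annotations. Identified
  peptides are assigned the **lowest common ancestor (LCA)** of the
  taxa that could have produced them, and peptide spectral counts roll
  up into rank-level taxon abundance tables.
* **Differential abundance.** Per-feature ordinary least squares of the
  normalized, log-transformed abundance on a phenotype plus covariates:
  for feature *i* and sample *j*,

      log2 TSS(x)_ij = β0_i + β1_i · phenotype_j + Σ_k γ_ik · covariate_jk + ε_ij

  with two-sided t-tests on coefficients and Benjamini–Hochberg FDR
  across features within each term. With two groups and no covariates
  this reduces exactly to the classical equal-variance t-test.
* **Pathway-level integration with split nodes.** Each layer is
  aggregated to shared KO/EC identifiers, total-sum scaled, and
  summarized as log2(mean abundance in group B / group A). Matched
  identifiers fill a pathway's nodes with one column per omics layer —
  the split-node table — so a single enzymatic step can show, e.g.,
  reduced gene abundance but increased protein abundance.
* **Joint ordination.** A multi-block SVD ordination (CLR per block,
  feature centring, unit-total-variance block scaling, shared sample
  scores) places all layers and the metadata covariates on one biplot.
* **Synthetic fixtures.** Deterministic generators for toy taxonomies,
  proteome directories, Dirichlet-multinomial ASV counts with planted
  effects, peptide identifications drawn from taxon digests, and
  annotated multi-layer matrices with planted KO-level fold changes —
  every stage runs end to end with no downloads, and truth files make
  the results self-scoring.

## Worked example

Simulate a small community and run the amplicon half of the pipeline:

```
$ metaomix simulate community --seed 7 --n-genera 8 --out-dir fixtures
community: 8 genera, 320 proteins (288 distinct sequences)

$ metaomix simulate asv --community-dir fixtures --seed 8 --n-per-group 6 \
    --effect Genus_05=2.0 --out-dir fixtures/asv
ASV table: 16 ASVs x 12 samples

$ metaomix profile --asv fixtures/asv/asv_counts.tsv \
    --taxonomy fixtures/taxonomy.tsv --asv-taxa fixtures/asv/asv_taxa.tsv \
    --rank genus --top-n 5 --out-dir out
top 5 taxa at genus level:
  Genus_05      0.4491
  Genus_07      0.2048
  Genus_06      0.1106
  Genus_04      0.0840
  Genus_08      0.0778

$ metaomix builddb --asv fixtures/asv/asv_counts.tsv \
    --taxonomy fixtures/taxonomy.tsv --asv-taxa fixtures/asv/asv_taxa.tsv \
    --source-dir fixtures/proteomes --host fixtures/host.faa \
    --rank genus --top-n 5 --out out/db.faa --report out/report.tsv
database: 200 raw -> 192 nonredundant (+30 host) = 222 total proteins
```

The ranked list is the mean per-sample relative abundance of each
genus (`Genus_05` carries the planted 4-fold group effect, which also
raises its mean share). The database report counts the proteins
collected for the 5 genera (200), the distinct sequences among them
(192) and the final size after host merge and global deduplication
(222).

Differential abundance on the aggregated table then recovers the
planted effect:

```
$ metaomix da --matrix out/as_genus_counts.tsv \
    --metadata fixtures/asv/metadata.tsv --phenotype group \
    --covariates age,sex --out-dir out/da
Differential abundance (OLS per feature, BH within term)
  features tested : 8
  features filtered: 0
  normalization/transform: TSS/log
  term group[B]: 3 features at q<0.05
    Genus_05                 coef=+1.285 se=0.192 p=1.55e-04 q=6.19e-04
    Genus_07                 coef=-1.222 se=0.166 p=7.85e-05 q=6.19e-04
    ...
```

`Genus_05`'s coefficient (+1.29 log2 units) is the planted enrichment
after compositional closure — raising one abundant genus 4-fold
necessarily depresses every other relative abundance, which is why
`Genus_07` appears depleted. A full multi-layer run (database, peptide
tables, per-layer models, split-node pathway table, joint ordination)
is driven by a YAML config:

```
$ metaomix run --config run.yaml
```

with stage outputs, content hashes and skip/rerun decisions recorded
in `out/manifest.json`.

The same functionality is available as a library
(`metaomix.profile`, `metaomix.dbbuild`, `metaomix.peptides`,
`metaomix.da` with its `DifferentialAbundanceModel` / `DAResults`
objects, `metaomix.pathways`, `metaomix.ordination`,
`metaomix.simulate`). See `docs/methods.md` for the modelling details
and design choices.

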