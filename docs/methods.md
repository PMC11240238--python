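# Methods

This note records the models, parameter choices and numerical
conventions behind each stage, what the synthetic fixtures do and do
not emulate, and the design decisions taken where several reasonable
options existed.

## Amplicon profiling and taxon ranking

ASV counts are summed into taxa at a user-chosen rank by walking each
feature's lineage; features whose lineage does not pass through that
rank are pooled under the reserved name `Unclassified`, so per-sample
totals are conserved exactly (integer sums). "Most abundant" is
defined as the **mean per-sample relative abundance** (total-sum
scaling per sample, then the mean across samples). This makes the
ranking invariant to sequencing depth: summed raw counts would let one
deep sample dominate the selection. Ranking by summed counts remains
available (`--rank-by total-count`). Exact score ties are broken
lexicographically so results are deterministic. `Unclassified` never
enters the top-*n* (no proteome can be retrieved for it).

## Database construction

Proteomes are collected in ranked-taxon order, then genome order
(sorted ids), then record order, so two runs on identical inputs give
byte-identical FASTA output. Redundancy removal is **exact full-length
sequence identity** only — no clustering below 100% identity. The
survivor is the first record in collection order; its EC/KO sets
become the union over all duplicates, and the full set of source taxa
per kept record is written to a sidecar table. Discarding duplicate
taxa would silently bias the downstream LCA toward the surviving
record's taxon. Host proteins are appended and the merged set is
deduplicated again (microbial records win ties by order), a choice we
make explicit because a host sequence identical to a microbial one
must count as ambiguous for LCA purposes. "Cleaning" removes records
with empty sequences or residues outside the amino-acid alphabet.
Remote proteome fetching is an interface contract only
(`RemoteProteomeSource`); all tested paths use the local directory
layout `<root>/<taxon>/<genome>.faa`.

## Peptide digestion, indexing and LCA

Trypsin is modelled as cleavage after K or R except before P, the
plain rule without the WKP/MRP exception clauses of the full ExPASy
regex (verified against both a substring-enumeration oracle and
pyteomics' cleaving machinery under the same rule). Defaults follow
common MS practice: up to 2 missed cleavages, peptide length 7–45,
I/L equated (leucine and isoleucine are isobaric). Digest output is
ordered by start position, then by missed-cleavage count, with
duplicates retained.

Peptide assignment runs against the constructed database itself rather
than an external reference, so taxonomy and function are always
consistent with the search space that produced the identifications.
A peptide's taxon set is the union over all containing proteins
(including sidecar duplicate taxa); its LCA is the deepest node that
is ancestor-or-self of every member, computed by pairwise
depth-equalising walks and tested against root-path intersection.
EC/KO annotation is the **union** over containing proteins — an
intersection is empty too often on sparsely annotated databases.
Peptide abundance is the summed spectral count; no intensity-based
quantification. In rank-level taxon tables, peptides whose LCA sits
above the requested rank, and unmapped peptides, pool into
`Unclassified` so column totals are conserved.

## Differential abundance

Per feature, ordinary least squares of the transformed abundance on an
intercept, the phenotype, and covariates (categoricals dummy-coded
against a reference level, first sorted level by default); two-sided
t-tests on each non-intercept coefficient; Benjamini–Hochberg across
features within each term. OLS is used throughout — no mixed,
zero-inflated or count models.

Processing order: when the matrix contains zeros and a log/CLR
transform is requested, the pseudocount (default 0.5) is added to
**all entries on the raw count scale** — i.e. half a count — *before*
total-sum scaling; applying it after TSS would swamp relative
abundances that are O(1e-4). All-positive matrices get no pseudocount.
All logarithms are base 2, so two-group coefficients read directly as
log2 fold changes and match the pathway stage's ratio scale. CLR is
the per-sample log2 values minus their per-sample mean. Defaults:
TSS + log, pseudocount 0.5, prevalence filter 0.1 (a feature must
exceed the abundance floor in ≥10% of samples); every choice is
configurable, and features removed by filtering or constant after
transform are listed in a ledger rather than silently dropped.
Designs are rejected (with the offending terms named) when the model
matrix is rank deficient or leaves fewer than 3 residual degrees of
freedom.

## Pathway-level integration

Features are aggregated to their annotated KO/EC identifiers; a
feature carrying *k* identifiers contributes its full abundance to
each (the convention of KEGG mapping tools), with an optional
even-split alternative. The per-layer summary is

    log2( mean_B TSS(x) + ε ) − log2( mean_A TSS(x) + ε )

computed per identifier. Total-sum scaling before the group means is
what makes the ratio library-size invariant — this is the "fold
change normalization" hook, and it is isolated so another scaling
could be substituted. ε defaults to half the smallest nonzero
normalized value in the layer, guaranteeing finite ratios; on strictly
positive data the ε→0 limit is the exact log2 ratio of group means.
The difference-of-logs form makes group-swap antisymmetry bitwise
exact. Split-node assembly fills each pathway node, per layer, with
the mean ratio over the node's matched identifiers (or the
largest-magnitude one under `max_abs`); a cell exists iff at least one
identifier matched. Rendering is a node × layer heatmap with a
diverging palette centred at 0, red = up and green = down in group B,
plus a bit-exact TSV companion; drawing on curated pathway-map images
is out of scope. Statistical testing of the ratios is deliberately
left to the differential-abundance stage.

## Joint ordination

Each block is CLR-transformed (same pseudocount convention as above),
feature-centred across samples, and scaled to unit total variance so
that no layer dominates by feature count or variance; the concatenated
matrix is decomposed by SVD. Scores are U·S (shared across blocks),
loadings split back per block, explained variance is the normalized
squared singular values. The sign of each axis is fixed by making its
largest-magnitude loading entry positive, which makes results
reproducible to the byte. Numeric covariates are displayed as
correlation arrows against the score axes; categorical covariates as
level centroids. This is a transparent multi-block principal-component
ordination: it serves the joint-visualization role of model-based
compositional integration methods but is methodologically simpler, and
no attempt is made to reproduce any such method's coordinates.

## Synthetic fixtures

The generators emulate the *structure* of real multi-omics studies —
two-group designs with age/sex covariates, compositional counts,
peptides drawn from taxon proteomes proportionally to abundance,
planted KO-level fold changes — at desk scale (defaults: 12 genera,
2 genomes per genus, 20 proteins per genome, 16–80 samples,
10k–30k reads). Specifics:

* **Counts** follow a Dirichlet-multinomial. Concentration defaults to
  50 for ASV tables (strong overdispersion, typical of taxon
  profiles). Function-level layer matrices use concentration 600:
  KO-level profiles aggregate many genes and vary far less between
  replicate samples than taxon counts do; at concentration 50 the
  sampling noise of a between-group log2 ratio alone would exceed a
  quarter log2 unit at these sample sizes, which does not describe
  function-level data.
* **Planted effects live on a simplex.** A multiplicative effect on one
  taxon changes every proportion after renormalization (closure), so
  truth files record the **expected log2 ratio of renormalized
  proportions**, not the nominal multiplier. For linear models on
  log-transformed data the truth is taken one step further: the model
  estimates the difference of *expected logs*, and a summed subset of
  a Dirichlet vector is Beta(cp, c(1−p)), so the truth uses
  E[ln p] = ψ(cp) − ψ(c) exactly. Planted KOs in layer matrices are
  pinned to a base share of 5% of the layer so their ratios sit well
  above the sampling-noise floor.
* **Protein sequences are uniform random** over the 20 amino acids with
  a planted fraction of exact cross-taxon duplicates. This exercises
  digestion, indexing, deduplication and LCA logic correctly, but it
  makes shared peptides between taxa far rarer than in real proteomes,
  where homology is pervasive. Passing tests therefore demonstrate the
  correctness of the machinery, not the LCA resolution attainable on
  real communities.
* Covariates are generated but carry no planted effect; the
  confounding behaviour of the models is tested with purpose-built
  data instead.

Recovery experiments average the estimated coefficient over five
replicate simulations: the quantity under test is the estimator's
mean, and a single dataset would confound estimator bias with one
draw's sampling noise.

## Run configuration and caching

A YAML config selects a module preset (1–6, the classic layer
combinations from amplicon-only up to AS+MG+MT+MP) or an explicit
stage list. Validation reports every violation at once. The runner
hashes each stage's input files and parameters; a stage is skipped
when its hash matches the previous manifest and all recorded outputs
still match their content hashes — a deliberate, dependency-free
replacement for a workflow engine's DAG. The manifest contains no
timestamps (they live in the JSON-lines log), and figures are rendered
with a fixed SVG hash salt and stripped date metadata, so identical
inputs yield a byte-identical manifest.

## Problem sizes

Tests and the acceptance script run on communities of 8–12 genera
(480 proteins), peptide pools of a few thousand, 500-feature null
panels at 40 samples, and 16-per-group layer matrices — sizes chosen
so every oracle comparison is exhaustive and the full suite plus the
acceptance script complete in well under a minute on one CPU.

## Known limitations

* No MS/MS search or FDR modelling: spectral identifications enter as
  given peptide/count lists, so search-engine effects (decoy
  competition, score calibration) are outside the model.
* OLS on log-transformed proportions ignores the mean–variance
  relation of counts at very low abundance; the prevalence filter is
  the only guard.
* Exact-identity deduplication does not collapse near-identical
  isoforms, matching its specification but not reducing database size
  as aggressively as clustering tools would.
* The ordination is not a compositional model; CLR mitigates but does
  not remove closure effects.
* Taxon identifiers are opaque strings; no external taxonomy service
  is consulted.
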