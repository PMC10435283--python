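# Methods

`orthobridge` builds a labeled-property knowledge graph for translational
plant genomics: it connects genes across species through orthology and
collinearity, and layers quantitative-genetics (QTL), expression and
functional-annotation evidence on top, so that knowledge established in a
well-studied species can be transferred to the orthologous loci of
less-studied relatives. This note documents the models, rules and design
choices; everything stated here is computed by the test suite or the
acceptance script, not asserted from memory.

## Graph model

Nodes carry a non-empty set of labels plus scalar/list properties; edges
are directed, typed, and may carry properties. Core labels cover the
genomic backbone (Species, Chromosome, Gene, RNA, Protein), the
comparative layer (Orthogroup, Synteny), genetics (QTL with a second label
BiparentalPopulation or DiversityPanel, Trait, Marker, Population, Site),
transcriptomics (Sample, Condition — the latter double-labeled RNASeq) and
vocabularies (GO, PO, PECO, MapMan, FunctionalAnnotation, GeneFamily,
Resource). A schema registry constrains admissible labels and
(edge type, source label, target label) triples; the build pipeline runs
in strict mode so malformed ETL output fails at insertion, and the
registry is explicitly extensible for new data layers. Edge direction
conventions (Gene→RNA `HAS_TRANSCRIPT`, Gene→Orthogroup `MEMBER_OF`,
Gene→QTL `COLOCALIZES_WITH` / `IS_CLOSEST_TO_PEAK`, child-term→parent-term
`SCO` / `PART_OF`, …) are fixed so query code and exports are
deterministic.

The graph is held in plain dictionaries with a label index and per-node
adjacency sets rather than delegating to a general graph library: the
schema checking, idempotent `merge_node`/`merge-edge` semantics and sorted
traversal order are the module's contract, and the index-consistency
invariant (label counts equal a full rescan) is tested directly.

## Coordinates and input formats

All coordinates are 1-based inclusive (GFF3 convention) everywhere in
memory; half-open arithmetic exists only inside individual operations
(e.g. the interval tree used for colocalization). Chromosome-ID conversion
tables are strict — a chromosome missing from a supplied table is an
error, because silently passing IDs through can mask collisions between
species that the graph requires to be globally unique.

GFF3 is read through `gffutils` (gene/mRNA/CDS features with ID/Parent
attributes); a pre-scan reports duplicated gene IDs by name. OBO 1.4
ontologies are read through `obonet`, keeping the `is_a` and `part_of`
predicates; acyclicity is verified on load. Orthogroup tables follow the
OrthoFinder `Orthogroups.tsv` layout. Collinearity files follow the
MCScanX layout (`## Alignment k: … N=n chrA&chrB plus|minus` headers with
exactly `n` pair lines) and are parsed by hand since no installed library
reads that format. QTL tables are CSV with remappable column names —
upstream QTL curation has no standard schema, so the documented defaults
(`qtl_id, trait, study_type, chromosome, flank_left, flank_right, peak,
population, site, reference`) are a convention, not an assumption about
third-party files.

## Longest-isoform selection

One transcript per gene is retained: the greatest summed CDS length, ties
broken by lexicographically smallest transcript ID. CDS length is the
standard proxy for "longest isoform" in annotation toolkits because UTR
annotation quality varies widely between genomes. The operation is
idempotent.

## Collinear-block detection

Chaining operates on gene *ranks* — ordinal position along the chromosome
after isoform selection — not base pairs; bp spans are derived afterwards
as the hull of member genes. For every pair of chromosomes (including
intra-species pairs; a chromosome against itself excludes the trivial
diagonal and mirrored duplicates by requiring rank_a < rank_b), the
candidate matches are gene pairs sharing an orthogroup. Tandem duplicates
— consecutive genes of one orthogroup on a chromosome — contribute only
their first-ranked member, which prevents degenerate vertical chains.

A block is a chain of matches strictly monotone in both rank sequences
(increasing/increasing = `plus`, increasing/decreasing = `minus`) with
consecutive rank gaps of at most `max_gap` on both chromosomes. Blocks are
extracted greedily: the best remaining chain is taken, its gene pairs are
consumed, and extraction repeats until no chain of at least `min_genes`
pairs remains. "Best" is a total order — longest first, then smallest
starting rank on the first chromosome, then `plus` before `minus`, then
lexicographically smallest (rank_a, rank_b) sequence — so detection is
fully deterministic. The chain search itself is a longest-path dynamic
program over the match DAG with the same tie-break carried through.

Parameters: `min_genes = 10` (the field-standard minimum for calling a
collinear block, and the one knob the upstream pipeline exposes);
`max_gap = 25` ranks (every chaining algorithm needs a gap bound; 25 is
MCScanX's long-standing default and is exposed as configuration). A real
MCScanX `.collinearity` file can be ingested in place of the detector; the
two paths produce the same `SyntenyBlock` type.

Validation is dual-route: (i) an exhaustive oracle that enumerates *all*
maximal monotone chains by depth-first search and applies the identical
greedy/tie-break rules — exact but exponential, so oracle fixtures use
shuffled one-to-one gene orders of 15–30 genes where full enumeration is
feasible (a planted fully-collinear run of length n has ~2^n chains);
(ii) per-block invariant checks (monotonicity, gap bound, span hull) and
planted-segment recovery on larger generated genomes.

## QTL model and colocalization

A QTL record carries one to three marker positions. Loci mapped in
biparental populations have two flanking markers and optionally a peak;
association-panel (GWAS) loci are a single peak marker. The confidence
interval is the closed hull of the flanking markers. Records failing
validation (missing mandatory fields, peak outside flanks) are rejected
individually with a logged reason rather than aborting a load.

Colocalization: every gene whose body overlaps the closed confidence
interval is linked `COLOCALIZES_WITH`; point QTL use the window
`[peak − gwas_window, peak + gwas_window]` with `gwas_window = 0` by
default (without linkage-disequilibrium data there is no principled wider
interval). When a peak exists, the gene nearest to it on that chromosome —
searched genome-wide, even when the colocalizing set is empty — gets an
additional `IS_CLOSEST_TO_PEAK` edge carrying the bp distance (0 when the
peak falls inside the gene body; otherwise distance to the nearer gene
end). Distance ties resolve to the smallest gene start, then the smallest
gene ID. The implementation uses an interval tree; the test oracle is an
all-pairs scan.

## Expression rules

Genes whose TPM sum across all samples is ≤ 5 are dropped (strict `> 5`
keeps), avoiding edge clutter from non-expressed genes. Replicate samples
of a condition are averaged per gene: the arithmetic mean and the
geometric mean are both stored on the Gene→Condition edge (the geometric
mean is robust to a single high replicate; keeping both lets queries
choose). The geometric mean is `exp(mean(ln tpm))`, defined as 0 whenever
any replicate is 0 — the continuous limit, avoiding an arbitrary
pseudocount; a pseudocount is available as an option. When all replicates
are equal the geometric mean is set to the arithmetic mean exactly rather
than through the log/exp round trip (float hygiene). Per-sample TPM is
additionally stored on Gene→Sample edges so queries can drill below
condition level. Differential expression is deliberately out of scope:
the graph stores normalized expression so any cross-experiment comparison
remains possible, rather than freezing one contrast.

## Ontology semantics

Each ontology term becomes a node labeled by its source (GO/PO/PECO/
MapMan); `is_a` becomes a subclass-of (`SCO`) edge and `part_of` a
`PART_OF` edge, both child→parent. Re-loading an ontology is an idempotent
merge. Subsumption queries take the reflexive-transitive closure of
"narrower-than" over a chosen predicate set — default `{SCO, PART_OF}`,
since tissue queries like "shoot system" should match parts (pods) as well
as subtypes (leaves); the predicate set is an argument for callers who
want strict subclass reasoning. The closure is validated against a
boolean-matrix repeated-squaring oracle on random DAGs.

## Queries

All four use-case queries return flat records with documented sort keys,
so CSV exports are byte-identical across runs. "QTL in syntenic blocks"
operationalizes "contained within a block" as bp-span overlap between the
QTL interval (or point) and the block hull on the matching chromosome —
this deliberately returns QTL whose intervals contain no ortholog of the
query gene, which is the translational point of the query. Trait filtering
is case-insensitive substring matching on trait names; trait vocabularies
are not harmonized upstream, so substring matching ("flower" matching
"days to 50% flowering") is the robust choice.

## Bulk export

The exporter writes one node CSV per distinct label set (`id:ID`, typed
property columns `:int`/`:float`/`:string`/`:string[]`, `:LABEL`) and one
edge CSV per relationship type (`:START_ID`, `:END_ID`, `:TYPE`), UTF-8
with RFC 4180 quoting, rows sorted by node/edge ID, plus a tab-separated
manifest (`role	label	path`). Floats are serialized with `repr` so the
write→read round trip is the identity property-by-property; booleans are
rejected rather than coerced. The dialect follows the graph-database
bulk-import convention so the files load into a real server unchanged;
no server is required by any test.

## Synthetic data

The toy generator emits complete datasets — per-species GFF3 with
chromosome-conversion tables, orthogroup TSV, QTL CSV, TPM/count matrices,
condition metadata, mini PO/PECO/GO ontologies, functional annotations —
from a single seed (same seed ⇒ byte-identical trees). Collinear segments
of a chosen length are planted in identical order across species;
species-private noise genes are interleaved at `noise_rate` and segments
are separated by 30 private genes (more than the default rank gap, so
segments cannot merge). Background genes outside segments are
species-private by default, making planted truths exact; an option adds
shared orthogroups in independently shuffled order — homology without
conserved order. Pure-noise fixtures use 12 such shuffled orthogroups
because the longest monotone run of a random 12-permutation stays well
below the 10-gene block threshold, so "no block detected" is a property of
the condition rather than luck. The generator also plants a QTL over a
known gene run, two below-threshold expression genes, condition→tissue
assignments and a 100-record GO table with exactly 90 hidden terms.

The worked-example generator reconstructs the flowering-time scenario:
twenty orthologous slots collinear across Mt07/Ps03/Lc06/Vf05 with the
FTa1 family at slot 10 (in pea an adjacent tandem pair,
Psat3g090680/Psat3g090720), eight flowering QTL placed inside the
syntenic spans with only `qDTF.6-2_1` containing the lentil ortholog
Lcu.2RBY.6g043850, one far-away flowering QTL and one non-flowering QTL
as negative controls, a PO mini-hierarchy under "shoot system", PANTHER
domain records for the family proteins, and expression placing the
*M. truncatula* gene highest in vegetative shoot apex conditions.

What the generators do **not** emulate: sequence evolution, realistic
read-count noise beyond lognormal TPM draws, annotation errors, assembly
fragmentation, paralog interference beyond tandem pairs, and genome-scale
data volumes. Passing tests therefore demonstrate correctness of the
rules and algorithms on internally consistent inputs, not robustness to
the messiness of real annotation pipelines.

## Problem sizes and determinism

Desk-scale sizes are used throughout: 2–4 species, 24–70 genes per
chromosome, 20-seed oracle sweeps, a 100-seed pure-noise sweep, 200
genes × 20 QTL colocalization fixtures and 40-term ontologies. The full
test suite runs in well under a minute; the acceptance script recomputes
everything from scratch in a few seconds. Every random draw flows from an
explicit seed (numpy `default_rng`); no wall-clock or OS entropy is used
anywhere, and all query and export outputs are byte-stable given the same
graph.

## Known limitations

* The chain extractor is greedy; a gene pair consumed by one block cannot
  seed another, so heavily nested duplications may be under-reported
  relative to scoring-based tools. Scores/e-values of the reference
  collinearity tool are not reproduced.
* Orthogroup membership is taken as given (one orthogroup per gene);
  the package does not infer orthology from sequences.
* Trait matching is lexical; without a harmonized trait ontology,
  synonymous trait names in different vocabularies will not match.
* The property graph is in-memory and single-process: no persistence,
  transactions or query language — the bulk-CSV export is the hand-off
  point to a real graph database.
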