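# orthobridge

A desk-scale toolkit for **translational research across plant species**:
it parses genome annotations, orthogroups, collinearity, QTL, expression
and ontology inputs, applies the standard filtering and aggregation rules,
assembles a labeled-property knowledge graph, answers the recurring
comparative-genomics questions programmatically or from the shell, and
emits bulk-import CSV files ready for a graph database.

The intended user is a geneticist or breeder working on an under-studied
crop who wants to borrow evidence from better-studied relatives: *which
genes are the orthologs of my candidate? do they sit in collinear
(syntenic) blocks? which trait loci (QTL) map into those blocks in any
species? and in which tissues are the orthologs expressed?*

## The model in brief

Genes **g** are partitioned into orthogroups **O(g)** (homology clusters
from orthology inference). On each chromosome, genes are ranked by
position; for a chromosome pair, a *collinear block* is a maximal chain of
gene pairs (gᵢ, hᵢ) with O(gᵢ) = O(hᵢ), strictly monotone in both rank
sequences (same direction = `plus`, opposed = `minus`), consecutive rank
gaps ≤ 25, and length ≥ 10 — the standard minimum for calling a block.
A QTL with flanking markers defines the closed confidence interval
[fl, fr]; every gene overlapping it *colocalizes*, and the gene nearest
the peak marker is flagged with its bp distance. Expression is kept for
genes with ΣTPM > 5 across samples and summarized per condition by the
arithmetic and geometric means (GM = exp(mean ln TPM), 0 if any replicate
is 0). Ontology terms (GO/PO/PECO/MapMan) enter the graph with
subclass-of (`SCO`) and `PART_OF` edges so a query for "shoot system"
also matches data annotated with narrower terms such as "leaf" or
"vegetative shoot apex".

All of this lives in one labeled-property graph (typed nodes/edges with
key-value properties) with a strict, extensible schema. See
`docs/methods.md` for the full account.

## Worked example

The package ships a generator that reconstructs a flowering-time
use case: the *FTa1* orthogroup of *Medicago truncatula*, pea, lentil and
faba bean on chromosomes Mt07/Ps03/Lc06/Vf05, with eight flowering QTL
placed inside the syntenic spans.

```bash
orthobridge fixtures fta1 demo --seed 1
orthobridge build demo --out demo_export
# 423 nodes, 4305 edges
#   Chromosome: 4 … Gene: 97 … Orthogroup: 20 … QTL: 10 … Synteny: 6 …

orthobridge query orthologs demo MtrunA17Chr7_39606925_39618489
```

prints the four orthologs of *MtFTa1* with their positions:

```
gene_id,species,chromosome,start,end
Lcu.2RBY.6g043850,lcul,Lc06,330800000,330803500
Psat3g090680,psat,Ps03,41000000,41004000
Psat3g090720,psat,Ps03,41040000,41044000
Vfaba.Hedin2.R1.5g087000,vfab,Vf05,1201500000,1201505000
```

(The two pea genes are an adjacent tandem pair — the fixture mirrors the
real situation where two pea *FT* copies are candidate orthologs.)

Mining QTL whose intervals overlap the syntenic blocks that carry the
family — including QTL that contain **no** ortholog in their own interval,
which is exactly the translational payoff:

```bash
orthobridge query qtl-in-blocks demo MtrunA17Chr7_39606925_39618489 \
    --trait-keyword flower --csv qtl.csv
# 24 records -> qtl.csv   (8 distinct QTL, one row per overlapping block)
```

The eight distinct QTL are `DF50_09-10(2)_1`, `DF1_07-08(3)_1`,
`DF1_06-07(2)_1` (faba bean), `PR15_26_1`, `DTF3_1`, `DTF3_3` (pea) and
`qDTF.6-2_1`, `qDTFL-6A_1` (lentil); of these, only `qDTF.6-2_1` contains
a family member (the lentil gene) in its confidence interval. Expression
with ontology inference:

```bash
orthobridge query expression demo MtrunA17Chr7_39606925_39618489 \
    --tissue PO:0009006 --top-k 3
```

returns per-sample TPM restricted to conditions under "shoot system",
ranked by condition mean — for *MtFTa1* the top three are the vegetative
shoot apex, reproductive shoot apex and vegetative shoot system
conditions, while root conditions are excluded. The same operations are
available as Python functions (`find_orthologs`, `qtl_in_syntenic_blocks`,
`expression_in_tissue`, `get_protein_domains`) on the graph returned by
`orthobridge.build_graph(...)`.

`demo_export/` contains the bulk-import CSVs (`nodes_*.csv`,
`edges_*.csv` with `id:ID` / `:LABEL` / `:START_ID` / `:END_ID` / `:TYPE`
headers) plus `import_manifest.tsv`; `orthobridge.read_bulk_csv` reloads
them into an identical graph.

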