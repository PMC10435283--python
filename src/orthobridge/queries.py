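"""The four use-case queries, as a programmatic API over the property graph.

Each query returns a :class:`QueryResult` — an ordered list of flat records
with a fixed column schema and documented sort keys, so a CSV export of the
same graph is byte-identical across runs.

The scientific intent, in brief: starting from a gene of interest, (1) find
its orthologs through the orthogroup bridge, (2) compare their protein
domain annotations, (3) mine QTL whose confidence intervals fall inside
syntenic blocks carrying the gene or its orthologs — which surfaces trait
loci in *other* species even when no ortholog lies inside the QTL interval
itself — and (4) compare expression across tissues using ontology
subsumption, so a query for "shoot system" also matches conditions
annotated with more specific descendant terms.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .graph_model import GraphError, PropertyGraph

__all__ = [
    "QueryResult",
    "find_orthologs",
    "get_protein_domains",
    "qtl_in_syntenic_blocks",
    "expression_in_tissue",
    "ontology_descendants",
]


@dataclass
class QueryResult:
    """Tabular query output: shared column schema, deterministic order."""

    query: str
    parameters: dict
    columns: list[str]
    records: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def column(self, name: str) -> list:
        return [r[name] for r in self.records]

    def to_csv(self, path: str | Path) -> None:
        """RFC 4180 CSV with a header row."""
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=self.columns)
            writer.writeheader()
            writer.writerows(self.records)


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------


def _require_gene(graph: PropertyGraph, gene_id: str) -> None:
    node = graph.node(gene_id)  # raises on unknown node
    if "Gene" not in node.labels:
        raise GraphError(f"node {gene_id} is not a Gene")


def _orthogroup_of(graph: PropertyGraph, gene_id: str) -> str | None:
    for _, node in graph.neighbors(gene_id, edge_type="MEMBER_OF", direction="out"):
        return node.node_id
    return None


def _orthogroup_members(graph: PropertyGraph, orthogroup: str) -> list[str]:
    return [
        n.node_id
        for _, n in graph.neighbors(orthogroup, edge_type="MEMBER_OF", direction="in")
    ]


# ---------------------------------------------------------------------------
# Query 1: orthologs through the orthogroup bridge
# ---------------------------------------------------------------------------


def find_orthologs(
    graph: PropertyGraph,
    gene_id: str,
    species_filter: Iterable[str] | None = None,
) -> QueryResult:
    """All other members of the gene's orthogroup, with their positions.

    Sorted by species then gene ID.  A gene outside any orthogroup yields
    an empty result.
    """
    _require_gene(graph, gene_id)
    columns = ["gene_id", "species", "chromosome", "start", "end"]
    result = QueryResult(
        "find_orthologs",
        {"gene_id": gene_id, "species_filter": sorted(species_filter) if species_filter else None},
        columns,
    )
    og = _orthogroup_of(graph, gene_id)
    if og is None:
        return result
    wanted = set(species_filter) if species_filter is not None else None
    rows = []
    for member in _orthogroup_members(graph, og):
        if member == gene_id:
            continue
        props = graph.node(member).properties
        species = props.get("species", "")
        if wanted is not None and species not in wanted:
            continue
        rows.append(
            {
                "gene_id": member,
                "species": species,
                "chromosome": props.get("chromosome", ""),
                "start": props.get("start", ""),
                "end": props.get("end", ""),
            }
        )
    rows.sort(key=lambda r: (r["species"], r["gene_id"]))
    result.records = rows
    return result


# ---------------------------------------------------------------------------
# Query 2: protein domain annotations
# ---------------------------------------------------------------------------


def get_protein_domains(
    graph: PropertyGraph,
    gene_ids: Sequence[str],
    source_db: str = "PANTHER",
) -> QueryResult:
    """Domain annotations from one source DB for the proteins of the given
    genes.  Sorted by gene, protein, accession, domain start."""
    for g in gene_ids:
        _require_gene(graph, g)
    columns = [
        "gene_id",
        "protein_id",
        "protein_length",
        "accession",
        "description",
        "domain_start",
        "domain_end",
    ]
    result = QueryResult(
        "get_protein_domains",
        {"gene_ids": list(gene_ids), "source_db": source_db},
        columns,
    )
    rows = []
    for gene_id in gene_ids:
        for _, rna in graph.neighbors(gene_id, edge_type="HAS_TRANSCRIPT", direction="out"):
            for _, protein in graph.neighbors(
                rna.node_id, edge_type="TRANSLATES_TO", direction="out"
            ):
                for edge, ann in graph.neighbors(
                    protein.node_id, edge_type="HAS_DOMAIN", direction="out"
                ):
                    if ann.properties.get("source") != source_db:
                        continue
                    rows.append(
                        {
                            "gene_id": gene_id,
                            "protein_id": protein.node_id,
                            "protein_length": protein.properties.get("length", ""),
                            "accession": ann.properties.get("accession", ""),
                            "description": ann.properties.get("description", ""),
                            "domain_start": edge.properties.get("domain_start", ""),
                            "domain_end": edge.properties.get("domain_end", ""),
                        }
                    )
    rows.sort(
        key=lambda r: (r["gene_id"], r["protein_id"], r["accession"], str(r["domain_start"]))
    )
    result.records = rows
    return result


# ---------------------------------------------------------------------------
# Query 3: QTL inside syntenic blocks carrying the gene or its orthologs
# ---------------------------------------------------------------------------


def _spans_of_block(node) -> list[tuple[str, int, int]]:
    spans = []
    p = node.properties
    if "span_a_start" in p:
        spans.append((p["chromosome_a"], p["span_a_start"], p["span_a_end"]))
    if "span_b_start" in p:
        spans.append((p["chromosome_b"], p["span_b_start"], p["span_b_end"]))
    return spans


def qtl_in_syntenic_blocks(
    graph: PropertyGraph,
    gene_id: str,
    trait_keyword: str | None = None,
) -> QueryResult:
    """QTL whose interval overlaps a syntenic block containing the gene or
    any of its orthogroup co-members.

    Overlap is measured between the QTL confidence interval (or point) and
    the block's bp span on the matching chromosome, so QTL that do not
    contain any ortholog in their interval are still returned.  An optional
    case-insensitive substring filter on the trait name keeps e.g. only
    flowering-related loci.  Sorted by chromosome, QTL ID, block ID.
    """
    _require_gene(graph, gene_id)
    columns = [
        "qtl_id",
        "trait",
        "chromosome",
        "interval_start",
        "interval_end",
        "block_id",
        "species",
    ]
    result = QueryResult(
        "qtl_in_syntenic_blocks",
        {"gene_id": gene_id, "trait_keyword": trait_keyword},
        columns,
    )
    og = _orthogroup_of(graph, gene_id)
    seeds = [gene_id] if og is None else sorted(set(_orthogroup_members(graph, og)) | {gene_id})
    block_ids: set[str] = set()
    for seed in seeds:
        for _, block in graph.neighbors(seed, edge_type="IN_SYNTENY_BLOCK", direction="out"):
            block_ids.add(block.node_id)
    rows = []
    seen: set[tuple[str, str]] = set()
    for block_id in sorted(block_ids):
        block = graph.node(block_id)
        for chrom, span_lo, span_hi in _spans_of_block(block):
            chrom_node = graph.node(chrom) if graph.has_node(chrom) else None
            species = chrom_node.properties.get("species", "") if chrom_node else ""
            for qtl in graph.nodes("QTL"):
                if qtl.properties.get("chromosome") != chrom:
                    continue
                lo = qtl.properties.get("interval_start", qtl.properties.get("peak"))
                hi = qtl.properties.get("interval_end", qtl.properties.get("peak"))
                if lo is None or hi is None:
                    continue
                if hi < span_lo or lo > span_hi:
                    continue
                trait = qtl.properties.get("trait", "")
                if trait_keyword is not None and trait_keyword.lower() not in trait.lower():
                    continue
                if (qtl.node_id, block_id) in seen:
                    continue
                seen.add((qtl.node_id, block_id))
                rows.append(
                    {
                        "qtl_id": qtl.node_id,
                        "trait": trait,
                        "chromosome": chrom,
                        "interval_start": lo,
                        "interval_end": hi,
                        "block_id": block_id,
                        "species": species,
                    }
                )
    rows.sort(key=lambda r: (r["chromosome"], r["qtl_id"], r["block_id"]))
    result.records = rows
    return result


# ---------------------------------------------------------------------------
# Query 4: expression in a tissue, with ontology subsumption
# ---------------------------------------------------------------------------


def ontology_descendants(
    graph: PropertyGraph,
    term_id: str,
    predicates: Iterable[str] = ("SCO", "PART_OF"),
) -> set[str]:
    """Reflexive-transitive closure of "narrower-than" over the chosen edge
    types (edges point child -> parent, so descendants come in via in-edges)."""
    graph.node(term_id)  # raises on unknown term
    preds = set(predicates)
    if not preds <= {"SCO", "PART_OF"}:
        raise ValueError(f"unsupported predicates: {preds - {'SCO', 'PART_OF'}}")
    closure = {term_id}
    frontier = [term_id]
    while frontier:
        term = frontier.pop()
        for edge, child in graph.neighbors(term, direction="in"):
            if edge.edge_type in preds and child.node_id not in closure:
                closure.add(child.node_id)
                frontier.append(child.node_id)
    return closure


def expression_in_tissue(
    graph: PropertyGraph,
    gene_ids: Sequence[str],
    tissue_term: str,
    top_k: int | None = None,
    predicates: Iterable[str] = ("SCO", "PART_OF"),
) -> QueryResult:
    """Per-sample TPM of the genes in conditions annotated with the tissue
    term or any of its more specific descendant terms.

    ``top_k`` keeps, per gene, only the k conditions with the highest
    condition-level arithmetic-mean TPM ("top tissues by expression").
    Sorted by gene, then condition mean TPM (descending), then condition and
    sample ID.
    """
    for g in gene_ids:
        _require_gene(graph, g)
    terms = ontology_descendants(graph, tissue_term, predicates)
    columns = [
        "gene_id",
        "sample_id",
        "tpm",
        "condition_id",
        "condition_mean_tpm",
        "tissue_terms",
    ]
    result = QueryResult(
        "expression_in_tissue",
        {"gene_ids": list(gene_ids), "tissue_term": tissue_term, "top_k": top_k},
        columns,
    )
    # conditions annotated with a term of the closure
    cond_tissues: dict[str, list[str]] = {}
    for cond in graph.nodes("Condition"):
        annotated = [
            n.node_id
            for _, n in graph.neighbors(cond.node_id, edge_type="ANNOTATED_WITH", direction="out")
            if "PO" in n.labels
        ]
        if any(t in terms for t in annotated):
            cond_tissues[cond.node_id] = sorted(annotated)
    rows = []
    for gene_id in gene_ids:
        cond_mean: dict[str, float] = {}
        for edge, cond in graph.neighbors(gene_id, edge_type="EXPRESSED_IN", direction="out"):
            if cond.node_id in cond_tissues:
                cond_mean[cond.node_id] = edge.properties.get("arithmetic_mean_tpm", 0.0)
        kept = sorted(cond_mean, key=lambda c: (-cond_mean[c], c))
        if top_k is not None:
            kept = kept[:top_k]
        kept_set = set(kept)
        for edge, sample in graph.neighbors(gene_id, edge_type="MEASURED_IN", direction="out"):
            for _, cond in graph.neighbors(sample.node_id, edge_type="BELONGS_TO", direction="out"):
                if cond.node_id not in kept_set:
                    continue
                rows.append(
                    {
                        "gene_id": gene_id,
                        "sample_id": sample.node_id,
                        "tpm": edge.properties.get("tpm", 0.0),
                        "condition_id": cond.node_id,
                        "condition_mean_tpm": cond_mean[cond.node_id],
                        "tissue_terms": ";".join(cond_tissues[cond.node_id]),
                    }
                )
    rows.sort(
        key=lambda r: (
            r["gene_id"],
            -r["condition_mean_tpm"],
            r["condition_id"],
            r["sample_id"],
        )
    )
    result.records = rows
    return result
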