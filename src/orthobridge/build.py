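"""End-to-end graph assembly from a dataset directory.

A dataset directory is described by a ``dataset.json`` file (written by the
fixture generators, or by hand for real data) mapping logical roles to file
paths: per-species GFF3 + chromosome-conversion tables, the orthogroup
table, optional collinearity file, QTL CSV, TPM/count matrices, condition
metadata, OBO ontologies and a functional-annotation table.

The assembly order mirrors the two-pipeline design: structural backbone
first (species, chromosomes, genes, transcripts, proteins, orthogroups,
synteny), then the functional layers (ontologies, expression, QTL,
annotations).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from . import io_formats as iof
from .functional_etl import (
    aggregate_condition_expression,
    attach_expression,
    attach_functional_annotations,
    attach_qtl,
    build_ontology_subgraph,
    colocalize_qtl,
    filter_expression,
    filter_go_most_specific,
)
from .graph_model import PropertyGraph
from .structural import (
    build_homology_subgraph,
    build_synteny_subgraph,
    chromosome_gene_orders,
    detect_collinear_blocks,
)

logger = logging.getLogger(__name__)

__all__ = ["BuildConfig", "build_graph", "load_annotations"]


@dataclass
class BuildConfig:
    min_block_genes: int = 10
    max_rank_gap: int = 25
    tpm_sum_threshold: float = 5.0
    gwas_window: int = 0
    use_collinearity_file: bool = False
    pairwise_orthology: bool = False
    strict: bool = True


def _protein_id(transcript_id: str) -> str:
    return f"{transcript_id}.p"


def load_annotations(directory: Path, files: dict) -> dict[str, iof.GenomeAnnotation]:
    """Read per-species GFF3 (with chromosome conversion) and keep the
    longest isoform of every gene."""
    annotations: dict[str, iof.GenomeAnnotation] = {}
    for sp, gff in files["gff3"].items():
        conv_path = files.get("chromosome_conversion", {}).get(sp)
        conversion = (
            iof.read_chromosome_conversion(directory / conv_path) if conv_path else None
        )
        ann = iof.read_gff3(directory / gff, id_conversion=conversion, species=sp)
        annotations[sp] = iof.select_longest_isoform(ann)
    return annotations


def build_graph(
    dataset_dir: str | Path, config: BuildConfig | None = None
) -> PropertyGraph:
    """Assemble the full knowledge graph from a dataset directory."""
    config = config or BuildConfig()
    directory = Path(dataset_dir)
    files = json.loads((directory / "dataset.json").read_text())["files"]

    annotations = load_annotations(directory, files)
    graph = PropertyGraph(strict=config.strict)

    # structural backbone ---------------------------------------------------
    for sp, ann in sorted(annotations.items()):
        graph.add_node(sp, {"Species"}, {"tag": sp})
        for chrom, length in ann.chromosomes:
            graph.add_node(chrom, {"Chromosome"}, {"length": length, "species": sp})
            graph.add_edge("BELONGS_TO_SPECIES", chrom, sp)
        for g in ann.genes:
            props = {
                "species": sp,
                "chromosome": g.chromosome,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
            }
            if g.name:
                props["name"] = g.name
            graph.add_node(g.gene_id, {"Gene"}, props)
            graph.add_edge("LOCATED_ON", g.gene_id, g.chromosome)
        for t in ann.transcripts:
            graph.add_node(t.transcript_id, {"RNA"}, {"cds_length": t.cds_length})
            graph.add_edge("HAS_TRANSCRIPT", t.gene_id, t.transcript_id)
            pid = _protein_id(t.transcript_id)
            graph.add_node(pid, {"Protein"}, {"length": t.cds_length // 3})
            graph.add_edge("TRANSLATES_TO", t.transcript_id, pid)

    orthogroups = iof.read_orthogroups(directory / files["orthogroups"])
    build_homology_subgraph(orthogroups, graph, pairwise_orthology=config.pairwise_orthology)

    if config.use_collinearity_file and files.get("collinearity"):
        blocks = iof.read_collinearity(directory / files["collinearity"])
    else:
        orders = chromosome_gene_orders(annotations.values())
        blocks = detect_collinear_blocks(
            orders,
            orthogroups,
            min_genes=config.min_block_genes,
            max_gap=config.max_rank_gap,
        )
    build_synteny_subgraph(blocks, graph)

    # functional layers -----------------------------------------------------
    for source, fname in sorted(files.get("ontologies", {}).items()):
        ontology = iof.read_obo(directory / fname, source=source)
        build_ontology_subgraph(ontology, graph)

    if files.get("tpm"):
        matrix = iof.read_expression_matrix(
            directory / files["tpm"],
            directory / files["counts"] if files.get("counts") else None,
        )
        known = [g for g in matrix.genes if graph.has_node(g)]
        if len(known) < len(matrix.genes):
            logger.warning(
                "%d expression rows without a Gene node dropped",
                len(matrix.genes) - len(known),
            )
            matrix = iof.ExpressionMatrix(
                matrix.tpm.loc[known],
                matrix.counts.loc[known] if matrix.counts is not None else None,
            )
        matrix = filter_expression(matrix, threshold=config.tpm_sum_threshold)
        conditions = iof.read_condition_metadata(directory / files["conditions"], matrix)
        expr = aggregate_condition_expression(matrix, conditions)
        attach_expression(expr, conditions, matrix, graph)

    if files.get("qtl"):
        qtls = iof.read_qtl_table(directory / files["qtl"])
        colocs = colocalize_qtl(
            qtls, list(annotations.values()), gwas_window=config.gwas_window
        )
        attach_qtl(qtls, colocs, graph)

    if files.get("functional_annotations"):
        records = iof.read_functional_annotations(
            directory / files["functional_annotations"]
        )
        records = filter_go_most_specific(records)
        attach_functional_annotations(records, graph)

    return graph
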