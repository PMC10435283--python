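"""Filtering/aggregation rules of the functional pipeline, and the graph
wiring for QTL, expression, functional-annotation and ontology data.

The rules are deliberately simple and stated exactly:

* GO annotations: keep the most specific terms only (``is_hidden == 0``).
* Expression: keep genes whose TPM sum across samples is strictly > 5.
* Condition aggregation: arithmetic and geometric mean TPM per
  (gene, condition); the geometric mean is 0 whenever any replicate is 0.
* QTL colocalization: interval overlap between the gene body and the QTL
  confidence interval (closed intervals); the gene nearest the peak marker
  gets an extra closest-to-peak link carrying the bp distance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree

from .graph_model import GraphError, PropertyGraph
from .io_formats import (
    ConditionAnnotation,
    ExpressionMatrix,
    FunctionalAnnotationRecord,
    GenomeAnnotation,
    Ontology,
    QTLRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionExpression",
    "Colocalization",
    "filter_go_most_specific",
    "filter_expression",
    "aggregate_condition_expression",
    "colocalize_qtl",
    "build_ontology_subgraph",
    "attach_functional_annotations",
    "attach_expression",
    "attach_qtl",
]


@dataclass(frozen=True)
class ConditionExpression:
    """Mean expression of one gene in one condition (n replicate samples)."""

    gene_id: str
    condition_id: str
    arithmetic_mean: float
    geometric_mean: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.arithmetic_mean < 0 or self.geometric_mean < 0:
            raise ValueError("means must be non-negative")
        if self.geometric_mean > self.arithmetic_mean + 1e-9:
            raise ValueError("geometric mean exceeds arithmetic mean")


@dataclass(frozen=True)
class Colocalization:
    """A gene-QTL link: either interval membership or nearest-to-peak."""

    gene_id: str
    qtl_id: str
    relation: str  # "COLOCALIZES_WITH" | "IS_CLOSEST_TO_PEAK"
    distance: int | None = None

    def __post_init__(self) -> None:
        if self.relation == "IS_CLOSEST_TO_PEAK":
            if self.distance is None or self.distance < 0:
                raise ValueError("closest-to-peak link requires distance >= 0")
        elif self.relation == "COLOCALIZES_WITH":
            if self.distance is not None:
                raise ValueError("distance only valid on closest-to-peak links")
        else:
            raise ValueError(f"unknown relation {self.relation!r}")


# ---------------------------------------------------------------------------
# Filtering rules
# ---------------------------------------------------------------------------


def filter_go_most_specific(
    records: Sequence[FunctionalAnnotationRecord],
    missing_flag: str = "drop",
) -> list[FunctionalAnnotationRecord]:
    """Keep only the most specific GO terms: records with ``is_hidden == 0``.

    Non-GO records pass through untouched.  GO records lacking the flag are
    dropped by default (``missing_flag="keep"`` retains them instead).
    """
    if missing_flag not in ("drop", "keep"):
        raise ValueError("missing_flag must be 'drop' or 'keep'")
    out: list[FunctionalAnnotationRecord] = []
    for r in records:
        if r.source_db != "GO":
            out.append(r)
        elif r.is_hidden == 0:
            out.append(r)
        elif r.is_hidden is None and missing_flag == "keep":
            out.append(r)
    return out


def filter_expression(
    matrix: ExpressionMatrix, threshold: float = 5.0
) -> ExpressionMatrix:
    """Drop genes whose TPM sum across all samples is <= ``threshold``
    (strict > keeps), avoiding graph clutter from non-expressed genes."""
    keep = matrix.tpm.sum(axis=1) > threshold
    counts = matrix.counts.loc[keep] if matrix.counts is not None else None
    return ExpressionMatrix(matrix.tpm.loc[keep], counts)


def aggregate_condition_expression(
    matrix: ExpressionMatrix,
    conditions: Sequence[ConditionAnnotation],
    pseudocount: float = 0.0,
) -> list[ConditionExpression]:
    """Average each gene's TPM over the replicate samples of each condition.

    The geometric mean is ``exp(mean(ln(tpm + pseudocount))) - pseudocount``;
    with the default pseudocount of 0 it is defined as 0 whenever any
    replicate TPM is 0 (the continuous limit).
    """
    out: list[ConditionExpression] = []
    for cond in conditions:
        samples = [s for s in cond.samples if s in matrix.tpm.columns]
        if not samples:
            raise ValueError(
                f"condition {cond.condition_id}: no sample present in the matrix"
            )
        sub = matrix.tpm[samples]
        am = sub.mean(axis=1)
        vals = sub.to_numpy(dtype=float)
        if pseudocount > 0:
            gm = np.exp(np.log(vals + pseudocount).mean(axis=1)) - pseudocount
            gm = np.maximum(gm, 0.0)
        else:
            with np.errstate(divide="ignore"):
                gm = np.exp(
                    np.where(
                        (vals == 0).any(axis=1),
                        -np.inf,
                        np.log(np.where(vals > 0, vals, 1.0)).mean(axis=1),
                    )
                )
        # exp(mean(log .)) is exact only up to float rounding; when all
        # replicates agree the geometric mean is that value by definition
        all_equal = vals.max(axis=1) == vals.min(axis=1)
        gm = np.where(all_equal, am.to_numpy(), gm)
        for i, gene in enumerate(matrix.tpm.index):
            out.append(
                ConditionExpression(
                    gene_id=gene,
                    condition_id=cond.condition_id,
                    arithmetic_mean=float(am.iloc[i]),
                    geometric_mean=float(min(gm[i], am.iloc[i])),
                    n_samples=len(samples),
                )
            )
    return out


# ---------------------------------------------------------------------------
# QTL colocalization
# ---------------------------------------------------------------------------


def _gene_peak_distance(gene_start: int, gene_end: int, peak: int) -> int:
    if gene_start <= peak <= gene_end:
        return 0
    return min(abs(peak - gene_start), abs(peak - gene_end))


def colocalize_qtl(
    qtls: Sequence[QTLRecord],
    annotation: GenomeAnnotation | Sequence[GenomeAnnotation],
    gwas_window: int = 0,
) -> list[Colocalization]:
    """Link genes to QTL.

    Interval QTL: every gene whose body overlaps the closed confidence
    interval colocalizes.  Point (single-marker) QTL: genes overlapping
    ``[peak - gwas_window, peak + gwas_window]``.  When a peak marker is
    present, the gene nearest to it *on that chromosome* — searched
    genome-wide, even if the colocalizing set is empty — additionally gets a
    closest-to-peak link with its bp distance (0 when the peak falls inside
    the gene).  Distance ties go to the smallest gene start, then the
    lexicographically smallest ID.  QTL on chromosomes absent from the
    annotation are skipped with a log entry.
    """
    annotations = (
        [annotation] if isinstance(annotation, GenomeAnnotation) else list(annotation)
    )
    by_chrom: dict[str, list] = {}
    trees: dict[str, IntervalTree] = {}
    for ann in annotations:
        for chrom, genes in ann.genes_by_chromosome().items():
            by_chrom.setdefault(chrom, []).extend(genes)
    for chrom, genes in by_chrom.items():
        genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        # closed 1-based intervals -> half-open for the tree
        trees[chrom] = IntervalTree.from_tuples(
            (g.start, g.end + 1, g.gene_id) for g in genes
        )

    out: list[Colocalization] = []
    for qtl in qtls:
        genes = by_chrom.get(qtl.chromosome)
        if genes is None:
            logger.warning("QTL %s on unknown chromosome %s; skipped", qtl.qtl_id, qtl.chromosome)
            continue
        if qtl.interval is not None:
            lo, hi = qtl.interval
        else:
            lo, hi = qtl.peak - gwas_window, qtl.peak + gwas_window
        hit_ids = sorted(iv.data for iv in trees[qtl.chromosome].overlap(lo, hi + 1))
        for gene_id in hit_ids:
            out.append(Colocalization(gene_id, qtl.qtl_id, "COLOCALIZES_WITH"))
        if qtl.peak is not None and genes:
            best = min(
                genes,
                key=lambda g: (
                    _gene_peak_distance(g.start, g.end, qtl.peak),
                    g.start,
                    g.gene_id,
                ),
            )
            out.append(
                Colocalization(
                    best.gene_id,
                    qtl.qtl_id,
                    "IS_CLOSEST_TO_PEAK",
                    distance=_gene_peak_distance(best.start, best.end, qtl.peak),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Graph wiring
# ---------------------------------------------------------------------------


def build_ontology_subgraph(ontology: Ontology, graph: PropertyGraph) -> PropertyGraph:
    """One node per term labeled by source (GO/PO/PECO/MapMan); ``is_a``
    becomes a subclass-of (SCO) edge child->parent, ``part_of`` a PART_OF
    edge.  Re-loading the same ontology is an idempotent merge."""
    label = ontology.source
    if label not in graph.schema.labels:
        graph.schema.register_label(label)
        graph.schema.register_edge_type("SCO", label, label)
        graph.schema.register_edge_type("PART_OF", label, label)
    resource = f"resource:{label.lower()}"
    graph.merge_node(resource, {"Resource"}, {"name": label})
    for term in sorted(ontology.terms):
        graph.merge_node(term, {label}, {"name": ontology.terms[term]})
        graph.add_edge("FROM_RESOURCE", term, resource)
    for child, parent, pred in ontology.edges:
        graph.add_edge("SCO" if pred == "is_a" else "PART_OF", child, parent)
    return graph


def attach_functional_annotations(
    records: Sequence[FunctionalAnnotationRecord], graph: PropertyGraph
) -> PropertyGraph:
    """FunctionalAnnotation nodes deduplicated by (source, accession).

    Protein subjects get HAS_DOMAIN edges carrying the domain position;
    gene subjects get HAS_ANNOTATION edges.  GO term records whose term node
    exists link the subject straight to the ontology term instead.
    """
    for r in records:
        if not graph.has_node(r.subject_id):
            raise GraphError(f"annotation references absent subject {r.subject_id}")
        subject_labels = graph.node(r.subject_id).labels
        if r.source_db == "GO" and graph.has_node(r.accession):
            graph.add_edge("ANNOTATED_WITH", r.subject_id, r.accession)
            continue
        ann_id = f"{r.source_db}:{r.accession}"
        graph.merge_node(
            ann_id,
            {"FunctionalAnnotation"},
            {"source": r.source_db, "accession": r.accession, "description": r.description},
        )
        props: dict = {}
        if r.domain_start is not None:
            props["domain_start"] = r.domain_start
        if r.domain_end is not None:
            props["domain_end"] = r.domain_end
        edge_type = "HAS_DOMAIN" if "Protein" in subject_labels else "HAS_ANNOTATION"
        graph.add_edge(edge_type, r.subject_id, ann_id, props)
    return graph


def attach_expression(
    condition_expression: Sequence[ConditionExpression],
    conditions: Sequence[ConditionAnnotation],
    matrix: ExpressionMatrix,
    graph: PropertyGraph,
) -> PropertyGraph:
    """Sample and Condition nodes plus expression edges.

    Condition nodes carry the double label Condition+RNASeq.  Per-sample TPM
    goes on Gene->Sample MEASURED_IN edges; condition-level arithmetic and
    geometric means go on Gene->Condition EXPRESSED_IN edges.  Conditions
    link to their PO/PECO term nodes with ANNOTATED_WITH.
    """
    for cond in conditions:
        graph.merge_node(
            cond.condition_id,
            {"Condition", "RNASeq"},
            {"area": cond.area or ""},
        )
        for term in (*cond.po_terms, *cond.peco_terms):
            if not graph.has_node(term):
                raise GraphError(
                    f"condition {cond.condition_id} annotated with absent term {term}"
                )
            graph.add_edge("ANNOTATED_WITH", cond.condition_id, term)
        for sample in cond.samples:
            if sample not in matrix.tpm.columns:
                continue
            graph.merge_node(sample, {"Sample"})
            graph.add_edge("BELONGS_TO", sample, cond.condition_id)
            col = matrix.tpm[sample]
            for gene_id, tpm in col.items():
                if not graph.has_node(gene_id):
                    raise GraphError(f"expression references absent gene {gene_id}")
                graph.add_edge("MEASURED_IN", gene_id, sample, {"tpm": float(tpm)})
    for ce in condition_expression:
        if not graph.has_node(ce.gene_id):
            raise GraphError(f"expression references absent gene {ce.gene_id}")
        graph.add_edge(
            "EXPRESSED_IN",
            ce.gene_id,
            ce.condition_id,
            {
                "arithmetic_mean_tpm": ce.arithmetic_mean,
                "geometric_mean_tpm": ce.geometric_mean,
                "n_samples": ce.n_samples,
            },
        )
    return graph


def attach_qtl(
    qtls: Sequence[QTLRecord],
    colocalizations: Sequence[Colocalization],
    graph: PropertyGraph,
) -> PropertyGraph:
    """QTL nodes (double-labeled by study type) with Trait/Population/Site/
    Marker satellites, plus the colocalization edges."""
    study_label = {"biparental": "BiparentalPopulation", "diversity panel": "DiversityPanel"}
    for qtl in qtls:
        props: dict = {"trait": qtl.trait, "chromosome": qtl.chromosome}
        if qtl.interval is not None:
            props["interval_start"], props["interval_end"] = qtl.interval
        if qtl.peak is not None:
            props["peak"] = qtl.peak
        graph.merge_node(qtl.qtl_id, {"QTL", study_label[qtl.study_type]}, props)
        if graph.has_node(qtl.chromosome):
            graph.add_edge("LOCATED_ON", qtl.qtl_id, qtl.chromosome)
        trait_id = f"trait:{qtl.trait.lower()}"
        graph.merge_node(trait_id, {"Trait"}, {"name": qtl.trait})
        graph.add_edge("HAS_TRAIT", qtl.qtl_id, trait_id)
        if qtl.population:
            pop_id = f"population:{qtl.population}"
            graph.merge_node(pop_id, {"Population"}, {"name": qtl.population})
            graph.add_edge("STUDIED_IN", qtl.qtl_id, pop_id)
        if qtl.site:
            site_id = f"site:{qtl.site}"
            graph.merge_node(site_id, {"Site"}, {"name": qtl.site})
            graph.add_edge("OBSERVED_AT", qtl.qtl_id, site_id)
        for role, pos in (
            ("flank_left", qtl.flank_left),
            ("flank_right", qtl.flank_right),
            ("peak", qtl.peak),
        ):
            if pos is None:
                continue
            marker_id = f"marker:{qtl.chromosome}:{pos}"
            graph.merge_node(
                marker_id, {"Marker"}, {"chromosome": qtl.chromosome, "position": pos}
            )
            graph.add_edge("HAS_MARKER", qtl.qtl_id, marker_id, {"role": role})
    for c in colocalizations:
        if not graph.has_node(c.gene_id):
            raise GraphError(f"colocalization references absent gene {c.gene_id}")
        if not graph.has_node(c.qtl_id):
            raise GraphError(f"colocalization references absent QTL {c.qtl_id}")
        props = {} if c.distance is None else {"distance": c.distance}
        graph.add_edge(c.relation, c.gene_id, c.qtl_id, props)
    return graph
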