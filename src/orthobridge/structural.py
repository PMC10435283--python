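"""Cross-species backbone: orthology filtering and collinear-block detection.

Collinearity is detected on gene *ranks* (ordinal position along the
chromosome after longest-isoform selection), mirroring the gene-rank model
of standard collinearity tools; base-pair spans are derived afterwards from
the member genes.  A block is a maximal chain of gene pairs from the same
orthogroup, strictly monotone in both rank sequences — increasing/increasing
for a ``plus`` block, increasing/decreasing for ``minus`` — with consecutive
rank gaps bounded by ``max_gap`` on both chromosomes, and at least
``min_genes`` pairs long (default 10).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import cached_property
from typing import Callable, Iterable, Mapping, Sequence

from .graph_model import GraphError, PropertyGraph
from .io_formats import FormatError, GeneFeature, GenomeAnnotation, OrthogroupSet

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentHit",
    "SyntenyBlock",
    "filter_alignments_by_orthogroup",
    "chromosome_gene_orders",
    "detect_collinear_blocks",
    "build_homology_subgraph",
    "build_synteny_subgraph",
]


@dataclass(frozen=True)
class AlignmentHit:
    """A pairwise protein alignment hit (query, subject, score)."""

    query: str
    subject: str
    score: float = 0.0

    @property
    def is_self(self) -> bool:
        return self.query == self.subject


@dataclass(frozen=True)
class SyntenyBlock:
    """An ordered run of orthologous gene pairs on a chromosome pair."""

    block_id: str
    chromosome_a: str
    chromosome_b: str
    orientation: str  # "plus" | "minus"
    pairs: tuple[tuple[str, str], ...]
    span_a: tuple[int, int] | None = None
    span_b: tuple[int, int] | None = None
    score: float | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ("plus", "minus"):
            raise FormatError(f"unknown orientation token {self.orientation!r}")

    @cached_property
    def genes_a(self) -> tuple[str, ...]:
        return tuple(a for a, _ in self.pairs)

    @cached_property
    def genes_b(self) -> tuple[str, ...]:
        return tuple(b for _, b in self.pairs)

    @property
    def size(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# Alignment filtering
# ---------------------------------------------------------------------------


def filter_alignments_by_orthogroup(
    hits: Sequence[AlignmentHit],
    orthogroups: OrthogroupSet,
    protein_to_gene: Mapping[str, str] | Callable[[str], str] | None = None,
) -> list[AlignmentHit]:
    """Keep only hits whose two proteins map to genes of one orthogroup.

    ``protein_to_gene`` resolves protein IDs to gene IDs (identity when
    omitted).  Unmappable proteins are dropped, with a logged count, rather
    than raising: alignment files routinely contain entries filtered out
    upstream of orthology inference.
    """
    if protein_to_gene is None:
        resolve: Callable[[str], str | None] = lambda p: p
    elif callable(protein_to_gene):
        resolve = protein_to_gene
    else:
        mapping = protein_to_gene
        resolve = lambda p: mapping.get(p)

    kept: list[AlignmentHit] = []
    unmapped = 0
    for hit in hits:
        gq, gs = resolve(hit.query), resolve(hit.subject)
        if gq is None or gs is None or orthogroups.group_of(gq) is None or orthogroups.group_of(gs) is None:
            unmapped += 1
            continue
        if orthogroups.same_group(gq, gs):
            kept.append(hit)
    if unmapped:
        logger.info("dropped %d hits with unmappable/ungrouped proteins", unmapped)
    return kept


# ---------------------------------------------------------------------------
# Collinear-block detection
# ---------------------------------------------------------------------------


def chromosome_gene_orders(
    annotations: Iterable[GenomeAnnotation],
) -> dict[str, list[GeneFeature]]:
    """Per-chromosome gene orders (sorted by start) for the whole collection.

    Chromosome IDs must already be unique across species (enforced via the
    conversion tables at load time)."""
    orders: dict[str, list[GeneFeature]] = {}
    for ann in annotations:
        for chrom, genes in ann.genes_by_chromosome().items():
            if chrom in orders:
                raise FormatError(f"chromosome ID {chrom} occurs in two annotations")
            orders[chrom] = genes
    return orders


@dataclass(frozen=True)
class _Match:
    """A candidate gene pair expressed in rank space."""

    ra: int
    rb: int
    gene_a: str
    gene_b: str


def _chainable_ranks(
    genes: Sequence[GeneFeature], orthogroups: OrthogroupSet
) -> list[tuple[int, GeneFeature]]:
    """(rank, gene) for genes participating in chaining.

    Tandem duplicates — consecutive genes of one orthogroup on the same
    chromosome — contribute only their first-ranked member, which prevents
    degenerate vertical chains."""
    out: list[tuple[int, GeneFeature]] = []
    prev_group: str | None = None
    for rank, gene in enumerate(genes):
        group = orthogroups.group_of(gene.gene_id)
        if group is not None and group == prev_group:
            prev_group = group
            continue
        prev_group = group
        if group is not None:
            out.append((rank, gene))
    return out


def _best_chain(
    matches: list[_Match], orientation: str, max_gap: int
) -> list[_Match]:
    """Longest admissible chain; ties resolved by the lexicographically
    smallest (ra, rb) pair sequence.  Returns [] when no match remains."""
    if not matches:
        return []
    order = sorted(range(len(matches)), key=lambda i: (matches[i].ra, matches[i].rb))

    def can_follow(m1: _Match, m2: _Match) -> bool:
        if not (0 < m2.ra - m1.ra <= max_gap):
            return False
        if orientation == "plus":
            return 0 < m2.rb - m1.rb <= max_gap
        return 0 < m1.rb - m2.rb <= max_gap

    # best chain *starting* at index i, as a tuple of match indices
    best_from: dict[int, tuple[int, ...]] = {}
    for pos in range(len(order) - 1, -1, -1):
        i = order[pos]
        mi = matches[i]
        best_tail: tuple[int, ...] = ()
        best_key: tuple | None = None
        for succ_pos in range(pos + 1, len(order)):
            j = order[succ_pos]
            mj = matches[j]
            if mj.ra - mi.ra > max_gap:
                break  # sorted by ra: no later match can follow either
            if not can_follow(mi, mj):
                continue
            tail = best_from[j]
            key = (-len(tail), tuple((matches[k].ra, matches[k].rb) for k in tail))
            if best_key is None or key < best_key:
                best_key = key
                best_tail = tail
        best_from[i] = (i,) + best_tail

    def chain_key(idx: int) -> tuple:
        chain = best_from[idx]
        seq = tuple((matches[k].ra, matches[k].rb) for k in chain)
        return (-len(chain), seq)

    winner = min(best_from, key=chain_key)
    return [matches[k] for k in best_from[winner]]


def _pair_matches(
    chrom_a: str,
    genes_a: Sequence[GeneFeature],
    chrom_b: str,
    genes_b: Sequence[GeneFeature],
    orthogroups: OrthogroupSet,
) -> list[_Match]:
    ranked_a = _chainable_ranks(genes_a, orthogroups)
    by_group_b: dict[str, list[tuple[int, GeneFeature]]] = {}
    for rank, gene in _chainable_ranks(genes_b, orthogroups):
        by_group_b.setdefault(orthogroups.group_of(gene.gene_id), []).append(
            (rank, gene)
        )
    matches: list[_Match] = []
    self_pair = chrom_a == chrom_b
    for ra, ga in ranked_a:
        group = orthogroups.group_of(ga.gene_id)
        for rb, gb in by_group_b.get(group, ()):
            if self_pair and rb <= ra:
                continue  # skip the trivial diagonal and mirrored duplicates
            if ga.gene_id == gb.gene_id:
                continue
            matches.append(_Match(ra, rb, ga.gene_id, gb.gene_id))
    return matches


def detect_collinear_blocks(
    gene_orders: Mapping[str, Sequence[GeneFeature]],
    orthogroups: OrthogroupSet,
    min_genes: int = 10,
    max_gap: int = 25,
) -> list[SyntenyBlock]:
    """Detect collinear blocks over every chromosome pair.

    For each pair of chromosomes (including intra-species pairs; a
    chromosome against itself excludes the trivial diagonal), gene pairs
    sharing an orthogroup are chained under the monotonicity and gap
    constraints.  Chains are extracted greedily, longest first — ties by
    leftmost start rank, then ``plus`` before ``minus``, then smallest
    (ra, rb) sequence — consuming their gene pairs, until no chain of at
    least ``min_genes`` pairs remains.  Fully deterministic.
    """
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2")
    coords: dict[str, GeneFeature] = {}
    for chrom, genes in gene_orders.items():
        starts = [g.start for g in genes]
        if starts != sorted(starts):
            raise FormatError(f"gene order on {chrom} is not sorted by start")
        for g in genes:
            coords[g.gene_id] = g

    blocks: list[SyntenyBlock] = []
    counter = 0
    chroms = sorted(gene_orders)
    for ia, chrom_a in enumerate(chroms):
        for chrom_b in chroms[ia:]:
            pool = _pair_matches(
                chrom_a, gene_orders[chrom_a], chrom_b, gene_orders[chrom_b], orthogroups
            )
            while pool:
                candidates = []
                for orientation in ("plus", "minus"):
                    chain = _best_chain(pool, orientation, max_gap)
                    if len(chain) >= min_genes:
                        seq = tuple((m.ra, m.rb) for m in chain)
                        orient_rank = 0 if orientation == "plus" else 1
                        candidates.append(
                            ((-len(chain), chain[0].ra, orient_rank, seq), orientation, chain)
                        )
                if not candidates:
                    break
                _, orientation, chain = min(candidates)
                counter += 1
                ga = [coords[m.gene_a] for m in chain]
                gb = [coords[m.gene_b] for m in chain]
                blocks.append(
                    SyntenyBlock(
                        block_id=f"SB{counter:04d}",
                        chromosome_a=chrom_a,
                        chromosome_b=chrom_b,
                        orientation=orientation,
                        pairs=tuple((m.gene_a, m.gene_b) for m in chain),
                        span_a=(min(g.start for g in ga), max(g.end for g in ga)),
                        span_b=(min(g.start for g in gb), max(g.end for g in gb)),
                    )
                )
                consumed = {(m.gene_a, m.gene_b) for m in chain}
                pool = [m for m in pool if (m.gene_a, m.gene_b) not in consumed]
    return blocks


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


def build_homology_subgraph(
    orthogroups: OrthogroupSet,
    graph: PropertyGraph,
    pairwise_orthology: bool = False,
) -> PropertyGraph:
    """One Orthogroup node per group, MEMBER_OF edges from each member gene.

    ``pairwise_orthology`` additionally adds IS_ORTHOLOGOUS_TO edges between
    all cross-species member pairs (off by default — quadratic in group
    size)."""
    for og in sorted(orthogroups.groups):
        members = orthogroups.members(og)
        for gene in members:
            if not graph.has_node(gene):
                raise GraphError(f"orthogroup {og} references absent gene {gene}")
        graph.merge_node(og, {"Orthogroup"}, {"n_genes": len(members)})
        for gene in members:
            graph.add_edge("MEMBER_OF", gene, og)
        if pairwise_orthology:
            for i, g1 in enumerate(members):
                for g2 in members[i + 1 :]:
                    if orthogroups.gene_to_species[g1] != orthogroups.gene_to_species[g2]:
                        graph.add_edge("IS_ORTHOLOGOUS_TO", g1, g2)
    return graph


def build_synteny_subgraph(
    blocks: Sequence[SyntenyBlock], graph: PropertyGraph
) -> PropertyGraph:
    """One Synteny node per block (chromosome pair, orientation, bp spans),
    IN_SYNTENY_BLOCK edges from member genes, SPANS edges to chromosomes."""
    for b in blocks:
        props: dict = {
            "chromosome_a": b.chromosome_a,
            "chromosome_b": b.chromosome_b,
            "orientation": b.orientation,
            "n_pairs": b.size,
        }
        if b.span_a:
            props["span_a_start"], props["span_a_end"] = b.span_a
        if b.span_b:
            props["span_b_start"], props["span_b_end"] = b.span_b
        graph.add_node(b.block_id, {"Synteny"}, props)
        for gene in sorted(set(b.genes_a) | set(b.genes_b)):
            if not graph.has_node(gene):
                raise GraphError(f"block {b.block_id} references absent gene {gene}")
            graph.add_edge("IN_SYNTENY_BLOCK", gene, b.block_id)
        for chrom in {b.chromosome_a, b.chromosome_b}:
            if graph.has_node(chrom):
                graph.add_edge("SPANS", b.block_id, chrom)
    return graph
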