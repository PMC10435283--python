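"""Orthology filtering and collinear-block detection, validated against
exhaustive brute-force oracles and planted ground truth."""

import json

import numpy as np
import pytest

from orthobridge import generate_toy_dataset
from orthobridge.build import load_annotations
from orthobridge.graph_model import GraphError, PropertyGraph
from orthobridge.io_formats import (
    FormatError,
    GeneFeature,
    OrthogroupSet,
    read_orthogroups,
)
from orthobridge.structural import (
    AlignmentHit,
    build_homology_subgraph,
    build_synteny_subgraph,
    chromosome_gene_orders,
    detect_collinear_blocks,
    filter_alignments_by_orthogroup,
)

from oracles import exhaustive_blocks


def make_genes(chrom, gene_ids, spacing=1000, length=500):
    return [
        GeneFeature(g, chrom, (i + 1) * spacing, (i + 1) * spacing + length, "+")
        for i, g in enumerate(gene_ids)
    ]


def one_to_one_orthogroups(ids_a, ids_b, prefix="OG"):
    """Pair ids_a[i] with ids_b[i] in orthogroup i (spA/spB)."""
    return OrthogroupSet(
        {
            f"{prefix}{i:04d}": {"spA": [a], "spB": [b]}
            for i, (a, b) in enumerate(zip(ids_a, ids_b))
        }
    )


class TestAlignmentFilter:
    def test_same_orthogroup_rule(self):
        ogs = OrthogroupSet({"OG1": {"sp": ["p1", "p2"]}, "OG2": {"sp": ["p3"]}})
        hits = [AlignmentHit("p1", "p2"), AlignmentHit("p1", "p3")]
        assert filter_alignments_by_orthogroup(hits, ogs) == [AlignmentHit("p1", "p2")]

    def test_empty_input(self):
        ogs = OrthogroupSet({"OG1": {"sp": ["p1"]}})
        assert filter_alignments_by_orthogroup([], ogs) == []

    def test_random_hits_match_brute_force_count(self):
        rng = np.random.default_rng(11)
        proteins = [f"p{i}" for i in range(30)]
        group_of = {p: f"OG{rng.integers(0, 6)}" for p in proteins}
        members: dict[str, list[str]] = {}
        for p, og in group_of.items():
            members.setdefault(og, []).append(p)
        ogs = OrthogroupSet({og: {"sp": ms} for og, ms in members.items()})
        hits = [
            AlignmentHit(*rng.choice(proteins, size=2, replace=False))
            for _ in range(100)
        ]
        expected = [h for h in hits if group_of[h.query] == group_of[h.subject]]
        assert filter_alignments_by_orthogroup(hits, ogs) == expected

    def test_unmappable_proteins_dropped(self):
        ogs = OrthogroupSet({"OG1": {"sp": ["g1", "g2"]}})
        hits = [AlignmentHit("p1", "p2"), AlignmentHit("p1", "px")]
        kept = filter_alignments_by_orthogroup(
            hits, ogs, protein_to_gene={"p1": "g1", "p2": "g2"}
        )
        assert kept == [AlignmentHit("p1", "p2")]


class TestDetectCollinearBlocks:
    def test_perfect_collinearity_gives_one_plus_block(self):
        a = [f"a{i}" for i in range(12)]
        b = [f"b{i}" for i in range(12)]
        orders = {"c1": make_genes("c1", a), "c2": make_genes("c2", b)}
        blocks = detect_collinear_blocks(orders, one_to_one_orthogroups(a, b))
        assert len(blocks) == 1
        assert blocks[0].orientation == "plus" and blocks[0].size == 12
        assert blocks[0].pairs == tuple(zip(a, b))
        assert blocks[0].span_a == (1000, 12500)

    def test_nine_shared_genes_is_below_minimum(self):
        a = [f"a{i}" for i in range(9)]
        b = [f"b{i}" for i in range(9)]
        orders = {"c1": make_genes("c1", a), "c2": make_genes("c2", b)}
        assert detect_collinear_blocks(orders, one_to_one_orthogroups(a, b)) == []

    def test_reversed_order_gives_minus_block(self):
        a = [f"a{i}" for i in range(15)]
        b = [f"b{i}" for i in range(15)]
        orders = {"c1": make_genes("c1", a), "c2": make_genes("c2", list(reversed(b)))}
        blocks = detect_collinear_blocks(orders, one_to_one_orthogroups(a, b))
        assert len(blocks) == 1
        assert blocks[0].orientation == "minus" and blocks[0].size == 15

    def test_unsorted_input_is_hard_error(self):
        genes = make_genes("c1", ["a0", "a1"])
        orders = {"c1": list(reversed(genes))}
        with pytest.raises(FormatError, match="not sorted"):
            detect_collinear_blocks(orders, OrthogroupSet({}))

    def test_tandem_duplicates_contribute_once(self):
        # c1 carries an adjacent duplicate pair in OG5; the chain must use
        # only the first-ranked copy, keeping the block size at 12
        a = [f"a{i}" for i in range(12)]
        b = [f"b{i}" for i in range(12)]
        a_with_dup = a[:6] + ["a5dup"] + a[6:]
        groups = {f"OG{i:04d}": {"spA": [a[i]], "spB": [b[i]]} for i in range(12)}
        groups["OG0005"]["spA"].append("a5dup")
        orders = {
            "c1": make_genes("c1", a_with_dup),
            "c2": make_genes("c2", b),
        }
        blocks = detect_collinear_blocks(orders, OrthogroupSet(groups))
        assert len(blocks) == 1
        assert blocks[0].size == 12
        assert "a5dup" not in blocks[0].genes_a

    @pytest.mark.parametrize("seed", range(20))
    def test_shuffled_orders_match_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        a = [f"a{i}" for i in range(n)]
        b = [f"b{i}" for i in range(n)]
        perm = rng.permutation(n)
        b_order = [b[i] for i in perm]
        orders = {"c1": make_genes("c1", a), "c2": make_genes("c2", b_order)}
        ogs = one_to_one_orthogroups(a, b)
        got = detect_collinear_blocks(orders, ogs, min_genes=5, max_gap=8)
        og_of = {g: og for g, og in ogs.gene_to_group.items()}
        expected = exhaustive_blocks(
            {"c1": a, "c2": b_order}, og_of, min_genes=5, max_gap=8
        )
        assert [
            (blk.chromosome_a, blk.chromosome_b, blk.orientation, blk.pairs)
            for blk in got
        ] == expected

    @pytest.mark.parametrize("seed", [100, 101, 102])
    def test_larger_shuffles_with_multi_member_groups_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        a = [f"a{i}" for i in range(n)]
        b = [f"b{i}" for i in range(n)]
        groups = {f"OG{i:04d}": {"spA": [a[i]], "spB": [b[i]]} for i in range(n)}
        # a few groups gain a second member on chromosome b
        for i in (3, 11, 19):
            extra = f"bx{i}"
            groups[f"OG{i:04d}"]["spB"].append(extra)
            b.append(extra)
        perm = rng.permutation(len(b))
        b_order = [b[i] for i in perm]
        ogs = OrthogroupSet(groups)
        orders = {"c1": make_genes("c1", a), "c2": make_genes("c2", b_order)}
        got = detect_collinear_blocks(orders, ogs, min_genes=5, max_gap=8)
        expected = exhaustive_blocks(
            {"c1": a, "c2": b_order},
            dict(ogs.gene_to_group),
            min_genes=5,
            max_gap=8,
        )
        assert [
            (blk.chromosome_a, blk.chromosome_b, blk.orientation, blk.pairs)
            for blk in got
        ] == expected

    def test_every_block_satisfies_its_invariants(self, toy_dataset, toy_graph):
        annotations = load_annotations(
            toy_dataset.directory,
            json.loads((toy_dataset.directory / "dataset.json").read_text())["files"],
        )
        orders = chromosome_gene_orders(annotations.values())
        ogs = read_orthogroups(toy_dataset.directory / "orthogroups.tsv")
        rank = {
            chrom: {g.gene_id: i for i, g in enumerate(genes)}
            for chrom, genes in orders.items()
        }
        blocks = detect_collinear_blocks(orders, ogs)
        assert blocks  # planted segments are present
        for blk in blocks:
            assert blk.size >= 10
            ra = [rank[blk.chromosome_a][g] for g in blk.genes_a]
            rb = [rank[blk.chromosome_b][g] for g in blk.genes_b]
            assert ra == sorted(ra) and len(set(ra)) == len(ra)
            if blk.orientation == "plus":
                assert rb == sorted(rb) and len(set(rb)) == len(rb)
            else:
                assert rb == sorted(rb, reverse=True) and len(set(rb)) == len(rb)
            for seq in (ra, rb):
                gaps = [abs(y - x) for x, y in zip(seq, seq[1:])]
                assert max(gaps) <= 25
            coords = {g.gene_id: g for genes in orders.values() for g in genes}
            assert blk.span_a == (
                min(coords[g].start for g in blk.genes_a),
                max(coords[g].end for g in blk.genes_a),
            )

    def test_detection_is_deterministic(self):
        rng = np.random.default_rng(5)
        a = [f"a{i}" for i in range(40)]
        b = [f"b{i}" for i in range(40)]
        b_order = [b[i] for i in rng.permutation(40)]
        orders = {"c1": make_genes("c1", a), "c2": make_genes("c2", b_order)}
        ogs = one_to_one_orthogroups(a, b)
        first = detect_collinear_blocks(orders, ogs, min_genes=4, max_gap=10)
        second = detect_collinear_blocks(orders, ogs, min_genes=4, max_gap=10)
        assert first == second


class TestPlantedRecovery:
    @pytest.mark.parametrize("noise_rate", [0.0, 0.1, 0.2])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_segments_recovered(self, tmp_path, noise_rate, seed):
        manifest = generate_toy_dataset(
            tmp_path / f"d{seed}",
            n_species=2,
            genes_per_chromosome=60,
            n_blocks=2,
            noise_rate=noise_rate,
            block_length=12,
            seed=seed,
        )
        files = json.loads((manifest.directory / "dataset.json").read_text())["files"]
        annotations = load_annotations(manifest.directory, files)
        orders = chromosome_gene_orders(annotations.values())
        ogs = read_orthogroups(manifest.directory / files["orthogroups"])
        blocks = detect_collinear_blocks(orders, ogs)
        for segment in manifest.planted["segments"]:
            expected_pairs = set(
                zip(segment["genes"]["sp1"], segment["genes"]["sp2"])
            )
            best = max(
                (len(expected_pairs & set(blk.pairs)) for blk in blocks), default=0
            )
            assert best >= 0.9 * len(expected_pairs)
            # no reported block bridges two planted segments
            for blk in blocks:
                touched = [
                    s
                    for s in manifest.planted["segments"]
                    if set(zip(s["genes"]["sp1"], s["genes"]["sp2"])) & set(blk.pairs)
                ]
                assert len(touched) <= 1


class TestSubgraphBuilders:
    def _gene_graph(self, gene_ids):
        g = PropertyGraph(strict=False)
        for gid in gene_ids:
            g.add_node(gid, {"Gene"})
        return g

    def test_orthogroup_node_and_member_edges(self):
        ogs = OrthogroupSet({"OG1": {"spA": ["g1", "g2"], "spB": ["g3", "g4", "g5"]}})
        g = self._gene_graph(["g1", "g2", "g3", "g4", "g5"])
        build_homology_subgraph(ogs, g)
        assert len(g.nodes("Orthogroup")) == 1
        assert len(g.edges("MEMBER_OF")) == 5

    def test_pairwise_orthology_is_cross_species_only(self):
        ogs = OrthogroupSet({"OG1": {"spA": ["g1", "g2"], "spB": ["g3"]}})
        g = self._gene_graph(["g1", "g2", "g3"])
        build_homology_subgraph(ogs, g, pairwise_orthology=True)
        pairs = {(e.source, e.target) for e in g.edges("IS_ORTHOLOGOUS_TO")}
        assert pairs == {("g1", "g3"), ("g2", "g3")}

    def test_missing_member_gene_is_named(self):
        ogs = OrthogroupSet({"OG1": {"spA": ["g1", "ghost"]}})
        g = self._gene_graph(["g1"])
        with pytest.raises(GraphError, match="ghost"):
            build_homology_subgraph(ogs, g)

    def test_block_node_edge_counts(self):
        a = [f"a{i}" for i in range(12)]
        b = [f"b{i}" for i in range(12)]
        orders = {"c1": make_genes("c1", a), "c2": make_genes("c2", b)}
        (block,) = detect_collinear_blocks(orders, one_to_one_orthogroups(a, b))
        g = self._gene_graph(a + b)
        build_synteny_subgraph([block], g)
        assert len(g.nodes("Synteny")) == 1
        assert len(g.edges("IN_SYNTENY_BLOCK")) == 24  # 12 genes per chromosome
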