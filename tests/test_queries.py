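"""Use-case queries on the knowledge graph, including the flowering-gene
worked example and brute-force cross-checks."""

import numpy as np
import pytest

from orthobridge.fixtures import FTA1_GENES, FLOWERING_QTL_IDS
from orthobridge.graph_model import GraphError, PropertyGraph
from orthobridge.queries import (
    expression_in_tissue,
    find_orthologs,
    get_protein_domains,
    ontology_descendants,
    qtl_in_syntenic_blocks,
)

from oracles import closure_descendants

MTFTA1 = FTA1_GENES["mtru"]


class TestFindOrthologs:
    def test_fta1_orthogroup_members(self, fta1_graph):
        result = find_orthologs(fta1_graph, MTFTA1)
        assert result.column("gene_id") == [
            "Lcu.2RBY.6g043850",
            "Psat3g090680",
            "Psat3g090720",
            "Vfaba.Hedin2.R1.5g087000",
        ]
        by_gene = {r["gene_id"]: r for r in result}
        assert by_gene["Lcu.2RBY.6g043850"]["chromosome"] == "Lc06"
        assert by_gene["Psat3g090720"]["species"] == "psat"

    def test_species_filter(self, fta1_graph):
        result = find_orthologs(fta1_graph, MTFTA1, species_filter={"psat"})
        assert result.column("gene_id") == ["Psat3g090680", "Psat3g090720"]

    def test_gene_without_orthogroup_is_empty(self, fta1_graph):
        # private flanking genes belong to no orthogroup
        lonely = "Psat3g090200"
        assert len(find_orthologs(fta1_graph, lonely)) == 0

    def test_unknown_gene_raises(self, fta1_graph):
        with pytest.raises(GraphError):
            find_orthologs(fta1_graph, "no_such_gene")

    def test_symmetry(self, fta1_graph):
        for other in find_orthologs(fta1_graph, MTFTA1).column("gene_id"):
            back = find_orthologs(fta1_graph, other).column("gene_id")
            assert MTFTA1 in back

    def test_output_is_deterministic(self, fta1_graph, tmp_path):
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        find_orthologs(fta1_graph, MTFTA1).to_csv(p1)
        find_orthologs(fta1_graph, MTFTA1).to_csv(p2)
        assert p1.read_bytes() == p2.read_bytes()


class TestProteinDomains:
    def test_panther_domains_of_fta1_family(self, fta1_graph):
        genes = [MTFTA1, *find_orthologs(fta1_graph, MTFTA1).column("gene_id")]
        result = get_protein_domains(fta1_graph, genes, source_db="PANTHER")
        assert len(result) == 5
        assert set(result.column("accession")) == {"PTHR12565"}
        assert all(r["domain_start"] == 5 and r["domain_end"] == 170 for r in result)
        assert all(r["protein_length"] for r in result)

    def test_gene_without_domain_annotation_yields_no_rows(self, fta1_graph):
        result = get_protein_domains(fta1_graph, ["Psat3g090200"], source_db="PANTHER")
        assert len(result) == 0

    def test_other_source_db_is_empty(self, fta1_graph):
        result = get_protein_domains(fta1_graph, [MTFTA1], source_db="Pfam")
        assert len(result) == 0


class TestQTLInSyntenicBlocks:
    def test_flowering_qtl_of_worked_example(self, fta1_graph):
        result = qtl_in_syntenic_blocks(fta1_graph, MTFTA1, trait_keyword="flower")
        assert sorted(set(result.column("qtl_id"))) == sorted(FLOWERING_QTL_IDS)

    def test_no_keyword_is_a_superset(self, fta1_graph):
        everything = set(qtl_in_syntenic_blocks(fta1_graph, MTFTA1).column("qtl_id"))
        flowering = set(
            qtl_in_syntenic_blocks(fta1_graph, MTFTA1, "flower").column("qtl_id")
        )
        assert flowering < everything
        assert "SPC_15_1" in everything - flowering  # non-flowering control

    def test_gene_in_no_block_is_empty(self, fta1_graph):
        assert len(qtl_in_syntenic_blocks(fta1_graph, "Psat3g090200")) == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_blocks_match_span_overlap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = PropertyGraph(strict=False)
        chroms = [f"c{i}" for i in range(3)]
        for c in chroms:
            g.add_node(c, {"Chromosome"}, {"species": "sp"})
        g.add_node("focal", {"Gene"}, {"species": "sp", "chromosome": "c0"})
        spans = {}
        for b in range(5):
            c = chroms[int(rng.integers(0, 3))]
            lo = int(rng.integers(1, 900_000))
            hi = lo + int(rng.integers(10_000, 100_000))
            bid = f"B{b}"
            spans[bid] = (c, lo, hi)
            g.add_node(
                bid,
                {"Synteny"},
                {
                    "chromosome_a": c,
                    "chromosome_b": "c0",
                    "orientation": "plus",
                    "n_pairs": 10,
                    "span_a_start": lo,
                    "span_a_end": hi,
                    "span_b_start": 1,
                    "span_b_end": 2,
                },
            )
            g.add_edge("IN_SYNTENY_BLOCK", "focal", bid)
        qtl_pos = {}
        for j in range(50):
            c = chroms[int(rng.integers(0, 3))]
            lo = int(rng.integers(1, 1_000_000))
            hi = lo + int(rng.integers(0, 50_000))
            qid = f"q{j:02d}"
            qtl_pos[qid] = (c, lo, hi)
            g.add_node(
                qid,
                {"QTL"},
                {"trait": "t", "chromosome": c, "interval_start": lo, "interval_end": hi},
            )
        got = {
            (r["qtl_id"], r["block_id"])
            for r in qtl_in_syntenic_blocks(g, "focal")
        }
        expected = set()
        for qid, (qc, qlo, qhi) in qtl_pos.items():
            for bid, (bc, blo, bhi) in spans.items():
                if qc == bc and qhi >= blo and qlo <= bhi:
                    expected.add((qid, bid))
                # the c0 side span [1, 2] never reaches the QTL positions
        assert got == expected


class TestOntologyDescendants:
    def test_chain_closure(self):
        g = PropertyGraph(strict=False)
        for t in "abc":
            g.add_node(t, {"PO"})
        g.add_edge("SCO", "c", "b")
        g.add_edge("SCO", "b", "a")
        assert ontology_descendants(g, "a") == {"a", "b", "c"}
        assert ontology_descendants(g, "c") == {"c"}  # leaf: reflexive only

    def test_unknown_term_raises(self, fta1_graph):
        with pytest.raises(GraphError):
            ontology_descendants(fta1_graph, "PO:does-not-exist")

    @pytest.mark.parametrize("seed", range(20))
    def test_random_dag_matches_matrix_closure(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        terms = [f"T{i:02d}" for i in range(n)]
        g = PropertyGraph(strict=False)
        for t in terms:
            g.add_node(t, {"PO"})
        edges = {"SCO": [], "PART_OF": []}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.06:  # child i -> parent j keeps it acyclic
                    pred = "SCO" if rng.random() < 0.7 else "PART_OF"
                    edges[pred].append((terms[i], terms[j]))
                    g.add_edge(pred, terms[i], terms[j])
        root = terms[int(rng.integers(0, n))]
        for preds in ({"SCO"}, {"SCO", "PART_OF"}):
            chosen = [e for p in preds for e in edges[p]]
            assert ontology_descendants(g, root, preds) == closure_descendants(
                terms, chosen, root
            )


class TestExpressionInTissue:
    def test_descendant_annotated_conditions_included(self, fta1_graph):
        # "vegetative shoot apex" is two levels below "shoot system"
        result = expression_in_tissue(fta1_graph, [MTFTA1], "PO:0009006")
        conds = set(result.column("condition_id"))
        assert "cond_mt_veg_shoot_apex" in conds
        assert "cond_mt_root" not in conds  # root system branch excluded

    def test_exact_term_is_reflexively_included(self, fta1_graph):
        result = expression_in_tissue(fta1_graph, [MTFTA1], "PO:0004715")
        assert set(result.column("condition_id")) == {"cond_mt_veg_shoot_apex"}

    def test_ancestor_query_returns_superset(self, fta1_graph):
        genes = [MTFTA1, "Lcu.2RBY.6g043850"]
        broad = expression_in_tissue(fta1_graph, genes, "PO:0009006")
        key = lambda r: (r["gene_id"], r["sample_id"], r["condition_id"])
        broad_keys = {key(r) for r in broad}
        for descendant in ("PO:0000037", "PO:0004715", "PO:0025034"):
            narrow = expression_in_tissue(fta1_graph, genes, descendant)
            assert {key(r) for r in narrow} <= broad_keys

    def test_top_k_ranks_conditions_by_mean(self, fta1_graph, fta1_dataset):
        result = expression_in_tissue(fta1_graph, [MTFTA1], "PO:0009006", top_k=3)
        ordered_conditions = []
        for r in result:
            if r["condition_id"] not in ordered_conditions:
                ordered_conditions.append(r["condition_id"])
        assert ordered_conditions == fta1_dataset.planted["top_mtru_shoot_conditions"]
        # two replicate samples per condition
        assert len(result) == 6
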