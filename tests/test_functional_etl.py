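"""Functional-pipeline rules: GO specificity filter, expression filtering and
aggregation, QTL colocalization, ontology subgraph construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orthobridge.functional_etl import (
    aggregate_condition_expression,
    attach_functional_annotations,
    attach_qtl,
    build_ontology_subgraph,
    colocalize_qtl,
    filter_expression,
    filter_go_most_specific,
)
from orthobridge.graph_model import PropertyGraph
from orthobridge.io_formats import (
    ConditionAnnotation,
    ExpressionMatrix,
    FunctionalAnnotationRecord,
    GeneFeature,
    GenomeAnnotation,
    Ontology,
    QTLRecord,
)

from oracles import allpairs_colocalize


def go_record(gene, acc, hidden):
    return FunctionalAnnotationRecord(gene, "GO", acc, is_hidden=hidden)


class TestGOFilter:
    def test_keeps_only_unhidden_terms(self):
        records = [go_record("g", "GO:A", 1), go_record("g", "GO:B", 0)]
        assert filter_go_most_specific(records) == [records[1]]

    def test_empty_input(self):
        assert filter_go_most_specific([]) == []

    def test_non_go_records_pass_through(self):
        pfam = FunctionalAnnotationRecord("p", "Pfam", "PF00001", domain_start=1, domain_end=9)
        assert filter_go_most_specific([pfam, go_record("g", "GO:A", 1)]) == [pfam]

    def test_seeded_fixture_matches_brute_force(self):
        rng = np.random.default_rng(3)
        flags = np.array([1] * 90 + [0] * 10)
        rng.shuffle(flags)
        records = [go_record(f"g{i}", f"GO:{i}", int(flags[i])) for i in range(100)]
        survivors = filter_go_most_specific(records)
        assert survivors == [r for r in records if r.is_hidden == 0]
        assert len(survivors) == 10

    def test_missing_flag_policy(self):
        rec = FunctionalAnnotationRecord("g", "GO", "GO:A")
        assert filter_go_most_specific([rec]) == []
        assert filter_go_most_specific([rec], missing_flag="keep") == [rec]


class TestExpressionFilter:
    def _matrix(self, rows):
        return ExpressionMatrix(
            pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])
        )

    def test_boundary_is_strict(self):
        m = self._matrix([[1.0, 2.0, 3.0], [2.0, 2.0, 1.0], [0.0, 0.0, 0.0]])
        kept = filter_expression(m)
        assert kept.genes == ["g0"]  # sum 6 kept; sum exactly 5 and sum 0 dropped

    def test_counts_follow_tpm_rows(self):
        tpm = pd.DataFrame([[10.0], [1.0]], index=["g0", "g1"], columns=["s"])
        counts = pd.DataFrame([[100], [7]], index=["g0", "g1"], columns=["s"])
        kept = filter_expression(ExpressionMatrix(tpm, counts))
        assert list(kept.counts.index) == ["g0"]


class TestAggregation:
    def _one_condition(self, values, samples=None):
        samples = samples or [f"s{i}" for i in range(len(values))]
        m = ExpressionMatrix(pd.DataFrame([values], index=["g1"], columns=samples))
        cond = ConditionAnnotation("c1", tuple(samples))
        return aggregate_condition_expression(m, [cond])[0]

    def test_hand_values(self):
        ce = self._one_condition([2.0, 8.0])
        assert ce.arithmetic_mean == pytest.approx(5.0)
        assert ce.geometric_mean == pytest.approx(4.0)
        assert ce.n_samples == 2

    def test_zero_sends_geometric_mean_to_zero(self):
        ce = self._one_condition([0.0, 8.0])
        assert ce.arithmetic_mean == pytest.approx(4.0)
        assert ce.geometric_mean == 0.0

    def test_single_sample_is_identity(self):
        ce = self._one_condition([7.25])
        assert ce.arithmetic_mean == ce.geometric_mean == pytest.approx(7.25)

    def test_error_on_condition_without_samples(self):
        m = ExpressionMatrix(pd.DataFrame([[1.0]], index=["g1"], columns=["s1"]))
        with pytest.raises(ValueError, match="no sample"):
            aggregate_condition_expression(m, [ConditionAnnotation("c", ("ghost",))])

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1e5, allow_nan=False),
            min_size=1,
            max_size=8,
        )
    )
    def test_am_gm_inequality(self, values):
        ce = self._one_condition(values)
        assert ce.geometric_mean <= ce.arithmetic_mean + 1e-9
        if len(set(values)) == 1:
            assert ce.geometric_mean == pytest.approx(ce.arithmetic_mean)

    def test_filter_then_aggregate_commutes(self):
        rng = np.random.default_rng(9)
        tpm = pd.DataFrame(
            rng.lognormal(0.1, 1.5, size=(20, 4)),
            index=[f"g{i}" for i in range(20)],
            columns=["s1", "s2", "s3", "s4"],
        )
        m = ExpressionMatrix(tpm)
        conds = [
            ConditionAnnotation("cA", ("s1", "s2")),
            ConditionAnnotation("cB", ("s3", "s4")),
        ]
        filtered_first = aggregate_condition_expression(filter_expression(m), conds)
        retained = set(filter_expression(m).genes)
        aggregated_first = [
            ce for ce in aggregate_condition_expression(m, conds) if ce.gene_id in retained
        ]
        assert filtered_first == aggregated_first


def make_annotation(genes):
    chrom_len = max(g.end for g in genes) + 1000
    chroms = sorted({g.chromosome for g in genes})
    return GenomeAnnotation(
        species="sp",
        chromosomes=[(c, chrom_len) for c in chroms],
        genes=genes,
        transcripts=[],
    )


class TestColocalization:
    def test_interval_overlap(self):
        ann = make_annotation(
            [
                GeneFeature("A", "Ps03", 150, 200, "+"),
                GeneFeature("B", "Ps03", 600, 700, "+"),
            ]
        )
        qtl = QTLRecord("q", "trait", "biparental", "Ps03", 100, 500)
        colocs = colocalize_qtl([qtl], ann)
        assert [(c.gene_id, c.relation) for c in colocs] == [("A", "COLOCALIZES_WITH")]

    def test_peak_inside_gene_has_distance_zero(self):
        ann = make_annotation([GeneFeature("A", "Ps03", 150, 200, "+")])
        qtl = QTLRecord("q", "t", "biparental", "Ps03", 100, 500, peak=180)
        closest = [c for c in colocalize_qtl([qtl], ann) if c.relation == "IS_CLOSEST_TO_PEAK"]
        assert closest[0].gene_id == "A" and closest[0].distance == 0

    def test_point_qtl_with_window(self):
        ann = make_annotation(
            [
                GeneFeature("A", "c", 100, 200, "+"),
                GeneFeature("B", "c", 400, 500, "+"),
            ]
        )
        qtl = QTLRecord("q", "t", "diversity panel", "c", peak=300)
        none = [c for c in colocalize_qtl([qtl], ann) if c.relation == "COLOCALIZES_WITH"]
        assert none == []  # window 0: no gene touches the marker
        wide = [
            c
            for c in colocalize_qtl([qtl], ann, gwas_window=150)
            if c.relation == "COLOCALIZES_WITH"
        ]
        assert [c.gene_id for c in wide] == ["A", "B"]

    def test_closest_gene_search_is_genome_wide(self):
        ann = make_annotation([GeneFeature("far", "c", 5000, 5100, "+")])
        qtl = QTLRecord("q", "t", "diversity panel", "c", peak=100)
        colocs = colocalize_qtl([qtl], ann)
        assert [(c.relation, c.gene_id, c.distance) for c in colocs] == [
            ("IS_CLOSEST_TO_PEAK", "far", 4900)
        ]

    def test_unknown_chromosome_skipped(self, caplog):
        ann = make_annotation([GeneFeature("A", "c", 1, 10, "+")])
        qtl = QTLRecord("q", "t", "biparental", "elsewhere", 1, 100)
        assert colocalize_qtl([qtl], ann) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_random_fixture_matches_allpairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        genes = []
        for i in range(200):
            chrom = f"c{rng.integers(0, 4)}"
            start = int(rng.integers(1, 1_000_000))
            genes.append(
                GeneFeature(f"g{i:03d}", chrom, start, start + int(rng.integers(100, 20_000)), "+")
            )
        qtls = []
        for j in range(20):
            chrom = f"c{rng.integers(0, 5)}"  # c4 exercises the unknown-chromosome path
            if rng.random() < 0.3:
                qtls.append(
                    QTLRecord(f"q{j:02d}", "t", "diversity panel", chrom,
                              peak=int(rng.integers(1, 1_000_000)))
                )
            else:
                lo = int(rng.integers(1, 900_000))
                hi = lo + int(rng.integers(1, 100_000))
                peak = int(rng.integers(lo, hi + 1)) if rng.random() < 0.5 else None
                qtls.append(
                    QTLRecord(f"q{j:02d}", "t", "biparental", chrom, lo, hi, peak)
                )
        ann = make_annotation(genes)
        got = [
            (c.relation, c.gene_id, c.qtl_id, c.distance)
            for c in colocalize_qtl(qtls, ann)
        ]
        expected = [
            (rel, gid, qid, dist)
            for rel, gid, qid, dist in allpairs_colocalize(
                [(g.gene_id, g.chromosome, g.start, g.end) for g in genes], qtls
            )
        ]
        assert got == expected


class TestOntologySubgraph:
    def _po(self):
        return Ontology(
            "PO",
            {"PO:1": "shoot system", "PO:2": "leaf", "PO:3": "pod"},
            [("PO:2", "PO:1", "is_a"), ("PO:3", "PO:1", "part_of")],
        )

    def test_predicates_map_to_edge_types(self):
        g = PropertyGraph()
        build_ontology_subgraph(self._po(), g)
        sco = {(e.source, e.target) for e in g.edges("SCO")}
        part = {(e.source, e.target) for e in g.edges("PART_OF")}
        assert sco == {("PO:2", "PO:1")} and part == {("PO:3", "PO:1")}
        assert len(g.edges("SCO")) == 1  # one SCO edge per is_a pair

    def test_reload_is_idempotent(self):
        g = PropertyGraph()
        build_ontology_subgraph(self._po(), g)
        nodes, edges = g.num_nodes, g.num_edges
        build_ontology_subgraph(self._po(), g)
        assert (g.num_nodes, g.num_edges) == (nodes, edges)


class TestAttachOps:
    def test_protein_domain_and_dedup(self):
        g = PropertyGraph(strict=False)
        g.add_node("p1", {"Protein"})
        g.add_node("p2", {"Protein"})
        records = [
            FunctionalAnnotationRecord("p1", "PANTHER", "PTHR12565",
                                       "PEBP", domain_start=5, domain_end=170),
            FunctionalAnnotationRecord("p2", "PANTHER", "PTHR12565",
                                       "PEBP", domain_start=7, domain_end=168),
        ]
        attach_functional_annotations(records, g)
        assert len(g.nodes("FunctionalAnnotation")) == 1  # shared accession node
        edges = g.edges("HAS_DOMAIN")
        assert len(edges) == 2
        assert edges[0].properties["domain_start"] in (5, 7)

    def test_qtl_study_type_double_label(self):
        g = PropertyGraph(strict=False)
        qtls = [
            QTLRecord("q1", "days to flowering", "biparental", "c1", 1, 100),
            QTLRecord("q2", "height", "diversity panel", "c1", peak=50),
        ]
        attach_qtl(qtls, [], g)
        assert g.node("q1").labels == frozenset({"QTL", "BiparentalPopulation"})
        assert g.node("q2").labels == frozenset({"QTL", "DiversityPanel"})
        assert len(g.nodes("Trait")) == 2
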