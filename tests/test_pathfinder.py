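import pytest

from semview import (
    AnchorError,
    ColumnRef,
    ConceptTerm,
    NoPathError,
    SelfJoinError,
    SemviewError,
    annotate,
    brute_force_paths,
    build_query_graph,
    build_rdf_view,
    enrich_view,
    find_path,
    parse_rdf_view,
    random_annotated_case,
    serialize_rdf_view,
)
from semview.pathfinder import WEIGHT_FK, WEIGHT_SUBCLASS, association_weight
from semview.rdf_view import EnrichmentLabel
from semview.schema_model import load_schema_description

from conftest import PRINTED_PATH_GENO, PRINTED_PATH_PHENO

DIRECT_FK_SCHEMA = """\
# semview-schema v1
schema direct
table customer
  column id INTEGER
  column customer_name TEXT
  pk id
table invoice
  column id INTEGER
  column invoice_name TEXT
  column id_customer INTEGER
  pk id
  fk id_customer -> customer(id)
"""

TRIANGLE_SCHEMA = """\
# semview-schema v1
schema triangle
table a
  column a_name TEXT
  column id INTEGER
  pk id
table b
  column id INTEGER
  column id_a INTEGER
  pk id
  fk id_a -> a(id)
table c
  column c_name TEXT
  column id INTEGER
  column id_a INTEGER
  column id_b INTEGER
  pk id
  fk id_a -> a(id)
  fk id_b -> b(id)
"""

# a parent with three PK=FK children, each child reaching the sink table
THREE_SIBLINGS_SCHEMA = """\
# semview-schema v1
schema hier
table root
  column id INTEGER
  column root_name TEXT
  pk id
table kid1
  column id_root INTEGER
  column id_sink INTEGER
  column note TEXT
  pk id_root
  fk id_root -> root(id)
  fk id_sink -> sink(id)
table kid2
  column id_root INTEGER
  column id_sink INTEGER
  column note TEXT
  pk id_root
  fk id_root -> root(id)
  fk id_sink -> sink(id)
table kid3
  column id_root INTEGER
  column id_sink INTEGER
  column note TEXT
  pk id_root
  fk id_root -> root(id)
  fk id_sink -> sink(id)
table sink
  column id INTEGER
  column sink_name TEXT
  pk id
"""


def prepared_view(description: str, annotations):
    schema = load_schema_description(description)
    doc = enrich_view(build_rdf_view(schema), schema)
    terms = {}
    for table, column, curie in annotations:
        prefix, _, local = curie.partition(":")
        term = ConceptTerm(prefix, local, f"http://example.org/{prefix}#{local}")
        annotate(doc, ColumnRef(table, column), term)
        terms[curie] = term
    return doc, terms


class TestGraphConstruction:
    def test_gcp_graph_topology(self, gcp):
        doc, _ = gcp
        graph = build_query_graph(doc)
        assert graph.nodes == (
            "dnasample", "genotypingstudy", "germplasm", "phenotypingstudy", "study",
        )
        by_kind = {}
        for edge in graph.edges:
            by_kind.setdefault(edge.kind, set()).add((edge.u, edge.v, edge.via))
        assert by_kind["association"] == {
            ("dnasample", "genotypingstudy", "dnasamplegenotypingstudy"),
            ("germplasm", "phenotypingstudy", "germplasmphenotypingstudy"),
        }
        assert by_kind["fk"] == {("dnasample", "germplasm", None)}
        assert by_kind["subclass"] == {
            ("genotypingstudy", "study", None),
            ("phenotypingstudy", "study", None),
        }

    def test_single_annotated_table(self):
        doc, _ = prepared_view(
            "schema one\ntable t\n  column id INTEGER\n  column t_name TEXT\n  pk id\n",
            [("t", "t_name", "x:thing")],
        )
        graph = build_query_graph(doc)
        assert graph.nodes == ("t",)
        assert graph.edges == ()
        assert len(graph.anchors) == 1

    def test_ternary_association_edges(self):
        description = (
            "schema ternary\n"
            "table a\n  column a_name TEXT\n  column id INTEGER\n  pk id\n"
            "table b\n  column b_name TEXT\n  column id INTEGER\n  pk id\n"
            "table c\n  column c_name TEXT\n  column id INTEGER\n  pk id\n"
            "table link\n  column id_a INTEGER\n  column id_b INTEGER\n"
            "  column id_c INTEGER\n  pk id_a,id_b,id_c\n"
            "  fk id_a -> a(id)\n  fk id_b -> b(id)\n  fk id_c -> c(id)\n"
        )
        doc, _ = prepared_view(description, [])
        graph = build_query_graph(doc)
        assoc = [e for e in graph.edges if e.kind == "association"]
        assert len(assoc) == 3
        assert all(e.arity == 3 and e.weight == association_weight(3) for e in assoc)

    def test_unannotated_document_has_empty_anchors(self, gcp_fixture):
        doc = enrich_view(build_rdf_view(gcp_fixture.schema), gcp_fixture.schema)
        assert build_query_graph(doc).anchors == {}


class TestFindPath:
    def test_worked_example_aggregates_both_branches(self, gcp):
        doc, _ = gcp
        path = find_path(build_query_graph(doc), "gcpdm:study", "gcpdm:germplasm")
        rendered = {branch.rendered_nodes() for branch in path.branches}
        assert rendered == {PRINTED_PATH_GENO, PRINTED_PATH_PHENO}
        assert path.branches[0].rendered_nodes() == PRINTED_PATH_PHENO  # cheaper

    def test_direct_fk_single_branch(self):
        doc, _ = prepared_view(
            DIRECT_FK_SCHEMA,
            [("customer", "customer_name", "x:cust"), ("invoice", "invoice_name", "x:inv")],
        )
        path = find_path(build_query_graph(doc), "x:cust", "x:inv")
        assert len(path.branches) == 1
        branch = path.branches[0]
        assert branch.nodes == ("customer", "invoice")
        assert branch.cost == WEIGHT_FK

    def test_three_sibling_hierarchy_aggregates_all(self):
        doc, _ = prepared_view(
            THREE_SIBLINGS_SCHEMA,
            [("root", "root_name", "x:root"), ("sink", "sink_name", "x:sink")],
        )
        path = find_path(build_query_graph(doc), "x:root", "x:sink")
        assert [b.nodes for b in path.branches] == [
            ("root", "kid1", "sink"),
            ("root", "kid2", "sink"),
            ("root", "kid3", "sink"),
        ]
        assert all(b.cost == WEIGHT_SUBCLASS + WEIGHT_FK for b in path.branches)

    def test_self_join_rejected(self, gcp):
        doc, _ = gcp
        with pytest.raises(SelfJoinError):
            find_path(build_query_graph(doc), "gcpdm:study", "gcpdm:study")

    def test_unanchored_term_rejected(self, gcp):
        doc, _ = gcp
        with pytest.raises(AnchorError):
            find_path(build_query_graph(doc), "gcpdm:study", "gcpdm:qtl")

    def test_disconnected_concepts_raise_no_path(self):
        doc, _ = prepared_view(
            "schema split\n"
            "table a\n  column a_name TEXT\n  column id INTEGER\n  pk id\n"
            "table b\n  column b_name TEXT\n  column id INTEGER\n  pk id\n",
            [("a", "a_name", "x:a"), ("b", "b_name", "x:b")],
        )
        with pytest.raises(NoPathError) as err:
            find_path(build_query_graph(doc), "x:a", "x:b")
        assert "x#a" in str(err.value) and "x#b" in str(err.value)

    def test_deterministic_and_insertion_order_independent(self, gcp):
        doc, _ = gcp
        graph_a = build_query_graph(doc)
        graph_b = build_query_graph(parse_rdf_view(serialize_rdf_view(doc)))
        path_a = find_path(graph_a, "gcpdm:study", "gcpdm:germplasm")
        path_b = find_path(graph_b, "gcpdm:study", "gcpdm:germplasm")
        assert [b.nodes for b in path_a.branches] == [b.nodes for b in path_b.branches]
        assert [b.cost for b in path_a.branches] == [b.cost for b in path_b.branches]
        again = find_path(graph_a, "gcpdm:study", "gcpdm:germplasm")
        assert again == path_a


class TestBruteForceOracle:
    def test_enumeration_contains_both_printed_branches(self, gcp):
        doc, _ = gcp
        graph = build_query_graph(doc)
        rendered = {
            b.rendered_nodes() for b in brute_force_paths(graph, "study", "germplasm")
        }
        assert {PRINTED_PATH_GENO, PRINTED_PATH_PHENO} <= rendered

    def test_disconnected_pair_enumerates_nothing(self):
        doc, _ = prepared_view(
            "schema split\n"
            "table a\n  column id INTEGER\n  pk id\n"
            "table b\n  column id INTEGER\n  pk id\n",
            [],
        )
        assert brute_force_paths(build_query_graph(doc), "a", "b") == []

    def test_triangle_has_two_simple_paths(self):
        doc, _ = prepared_view(TRIANGLE_SCHEMA, [])
        paths = brute_force_paths(build_query_graph(doc), "a", "b")
        assert [p.nodes for p in paths] == [("a", "b"), ("a", "c", "b")]

    def test_size_guard_refuses_large_graphs(self, gcp):
        doc, _ = gcp
        graph = build_query_graph(doc)
        with pytest.raises(SemviewError):
            brute_force_paths(graph, "study", "germplasm", max_nodes=3)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(50))
    def test_primary_cost_matches_exhaustive_minimum(self, seed, tmp_path):
        doc, schema, _, t_in, t_out = random_annotated_case(
            seed, 4 + seed % 9, directory=str(tmp_path)
        )
        if t_in is None:
            pytest.skip("schema too small for two annotated tables")
        graph = build_query_graph(doc)
        src = graph.anchors[t_in.uri][0][0]
        dst = graph.anchors[t_out.uri][0][0]
        enumerated = brute_force_paths(graph, src, dst)
        try:
            path = find_path(graph, t_in, t_out)
        except NoPathError:
            assert enumerated == []
            return
        assert enumerated, "find_path found a path the oracle missed"
        assert path.branches[0].cost == min(p.cost for p in enumerated)

    @pytest.mark.parametrize("seed", range(0, 30, 3))
    def test_dijkstra_agrees_with_networkx(self, seed, tmp_path):
        import networkx as nx

        doc, schema, _, t_in, t_out = random_annotated_case(
            seed, 10, directory=str(tmp_path)
        )
        if t_in is None:
            pytest.skip("schema too small for two annotated tables")
        graph = build_query_graph(doc)
        g = nx.MultiGraph()
        g.add_nodes_from(graph.nodes)
        for e in graph.edges:
            g.add_edge(e.u, e.v, weight=e.weight)
        src = graph.anchors[t_in.uri][0][0]
        dst = graph.anchors[t_out.uri][0][0]
        try:
            expected = nx.shortest_path_length(g, src, dst, weight="weight")
        except nx.NetworkXNoPath:
            with pytest.raises(NoPathError):
                find_path(graph, t_in, t_out)
            return
        assert find_path(graph, t_in, t_out).branches[0].cost == expected


class TestWeightScheme:
    def test_weights(self):
        assert WEIGHT_FK == 10
        assert WEIGHT_SUBCLASS == 2
        assert association_weight(2) == 10
        assert association_weight(3) == 15

    def test_raising_arity_never_cheapens_paths(self, gcp):
        """Binary associations are favoured: bumping an arity label can only
        keep or increase every path cost."""
        doc, _ = gcp
        base = find_path(build_query_graph(doc), "gcpdm:study", "gcpdm:germplasm")
        doc.enrichment_labels = [
            EnrichmentLabel(l.subject, l.kind, 3)
            if l.kind == "arity" and l.subject == "map:dnasamplegenotypingstudy"
            else l
            for l in doc.enrichment_labels
        ]
        bumped = find_path(build_query_graph(doc), "gcpdm:study", "gcpdm:germplasm")
        assert bumped.branches[0].cost >= base.branches[0].cost
        geno_base = next(
            b for b in base.branches if "genotypingstudy" in b.nodes
        )
        geno_bumped = next(
            b for b in bumped.branches if "genotypingstudy" in b.nodes
        )
        assert geno_bumped.cost > geno_base.cost
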