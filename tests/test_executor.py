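import sqlite3

import pytest

from semview import (
    DatabaseConnectionError,
    FixtureSpec,
    UnsupportedConstructError,
    build_gcp_view,
    build_query_graph,
    execute,
    find_path,
    generate_sparql,
    random_annotated_case,
    translate_to_sql,
)
from semview.pathfinder import QueryPath
from semview.schema_model import ConnectionMeta

from _oracles import expected_rows


def gcp_query(gcp, pattern):
    doc, fixture = gcp
    path = find_path(build_query_graph(doc), "gcpdm:study", "gcpdm:germplasm")
    return doc, fixture, path, generate_sparql(path, doc, pattern)


def oracle_for(fixture, path, pattern, literal):
    chains = [b.rendered_nodes() for b in path.branches]
    return expected_rows(
        fixture.db_path, fixture.schema, chains,
        path.input[1], path.output[1], pattern, literal,
    )


class TestTranslation:
    def test_gcp_plan_has_two_selects_unioned(self, gcp):
        doc, fixture, path, query = gcp_query(gcp, "study_001")
        plan = translate_to_sql(query, doc)
        assert len(plan.selects) == 2
        assert plan.text.count("UNION") == 1
        # both printed join chains appear
        assert "FROM study, phenotypingstudy, germplasmphenotypingstudy, germplasm" in plan.text
        assert ("FROM study, genotypingstudy, dnasamplegenotypingstudy, "
                "dnasample, germplasm") in plan.text

    def test_single_block_plan_has_no_union(self, gcp):
        doc, fixture, path, _ = gcp_query(gcp, "study_001")
        solo = QueryPath(path.input, path.output, (path.branches[0],))
        plan = translate_to_sql(generate_sparql(solo, doc, "study_001"), doc)
        assert "UNION" not in plan.text
        assert plan.text.startswith("SELECT DISTINCT")

    def test_optional_is_unsupported(self, gcp):
        doc, fixture, path, query = gcp_query(gcp, "study_001")
        query.extra_clauses.append("OPTIONAL { ?x ?y ?z. }")
        with pytest.raises(UnsupportedConstructError) as err:
            translate_to_sql(query, doc)
        assert err.value.construct == "OPTIONAL"

    def test_literal_filter_becomes_equality(self, gcp):
        doc, fixture, path, query = gcp_query(gcp, "study_001")
        plan = translate_to_sql(query, doc)
        assert "study.study_name = 'study_001'" in plan.text
        assert plan.post_filter is None

    def test_regex_filter_becomes_post_filter(self, gcp):
        doc, fixture, path, query = gcp_query(gcp, "study_00[12]$")
        plan = translate_to_sql(query, doc)
        assert "study.study_name =" not in plan.text
        assert plan.post_filter is not None


class TestExecution:
    def test_literal_filter_matches_hand_oracle(self, gcp):
        doc, fixture, path, query = gcp_query(gcp, "study_001")
        result = execute(translate_to_sql(query, doc), fixture.connection)
        assert result.rows == oracle_for(fixture, path, "study_001", literal=True)
        # independent expectation from the fixture's branch membership
        reachable = sorted(set(fixture.genotyping_germplasms)
                           | set(fixture.phenotyping_germplasms))
        assert result.rows == [
            ("study_001", f"germplasm_{g:03d}") for g in reachable
        ]

    def test_regex_filter_matches_hand_oracle(self, gcp):
        doc, fixture, path, query = gcp_query(gcp, "study_00[12]$")
        result = execute(translate_to_sql(query, doc), fixture.connection)
        assert result.rows == oracle_for(fixture, path, "study_00[12]$", literal=False)
        assert result.rows  # the pattern matches two studies

    def test_unmatched_filter_yields_empty_result(self, gcp):
        doc, fixture, path, query = gcp_query(gcp, "no_such_study")
        result = execute(translate_to_sql(query, doc), fixture.connection)
        assert result.rows == []

    def test_overlapping_branches_deduplicate(self, tmp_path):
        gcp = build_gcp_view(FixtureSpec(overlap_fraction=1.0), str(tmp_path))
        doc, fixture, path, query = gcp_query(gcp, "study_001")
        plan = translate_to_sql(query, doc)
        result = execute(plan, fixture.connection)
        # every germplasm reachable via both branches, but reported once
        assert len(result.rows) == len(set(result.rows)) == 5
        # UNION ALL then dedupe equals the UNION result (set semantics)
        con = sqlite3.connect(fixture.db_path)
        try:
            raw = con.execute(plan.text.replace("UNION", "UNION ALL")).fetchall()
        finally:
            con.close()
        assert sorted({(str(a), str(b)) for a, b in raw}) == result.rows

    def test_rows_are_sorted(self, gcp):
        doc, fixture, path, query = gcp_query(gcp, "study_00.*")
        result = execute(translate_to_sql(query, doc), fixture.connection)
        assert result.rows == sorted(result.rows)

    def test_missing_database_raises(self, gcp):
        doc, fixture, path, query = gcp_query(gcp, "study_001")
        with pytest.raises(DatabaseConnectionError):
            execute(translate_to_sql(query, doc),
                    ConnectionMeta("sqlite", "/nonexistent/db.sqlite"))


class TestAggregationBenefit:
    def test_disjoint_branches_aggregated_strictly_more(self, tmp_path):
        doc, fixture = build_gcp_view(FixtureSpec(overlap_fraction=0.0), str(tmp_path))
        path = find_path(build_query_graph(doc), "gcpdm:study", "gcpdm:germplasm")
        full = execute(
            translate_to_sql(generate_sparql(path, doc, "study_001"), doc),
            fixture.connection,
        )
        solo = QueryPath(path.input, path.output, (path.branches[0],))
        primary = execute(
            translate_to_sql(generate_sparql(solo, doc, "study_001"), doc),
            fixture.connection,
        )
        assert len(full.rows) > len(primary.rows)
        assert set(primary.rows) <= set(full.rows)

    @pytest.mark.parametrize("overlap", [0.0, 0.5, 1.0])
    def test_aggregated_never_fewer(self, overlap, tmp_path):
        doc, fixture = build_gcp_view(
            FixtureSpec(overlap_fraction=overlap), str(tmp_path)
        )
        path = find_path(build_query_graph(doc), "gcpdm:study", "gcpdm:germplasm")
        full = execute(
            translate_to_sql(generate_sparql(path, doc, "study_001"), doc),
            fixture.connection,
        )
        solo = QueryPath(path.input, path.output, (path.branches[0],))
        primary = execute(
            translate_to_sql(generate_sparql(solo, doc, "study_001"), doc),
            fixture.connection,
        )
        assert len(full.rows) >= len(primary.rows)


class TestRandomSchemaEquivalence:
    @pytest.mark.parametrize("seed", range(12))
    def test_rows_match_nested_loop_oracle(self, seed, tmp_path):
        doc, schema, db_path, t_in, t_out = random_annotated_case(
            seed, 5 + seed % 7, directory=str(tmp_path)
        )
        if t_in is None:
            pytest.skip("schema too small for two annotated tables")
        graph = build_query_graph(doc)
        from semview import NoPathError

        try:
            path = find_path(graph, t_in, t_out)
        except NoPathError:
            pytest.skip("concepts not connected")
        connection = ConnectionMeta("sqlite", f"sqlite:///{db_path}")
        for pattern, literal in ((".*", False), (f"{path.input[1].table}_001", True)):
            query = generate_sparql(path, doc, pattern)
            result = execute(translate_to_sql(query, doc), connection)
            chains = [b.rendered_nodes() for b in path.branches]
            assert result.rows == expected_rows(
                db_path, schema, chains, path.input[1], path.output[1],
                pattern, literal,
            ), (seed, pattern)
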