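"""Translate the restricted SPARQL fragment to SQL and execute it.

Only queries produced by :func:`semview.sparql_gen.generate_sparql` are in
the translatable fragment: a shared input-anchor triple, a regex filter on
the input variable and UNION blocks of FK/association join triples.  Each
block becomes one SELECT over a join chain; blocks are combined with SQL
``UNION`` (set semantics, mirroring ``SELECT DISTINCT``).

Filters: an anchored literal pattern becomes a SQL equality predicate; a
genuine regular expression is applied as a row-level post-filter in Python
after fetching (regular expressions pushed into large scans are a known
memory hazard, and SQLite ships no native REGEXP), which bounds the risk
while preserving SPARQL ``regex()`` (unanchored search) semantics.

Result rows are deduplicated and sorted so executions are reproducible.
"""

from __future__ import annotations

import re
import sqlite3
from dataclasses import dataclass

from .errors import (
    DatabaseConnectionError,
    SqlExecutionError,
    UnsupportedConstructError,
    ViewError,
)
from .rdf_view import MappingDocument
from .schema_model import ConnectionMeta
from .sparql_gen import SparqlQuery

_BLOCKED_CONSTRUCTS = (
    "OPTIONAL", "GROUP BY", "GRAPH", "SERVICE", "MINUS", "BIND", "VALUES",
    "ORDER BY", "HAVING", "EXISTS",
)


@dataclass
class SqlPlan:
    selects: list[str]  # one SELECT per union block
    text: str  # combined with UNION
    columns: list[str]  # [input label, output label]
    post_filter: "re.Pattern[str] | None"  # applied to the input column


@dataclass
class ResultSet:
    columns: list[str]
    rows: list[tuple[str, str]]
    distinct: bool = True


def translate_to_sql(query: SparqlQuery, doc: MappingDocument) -> SqlPlan:
    """Mechanically map each union block to a SELECT over its join chain."""
    for clause in query.extra_clauses:
        stripped = clause.strip()
        for construct in _BLOCKED_CONSTRUCTS:
            if stripped.upper().startswith(construct):
                raise UnsupportedConstructError(construct)
        if not stripped.upper().startswith("FILTER"):
            raise UnsupportedConstructError(stripped.split()[0] if stripped else "<empty>")

    bridges_by_predicate = {
        b.predicate: b for b in doc.property_bridges.values() if b.predicate
    }
    in_col = query.input_anchor
    out_col = query.output_anchor
    literal = query.is_literal_filter
    selects = []
    for block in query.union_blocks:
        tables: list[str] = []
        joins: list[str] = []

        def seen(table: str):
            if table not in tables:
                tables.append(table)

        seen(in_col.table)
        for tp in query.shared_prefix + block:
            if tp.predicate in bridges_by_predicate:
                bridge = bridges_by_predicate[tp.predicate]
                seen(bridge.column.table)
                seen(bridge.join.target_table)
                for src, dst in bridge.join.pairs:
                    joins.append(f"{src} = {dst}")
            elif tp.predicate in (query.input_term, query.output_term):
                continue  # anchor triples contribute the SELECT columns
            else:
                raise UnsupportedConstructError(f"predicate {tp.predicate}")
        seen(out_col.table)
        where = list(joins)
        if literal:
            value = query.filter_regex[1:-1].replace("'", "''")
            where.append(f"{in_col} = '{value}'")
        distinct = "DISTINCT " if len(query.union_blocks) == 1 else ""
        sql = (
            f"SELECT {distinct}{in_col} AS input_value, {out_col} AS output_value\n"
            f"FROM {', '.join(tables)}"
        )
        if where:
            sql += "\nWHERE " + "\n  AND ".join(where)
        selects.append(sql)

    post = None if literal else re.compile(query.filter_regex)
    return SqlPlan(
        selects=selects,
        text="\nUNION\n".join(selects),
        columns=[v.lstrip("?") for v in query.select_vars],
        post_filter=post,
    )


def execute(plan: SqlPlan, connection: ConnectionMeta) -> ResultSet:
    """Run the plan against the source database; distinct, sorted rows."""
    if connection.engine not in ("sqlite", "sqlite3"):
        raise DatabaseConnectionError(f"unsupported engine {connection.engine!r}")
    import os

    path = connection.path
    if path != ":memory:" and not os.path.exists(path):
        raise DatabaseConnectionError(f"database file not found: {path}")
    con = sqlite3.connect(path)
    try:
        try:
            cursor = con.execute(plan.text)
        except sqlite3.Error as exc:
            raise SqlExecutionError(f"{exc}\n--- offending SQL ---\n{plan.text}") from exc
        rows = {(str(a), str(b)) for a, b in cursor.fetchall()}
    finally:
        con.close()
    if plan.post_filter is not None:
        rows = {r for r in rows if plan.post_filter.search(r[0])}
    return ResultSet(columns=list(plan.columns), rows=sorted(rows), distinct=True)


def run_query(query: SparqlQuery, doc: MappingDocument,
              connection: ConnectionMeta | None = None) -> ResultSet:
    """Convenience: translate and execute against the view's own database."""
    conn = connection or doc.connection
    if conn is None:
        raise ViewError("mapping document carries no connection metadata")
    return execute(translate_to_sql(query, doc), conn)
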