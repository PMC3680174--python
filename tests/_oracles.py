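"""Independent oracles for result-set and path checks.

These deliberately avoid the package's SPARQL/SQL machinery: rows are
joined by a naive nested-loop walk over tables fetched straight from
SQLite, using only the schema's foreign keys to pair columns.  The
pathfinder oracle lives in the package (`brute_force_paths`); this module
covers the data plane.
"""

from __future__ import annotations

import re
import sqlite3

from semview.schema_model import ColumnRef, RelationalSchema


def fetch_table(db_path: str, table: str) -> list[dict]:
    con = sqlite3.connect(db_path)
    try:
        cur = con.execute(f'SELECT * FROM "{table}"')
        cols = [d[0] for d in cur.description]
        return [dict(zip(cols, row)) for row in cur.fetchall()]
    finally:
        con.close()


def join_pairs(schema: RelationalSchema, a: str, b: str) -> list[tuple[str, str]]:
    """Column pairs (col_in_a, col_in_b) of the FK linking adjacent tables."""
    for fk in schema.tables[a].foreign_keys:
        if fk.target_table == b:
            return [(s.column, t.column) for s, t in zip(fk.source_columns, fk.target_columns)]
    for fk in schema.tables[b].foreign_keys:
        if fk.target_table == a:
            return [(t.column, s.column) for s, t in zip(fk.source_columns, fk.target_columns)]
    raise AssertionError(f"no foreign key between {a} and {b}")


def branch_rows(
    db_path: str,
    schema: RelationalSchema,
    chain: tuple[str, ...],
    in_col: ColumnRef,
    out_col: ColumnRef,
    match,
) -> set[tuple[str, str]]:
    """Nested-loop join along one expanded table chain (via tables included)."""
    data = {t: fetch_table(db_path, t) for t in set(chain)}
    partial = [
        (row,) for row in data[chain[0]] if match(str(row[in_col.column]))
    ]
    for i in range(1, len(chain)):
        a, b = chain[i - 1], chain[i]
        pairs = join_pairs(schema, a, b)
        nxt = []
        for tup in partial:
            ra = tup[-1]
            for rb in data[b]:
                if all(ra[ca] == rb[cb] for ca, cb in pairs):
                    nxt.append(tup + (rb,))
        partial = nxt
    return {
        (str(tup[0][in_col.column]), str(tup[-1][out_col.column])) for tup in partial
    }


def expected_rows(
    db_path: str,
    schema: RelationalSchema,
    chains: list[tuple[str, ...]],
    in_col: ColumnRef,
    out_col: ColumnRef,
    pattern: str,
    literal: bool,
) -> list[tuple[str, str]]:
    """Set-union of nested-loop results over all branches, sorted."""
    if literal:
        match = lambda v: v == pattern  # noqa: E731
    else:
        rx = re.compile(pattern)
        match = lambda v: bool(rx.search(v))  # noqa: E731
    rows: set[tuple[str, str]] = set()
    for chain in chains:
        rows |= branch_rows(db_path, schema, chain, in_col, out_col, match)
    return sorted(rows)
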