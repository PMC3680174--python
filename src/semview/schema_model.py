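"""Relational schema model and acquisition.

A :class:`RelationalSchema` captures the structural elements a mapping
document needs — tables, columns, primary keys and foreign keys — without
any of the data.  Schemas are acquired either by live introspection of an
embedded SQLite database (:func:`introspect_schema`) or from a small
line-oriented schema description document (:func:`load_schema_description`),
which exists so that tests and tools can define schemas without a database.

Schema description format (version 1)::

    # semview-schema v1
    schema <name>
    table <name>
      column <name> <TYPE>
      pk <col>[,<col>...]
      fk <col>[,<col>...] -> <table>(<col>[,<col>...]) [name <fkname>]

Tables and columns are kept in canonical (name-sorted) order so that two
acquisitions of the same schema compare equal.
"""

from __future__ import annotations

import os
import re
import sqlite3
from dataclasses import dataclass, field, replace

from .errors import DatabaseConnectionError, SchemaError, SchemaParseError

SCHEMA_FORMAT_HEADER = "# semview-schema v1"


@dataclass(frozen=True)
class ColumnRef:
    """A column addressed as ``table.column``."""

    table: str
    column: str

    def __post_init__(self):
        if not self.table or not self.column:
            raise SchemaError("ColumnRef requires non-empty table and column names")

    def __str__(self) -> str:
        return f"{self.table}.{self.column}"

    @classmethod
    def parse(cls, text: str) -> "ColumnRef":
        table, sep, column = text.partition(".")
        if not sep:
            raise SchemaError(f"expected table.column, got {text!r}")
        return cls(table, column)


@dataclass(frozen=True)
class ForeignKey:
    """One relationship edge: ordered source columns referencing the target PK."""

    source_columns: tuple[ColumnRef, ...]
    target_columns: tuple[ColumnRef, ...]
    name: str | None = None

    def __post_init__(self):
        if len(self.source_columns) == 0:
            raise SchemaError("ForeignKey requires at least one column pair")
        if len(self.source_columns) != len(self.target_columns):
            raise SchemaError("ForeignKey source/target column counts differ")
        if len({c.table for c in self.source_columns}) != 1:
            raise SchemaError("ForeignKey source columns must be in one table")
        if len({c.table for c in self.target_columns}) != 1:
            raise SchemaError("ForeignKey target columns must be in one table")

    @property
    def source_table(self) -> str:
        return self.source_columns[0].table

    @property
    def target_table(self) -> str:
        return self.target_columns[0].table


@dataclass(frozen=True)
class Column:
    name: str
    dtype: str = "TEXT"


@dataclass(frozen=True)
class Table:
    name: str
    columns: tuple[Column, ...]
    primary_key: tuple[str, ...] = ()
    foreign_keys: tuple[ForeignKey, ...] = ()

    def __post_init__(self):
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise SchemaError(f"duplicate column names in table {self.name!r}")
        for pk_col in self.primary_key:
            if pk_col not in names:
                raise SchemaError(
                    f"primary key column {pk_col!r} not in table {self.name!r}"
                )
        for fk in self.foreign_keys:
            if fk.source_table != self.name:
                raise SchemaError(
                    f"foreign key of table {self.name!r} has sources in {fk.source_table!r}"
                )
            for ref in fk.source_columns:
                if ref.column not in names:
                    raise SchemaError(
                        f"foreign key column {ref.column!r} not in table {self.name!r}"
                    )

    @property
    def column_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)


@dataclass(frozen=True)
class ConnectionMeta:
    """How to reach the database: engine + URI (and optional credentials)."""

    engine: str
    uri: str
    credentials: tuple[str, str] | None = None

    def __post_init__(self):
        if not self.uri:
            raise SchemaError("ConnectionMeta.uri must be non-empty")

    @property
    def path(self) -> str:
        """Filesystem path for sqlite URIs (``sqlite:///path`` or a bare path)."""
        uri = self.uri
        if uri.startswith("sqlite:///"):
            return uri[len("sqlite:///"):]
        return uri


@dataclass
class RelationalSchema:
    name: str
    tables: dict[str, Table] = field(default_factory=dict)
    connection: ConnectionMeta | None = None

    def table(self, name: str) -> Table:
        try:
            return self.tables[name]
        except KeyError:
            raise SchemaError(f"unknown table {name!r}") from None

    def __eq__(self, other):
        if not isinstance(other, RelationalSchema):
            return NotImplemented
        return self.name == other.name and self.tables == other.tables

    def __hash__(self):
        return hash((self.name, tuple(sorted(self.tables))))


@dataclass(frozen=True)
class Diagnostic:
    severity: str  # "warning" | "error"
    table: str
    message: str


# ---------------------------------------------------------------------------
# Introspection (SQLite)
# ---------------------------------------------------------------------------

def _connect(connection: ConnectionMeta) -> sqlite3.Connection:
    if connection.engine not in ("sqlite", "sqlite3"):
        raise DatabaseConnectionError(
            f"unsupported engine {connection.engine!r}: only sqlite is built in"
        )
    path = connection.path
    if path != ":memory:" and not os.path.exists(path):
        raise DatabaseConnectionError(f"database file not found: {path}")
    try:
        return sqlite3.connect(path)
    except sqlite3.Error as exc:  # pragma: no cover - hard to force
        raise DatabaseConnectionError(str(exc)) from exc


def introspect_schema(connection: ConnectionMeta, name: str | None = None) -> RelationalSchema:
    """Read every base table (columns, PK, FKs) from a live SQLite database.

    Ordering is canonical: tables and columns sorted by name, so repeated
    introspection of an unchanged database yields equal schemas.  Views and
    SQLite-internal tables are skipped; tables without a declared primary key
    are retained (they surface as warnings in :func:`validate_schema`).
    """
    con = _connect(connection)
    try:
        cur = con.execute(
            "SELECT name FROM sqlite_master WHERE type='table' "
            "AND name NOT LIKE 'sqlite_%' ORDER BY name"
        )
        table_names = [row[0] for row in cur.fetchall()]
        tables: dict[str, Table] = {}
        for tname in table_names:
            info = con.execute(f'PRAGMA table_info("{tname}")').fetchall()
            # cid, name, type, notnull, dflt_value, pk-ordinal
            columns = tuple(
                sorted((Column(r[1], (r[2] or "TEXT").upper()) for r in info),
                       key=lambda c: c.name)
            )
            pk = tuple(r[1] for r in sorted((r for r in info if r[5]), key=lambda r: r[5]))
            fk_rows = con.execute(f'PRAGMA foreign_key_list("{tname}")').fetchall()
            # id, seq, table, from, to, on_update, on_delete, match
            grouped: dict[int, list] = {}
            for r in fk_rows:
                grouped.setdefault(r[0], []).append(r)
            fks = []
            for fid in sorted(grouped):
                rows = sorted(grouped[fid], key=lambda r: r[1])
                target = rows[0][2]
                sources = tuple(ColumnRef(tname, r[3]) for r in rows)
                tcols = []
                for r in rows:
                    if r[4] is not None:
                        tcols.append(ColumnRef(target, r[4]))
                if len(tcols) != len(sources):
                    # FK declared against the target PK implicitly
                    tinfo = con.execute(f'PRAGMA table_info("{target}")').fetchall()
                    tpk = [r[1] for r in sorted((r for r in tinfo if r[5]), key=lambda r: r[5])]
                    tcols = [ColumnRef(target, c) for c in tpk]
                fks.append(ForeignKey(sources, tuple(tcols)))
            fks.sort(key=lambda fk: tuple(str(c) for c in fk.source_columns))
            tables[tname] = Table(tname, columns, pk, tuple(fks))
        return RelationalSchema(name or _default_name(connection), tables, connection)
    finally:
        con.close()


def _default_name(connection: ConnectionMeta) -> str:
    base = os.path.basename(connection.path)
    return os.path.splitext(base)[0] or "schema"


# ---------------------------------------------------------------------------
# Schema description documents
# ---------------------------------------------------------------------------

_FK_RE = re.compile(
    r"^fk\s+(?P<src>[\w,\s]+?)\s*->\s*(?P<table>\w+)\s*\((?P<dst>[^)]*)\)"
    r"(?:\s+name\s+(?P<name>\S+))?$"
)


def load_schema_description(document: str) -> RelationalSchema:
    """Parse a version-1 schema description document into a schema.

    Raises :class:`SchemaParseError` (with the offending line number) on
    malformed input and :class:`SchemaError` if a foreign key references a
    table missing from the document.
    """
    schema_name: str | None = None
    tables: dict[str, Table] = {}
    current: str | None = None
    cols: list[Column] = []
    pk: tuple[str, ...] = ()
    fks: list[ForeignKey] = []

    def flush():
        nonlocal current, cols, pk, fks
        if current is not None:
            tables[current] = Table(
                current,
                tuple(sorted(cols, key=lambda c: c.name)),
                pk,
                tuple(sorted(fks, key=lambda fk: tuple(str(c) for c in fk.source_columns))),
            )
        current, cols, pk, fks = None, [], (), []

    for lineno, raw in enumerate(document.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        keyword = parts[0]
        rest = parts[1] if len(parts) > 1 else ""
        if keyword == "schema":
            if not rest:
                raise SchemaParseError("schema requires a name", lineno)
            schema_name = rest.strip()
        elif keyword == "table":
            if not rest:
                raise SchemaParseError("table requires a name", lineno)
            flush()
            current = rest.strip()
        elif keyword == "column":
            if current is None:
                raise SchemaParseError("column outside a table block", lineno)
            bits = rest.split()
            if not bits:
                raise SchemaParseError("column requires a name", lineno)
            cols.append(Column(bits[0], bits[1].upper() if len(bits) > 1 else "TEXT"))
        elif keyword == "pk":
            if current is None:
                raise SchemaParseError("pk outside a table block", lineno)
            pk = tuple(c.strip() for c in rest.split(",") if c.strip())
            if not pk:
                raise SchemaParseError("pk requires column names", lineno)
        elif keyword == "fk":
            if current is None:
                raise SchemaParseError("fk outside a table block", lineno)
            m = _FK_RE.match(line)
            if not m:
                raise SchemaParseError(f"malformed fk clause: {line!r}", lineno)
            src = [c.strip() for c in m.group("src").split(",") if c.strip()]
            dst = [c.strip() for c in m.group("dst").split(",") if c.strip()]
            target = m.group("table")
            if len(src) != len(dst):
                raise SchemaParseError("fk source/target column counts differ", lineno)
            fks.append(
                ForeignKey(
                    tuple(ColumnRef(current, c) for c in src),
                    tuple(ColumnRef(target, c) for c in dst),
                    m.group("name"),
                )
            )
        else:
            raise SchemaParseError(f"unknown keyword {keyword!r}", lineno)
    flush()
    if schema_name is None:
        raise SchemaParseError("document missing a 'schema <name>' line")
    schema = RelationalSchema(schema_name, dict(sorted(tables.items())))
    errors = [d for d in validate_schema(schema) if d.severity == "error"]
    if errors:
        raise SchemaError("; ".join(d.message for d in errors))
    return schema


def serialize_schema_description(schema: RelationalSchema) -> str:
    """Render a schema in the version-1 description format (canonical order)."""
    out = [SCHEMA_FORMAT_HEADER, f"schema {schema.name}"]
    for tname in sorted(schema.tables):
        table = schema.tables[tname]
        out.append(f"table {tname}")
        for col in table.columns:
            out.append(f"  column {col.name} {col.dtype}")
        if table.primary_key:
            out.append(f"  pk {','.join(table.primary_key)}")
        for fk in table.foreign_keys:
            src = ",".join(c.column for c in fk.source_columns)
            dst = ",".join(c.column for c in fk.target_columns)
            suffix = f" name {fk.name}" if fk.name else ""
            out.append(f"  fk {src} -> {fk.target_table}({dst}){suffix}")
    return "\n".join(out) + "\n"


def validate_schema(schema: RelationalSchema) -> list[Diagnostic]:
    """Check structural invariants; returns diagnostics instead of raising.

    An empty list means every table has a primary key and every foreign key
    resolves to an existing table whose primary key it targets.
    """
    diags: list[Diagnostic] = []
    for tname, table in schema.tables.items():
        if not table.primary_key:
            diags.append(Diagnostic("warning", tname, f"table {tname!r} has no primary key"))
        for fk in table.foreign_keys:
            target = fk.target_table
            if target not in schema.tables:
                diags.append(
                    Diagnostic("error", tname,
                               f"foreign key of {tname!r} references unknown table {target!r}")
                )
                continue
            tpk = schema.tables[target].primary_key
            tcols = tuple(c.column for c in fk.target_columns)
            if tuple(sorted(tcols)) != tuple(sorted(tpk)):
                diags.append(
                    Diagnostic("error", tname,
                               f"foreign key {tname!r}->{target!r} does not target the "
                               f"primary key of {target!r}")
                )
    return diags


def strip_connection(schema: RelationalSchema) -> RelationalSchema:
    """Copy of the schema without connection metadata (for comparisons)."""
    return replace(schema, connection=None)
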