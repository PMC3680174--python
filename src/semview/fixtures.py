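"""Synthetic databases and schemas for every pipeline stage.

Two generators, both seed-deterministic:

* :func:`build_gcp_fixture` — a seven-table crop-study schema wired as the
  worked example: a ``study`` specialised (PK=FK) into ``genotypingstudy``
  and ``phenotypingstudy``, germplasms reached from the genotyping side
  through DNA samples and a binary association table, and from the
  phenotyping side through a second binary association table.  Row
  population controls how many germplasms are reachable via both branches
  (``overlap_fraction``), so expected result sets are hand-countable.
* :func:`random_schema` — randomized connected schemas (FKs, association
  tables, PK=FK subclass links) with populated rows, for property tests.

Synthetic values are readable slugs (``study_001``, ``germplasm_017``).
Annotations ship as a manifest applied through :func:`semview.registry.annotate`,
keeping the manual-annotation stage an explicit step.
"""

from __future__ import annotations

import os
import random
import sqlite3
import tempfile
from dataclasses import dataclass, field

from .enrichment import enrich_view
from .errors import SemviewError
from .rdf_view import MappingDocument, build_rdf_view
from .registry import ConceptTerm, annotate
from .schema_model import (
    ColumnRef,
    ConnectionMeta,
    RelationalSchema,
    introspect_schema,
)

GCPDM_NS = "http://semview.org/ontologies/gcpdm#"
DEMO_NS = "http://semview.org/ontologies/demo#"

STUDY_TERM = ConceptTerm("gcpdm", "study", GCPDM_NS + "study")
GERMPLASM_TERM = ConceptTerm("gcpdm", "germplasm", GCPDM_NS + "germplasm")

DEFAULT_ROW_COUNTS = {"study": 3, "germplasm": 5}


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 0
    row_counts: dict = field(default_factory=lambda: dict(DEFAULT_ROW_COUNTS))
    overlap_fraction: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise SemviewError("overlap_fraction must be in [0, 1]")
        if any(v < 0 for v in self.row_counts.values()):
            raise SemviewError("row counts must be >= 0")


@dataclass
class GcpFixture:
    db_path: str
    connection: ConnectionMeta
    schema: RelationalSchema
    annotations: list[tuple[ColumnRef, ConceptTerm]]
    #: germplasm ids reachable per branch (same for every study)
    genotyping_germplasms: tuple[int, ...]
    phenotyping_germplasms: tuple[int, ...]


_GCP_DDL = """
CREATE TABLE study (
    id INTEGER PRIMARY KEY,
    study_name TEXT
);
CREATE TABLE germplasm (
    id INTEGER PRIMARY KEY,
    germplasm_name TEXT
);
CREATE TABLE genotypingstudy (
    id_study INTEGER PRIMARY KEY,
    FOREIGN KEY (id_study) REFERENCES study (id)
);
CREATE TABLE phenotypingstudy (
    id_study INTEGER PRIMARY KEY,
    FOREIGN KEY (id_study) REFERENCES study (id)
);
CREATE TABLE dnasample (
    id INTEGER PRIMARY KEY,
    sample_name TEXT,
    id_germplasm INTEGER,
    FOREIGN KEY (id_germplasm) REFERENCES germplasm (id)
);
CREATE TABLE dnasamplegenotypingstudy (
    id_genotypingstudy INTEGER,
    id_dnasample INTEGER,
    PRIMARY KEY (id_genotypingstudy, id_dnasample),
    FOREIGN KEY (id_genotypingstudy) REFERENCES genotypingstudy (id_study),
    FOREIGN KEY (id_dnasample) REFERENCES dnasample (id)
);
CREATE TABLE germplasmphenotypingstudy (
    id_phenotypingstudy INTEGER,
    id_germplasm INTEGER,
    PRIMARY KEY (id_phenotypingstudy, id_germplasm),
    FOREIGN KEY (id_phenotypingstudy) REFERENCES phenotypingstudy (id_study),
    FOREIGN KEY (id_germplasm) REFERENCES germplasm (id)
);
"""


def build_gcp_fixture(spec: FixtureSpec = FixtureSpec(),
                      directory: str | None = None) -> GcpFixture:
    """Create and populate the worked-example database.

    Every study has both a genotyping and a phenotyping specialisation.
    Germplasms are partitioned by ``overlap_fraction``: a fraction is
    reachable through both branches, the remainder is split between the
    genotyping-only and phenotyping-only sides.
    """
    directory = directory or tempfile.mkdtemp(prefix="semview-gcp-")
    os.makedirs(directory, exist_ok=True)
    db_path = os.path.join(directory, "gcp.sqlite")
    if os.path.exists(db_path):
        os.remove(db_path)
    rng = random.Random(spec.seed)
    n_study = spec.row_counts.get("study", DEFAULT_ROW_COUNTS["study"])
    n_germ = spec.row_counts.get("germplasm", DEFAULT_ROW_COUNTS["germplasm"])

    germ_ids = list(range(1, n_germ + 1))
    rng.shuffle(germ_ids)
    n_both = round(spec.overlap_fraction * n_germ)
    both, rest = germ_ids[:n_both], germ_ids[n_both:]
    geno_only = rest[: (len(rest) + 1) // 2]
    pheno_only = rest[(len(rest) + 1) // 2:]
    geno = tuple(sorted(both + geno_only))
    pheno = tuple(sorted(both + pheno_only))

    con = sqlite3.connect(db_path)
    try:
        con.executescript(_GCP_DDL)
        for s in range(1, n_study + 1):
            con.execute("INSERT INTO study VALUES (?, ?)", (s, f"study_{s:03d}"))
            con.execute("INSERT INTO genotypingstudy VALUES (?)", (s,))
            con.execute("INSERT INTO phenotypingstudy VALUES (?)", (s,))
        for g in range(1, n_germ + 1):
            con.execute("INSERT INTO germplasm VALUES (?, ?)", (g, f"germplasm_{g:03d}"))
            con.execute("INSERT INTO dnasample VALUES (?, ?, ?)", (g, f"sample_{g:03d}", g))
        for s in range(1, n_study + 1):
            for g in geno:
                con.execute("INSERT INTO dnasamplegenotypingstudy VALUES (?, ?)", (s, g))
            for g in pheno:
                con.execute("INSERT INTO germplasmphenotypingstudy VALUES (?, ?)", (s, g))
        con.commit()
    finally:
        con.close()

    connection = ConnectionMeta("sqlite", f"sqlite:///{db_path}")
    schema = introspect_schema(connection, name="gcp")
    annotations = [
        (ColumnRef("study", "study_name"), STUDY_TERM),
        (ColumnRef("germplasm", "germplasm_name"), GERMPLASM_TERM),
    ]
    return GcpFixture(db_path, connection, schema, annotations, geno, pheno)


def build_gcp_view(spec: FixtureSpec = FixtureSpec(),
                   directory: str | None = None) -> tuple[MappingDocument, GcpFixture]:
    """Fixture plus its fully prepared (built, enriched, annotated) view."""
    fixture = build_gcp_fixture(spec, directory)
    doc = build_rdf_view(fixture.schema)
    enrich_view(doc, fixture.schema)
    for column, term in fixture.annotations:
        annotate(doc, column, term)
    return doc, fixture


# ---------------------------------------------------------------------------
# Randomized schemas
# ---------------------------------------------------------------------------

def random_schema(seed: int, n_tables: int, p_association: float = 0.3,
                  p_subclass: float = 0.3, directory: str | None = None,
                  ) -> tuple[RelationalSchema, str]:
    """Seed-deterministic connected random schema with populated rows.

    Table 1 is a root entity; each further table is, with the given
    probabilities, an association table linking two earlier entity tables,
    a PK=FK subclass child of an earlier entity table, or a plain entity
    with a FK to one.  Returns the introspected schema and the database
    path.
    """
    if not 1 <= n_tables <= 15:
        raise SemviewError("n_tables must be between 1 and 15")
    if not (0.0 <= p_association <= 1.0 and 0.0 <= p_subclass <= 1.0):
        raise SemviewError("probabilities must be in [0, 1]")
    rng = random.Random(seed)
    directory = directory or tempfile.mkdtemp(prefix="semview-rand-")
    os.makedirs(directory, exist_ok=True)
    db_path = os.path.join(directory, f"rand_{seed}_{n_tables}.sqlite")
    if os.path.exists(db_path):
        os.remove(db_path)

    con = sqlite3.connect(db_path)
    entity_tables: list[str] = []  # non-association tables
    pk_column: dict[str, str] = {}
    pk_values: dict[str, list[int]] = {}
    try:
        for i in range(1, n_tables + 1):
            tname = f"t{i:02d}"
            roll = rng.random()
            if i >= 3 and roll < p_association:
                a, b = rng.sample(entity_tables, 2)
                ca, cb = f"id_{a}", f"id_{b}"
                con.execute(
                    f"CREATE TABLE {tname} ({ca} INTEGER, {cb} INTEGER, "
                    f"PRIMARY KEY ({ca}, {cb}), "
                    f"FOREIGN KEY ({ca}) REFERENCES {a} ({pk_column[a]}), "
                    f"FOREIGN KEY ({cb}) REFERENCES {b} ({pk_column[b]}))"
                )
                pairs = set()
                for _ in range(rng.randint(2, 6)):
                    if pk_values[a] and pk_values[b]:
                        pairs.add((rng.choice(pk_values[a]), rng.choice(pk_values[b])))
                for pa, pb in sorted(pairs):
                    con.execute(f"INSERT INTO {tname} VALUES (?, ?)", (pa, pb))
            elif i >= 2 and roll < p_association + p_subclass:
                parent = rng.choice(entity_tables)
                col = f"id_{parent}"
                con.execute(
                    f"CREATE TABLE {tname} ({col} INTEGER PRIMARY KEY, "
                    f"{tname}_name TEXT, "
                    f"FOREIGN KEY ({col}) REFERENCES {parent} ({pk_column[parent]}))"
                )
                ids = sorted(rng.sample(pk_values[parent],
                                        rng.randint(1, len(pk_values[parent])))) \
                    if pk_values[parent] else []
                for v in ids:
                    con.execute(f"INSERT INTO {tname} VALUES (?, ?)", (v, f"{tname}_{v:03d}"))
                entity_tables.append(tname)
                pk_column[tname] = col
                pk_values[tname] = ids
            else:
                cols = ["id INTEGER PRIMARY KEY", f"{tname}_name TEXT"]
                fk_clause = ""
                fk_target = None
                if i >= 2:
                    fk_target = rng.choice(entity_tables)
                    cols.append(f"id_{fk_target} INTEGER")
                    fk_clause = (f", FOREIGN KEY (id_{fk_target}) "
                                 f"REFERENCES {fk_target} ({pk_column[fk_target]})")
                con.execute(f"CREATE TABLE {tname} ({', '.join(cols)}{fk_clause})")
                n_rows = rng.randint(2, 6)
                ids = list(range(1, n_rows + 1))
                for v in ids:
                    if fk_target is not None:
                        ref = rng.choice(pk_values[fk_target]) if pk_values[fk_target] else None
                        con.execute(f"INSERT INTO {tname} VALUES (?, ?, ?)",
                                    (v, f"{tname}_{v:03d}", ref))
                    else:
                        con.execute(f"INSERT INTO {tname} VALUES (?, ?)",
                                    (v, f"{tname}_{v:03d}"))
                entity_tables.append(tname)
                pk_column[tname] = "id"
                pk_values[tname] = ids
        con.commit()
    finally:
        con.close()

    connection = ConnectionMeta("sqlite", f"sqlite:///{db_path}")
    schema = introspect_schema(connection, name=f"rand_{seed}_{n_tables}")
    return schema, db_path


def random_annotated_case(seed: int, n_tables: int = 8, p_association: float = 0.3,
                          p_subclass: float = 0.3, directory: str | None = None):
    """Random schema plus a prepared view annotated on two entity tables.

    Returns ``(doc, schema, db_path, input_term, output_term)`` where the
    two terms anchor the name columns of two distinct non-association
    tables (or ``None`` terms when the schema has fewer than two).
    """
    schema, db_path = random_schema(seed, n_tables, p_association, p_subclass, directory)
    doc = build_rdf_view(schema)
    enrich_view(doc, schema)
    rng = random.Random(seed + 10_000)
    from .enrichment import detect_association_tables

    association = {f.table for f in detect_association_tables(schema)}
    candidates = sorted(
        t for t in schema.tables
        if t not in association and any(c.name == f"{t}_name" for c in schema.tables[t].columns)
    )
    if len(candidates) < 2:
        return doc, schema, db_path, None, None
    t_in, t_out = rng.sample(candidates, 2)
    in_term = ConceptTerm("demo", "input_concept", DEMO_NS + "input_concept")
    out_term = ConceptTerm("demo", "output_concept", DEMO_NS + "output_concept")
    annotate(doc, ColumnRef(t_in, f"{t_in}_name"), in_term)
    annotate(doc, ColumnRef(t_out, f"{t_out}_name"), out_term)
    return doc, schema, db_path, in_term, out_term


def write_manifest(annotations: list[tuple[ColumnRef, ConceptTerm]], path: str) -> None:
    """Annotation manifest: TSV of column, CURIE, URI."""
    with open(path, "w", encoding="utf-8") as fh:
        for column, term in annotations:
            fh.write(f"{column}\t{term.curie}\t{term.uri}\n")


def read_manifest(path: str) -> list[tuple[ColumnRef, ConceptTerm]]:
    out = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            col_text, curie, uri = line.split("\t")
            prefix, _, local = curie.partition(":")
            out.append((ColumnRef.parse(col_text), ConceptTerm(prefix, local, uri)))
    return out
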