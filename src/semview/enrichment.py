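"""Semantic enrichment: association tables, arity, subclass relationships.

The mapping document produced from a bare schema only knows about tables,
columns and keys.  This stage classifies the *relationships* the schema
encodes and writes them into the view so that the path search can treat
them differently:

* **Association tables** link other tables.  A table qualifies iff it has
  at least two foreign keys and every one of its columns belongs to a
  foreign key or to the primary key (a single surrogate PK column is
  tolerated).  The arity of an association table is its foreign-key count.
* **Subclass relationships** arise from object-model inheritance mapped
  one-table-per-class (child PK columns coincide with its FK to the
  parent) and from identifying aggregation/composition relationships (the
  FK columns are a proper subset of the child PK).  Both are labelled with
  the same ``rdf:subClassOf`` property; the finding records which rule
  fired.  Association tables are never subclass children.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ConsistencyError
from .rdf_view import EnrichmentLabel, MappingDocument
from .schema_model import RelationalSchema


@dataclass(frozen=True)
class AssociationFinding:
    table: str
    arity: int
    member_tables: tuple[str, ...]  # FK target tables, one per FK

    def __post_init__(self):
        if self.arity < 2 or len(self.member_tables) != self.arity:
            raise ValueError("arity must equal the number of member tables (>= 2)")


@dataclass(frozen=True)
class SubclassFinding:
    child: str
    parent: str
    origin: str  # "inheritance" | "identifying"


def detect_association_tables(schema: RelationalSchema) -> list[AssociationFinding]:
    """Return every table satisfying the association-table rule, name-sorted."""
    findings = []
    for tname in sorted(schema.tables):
        table = schema.tables[tname]
        fks = table.foreign_keys
        if len(fks) < 2:
            continue
        fk_cols = {ref.column for fk in fks for ref in fk.source_columns}
        pk_cols = set(table.primary_key)
        if all(c.name in fk_cols or c.name in pk_cols for c in table.columns):
            findings.append(
                AssociationFinding(tname, len(fks), tuple(fk.target_table for fk in fks))
            )
    return findings


def detect_subclass_relationships(schema: RelationalSchema) -> list[SubclassFinding]:
    """Structural subclass detection (PK=FK or FK⊊PK), association tables excluded."""
    association = {f.table for f in detect_association_tables(schema)}
    findings = []
    for tname in sorted(schema.tables):
        if tname in association:
            continue
        table = schema.tables[tname]
        pk = set(table.primary_key)
        if not pk:
            continue
        for fk in table.foreign_keys:
            parent = fk.target_table
            if parent == tname:
                continue
            if parent in schema.tables and not schema.tables[parent].primary_key:
                continue  # PK-less tables are ineligible as parents
            fk_cols = {ref.column for ref in fk.source_columns}
            if fk_cols == pk:
                findings.append(SubclassFinding(tname, parent, "inheritance"))
            elif fk_cols < pk:
                findings.append(SubclassFinding(tname, parent, "identifying"))
    findings.sort(key=lambda f: (f.child, f.parent, f.origin))
    return findings


def enrich_view(doc: MappingDocument, schema: RelationalSchema) -> MappingDocument:
    """Write association/arity/subclass labels into the view (idempotent).

    The document must have been built from ``schema``: the table sets must
    coincide, otherwise a :class:`ConsistencyError` is raised.
    """
    doc_tables = set(doc.class_maps)
    schema_tables = set(schema.tables)
    if doc_tables != schema_tables:
        missing = sorted(schema_tables - doc_tables)
        extra = sorted(doc_tables - schema_tables)
        raise ConsistencyError(
            f"view/schema table mismatch (view missing {missing}, view extra {extra})"
        )
    labels = set(doc.enrichment_labels)
    for finding in detect_association_tables(schema):
        subject = doc.class_map_for(finding.table).uri
        labels.add(EnrichmentLabel(subject, "arity", finding.arity))
        for member in finding.member_tables:
            labels.add(
                EnrichmentLabel(subject, "associatedTo", doc.class_map_for(member).uri)
            )
    for finding in detect_subclass_relationships(schema):
        labels.add(
            EnrichmentLabel(
                doc.class_map_for(finding.child).uri,
                "subClassOf",
                doc.class_map_for(finding.parent).uri,
            )
        )
    doc.enrichment_labels = sorted(labels, key=lambda l: (l.subject, l.kind, str(l.value)))
    return doc
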