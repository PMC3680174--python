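"""RDF view construction, canonical Turtle serialization and parsing.

The RDF view is a D2RQ-dialect mapping document: one ``d2rq:ClassMap`` per
table, one ``d2rq:PropertyBridge`` per column, connection metadata, and —
after enrichment — relationship labels (``dr:associatedTo``, ``dr:arity``,
``rdf:subClassOf``).  The view never contains data; it is a queryable
description of the schema that later stages turn into SPARQL and SQL.

Serialization is canonical and byte-stable: prefixes sorted, class maps
sorted by table name, each followed by its bridges sorted by column name.
Parsing goes through rdflib's Turtle parser, so any syntactically valid
Turtle mapping (including externally produced D2RQ files) is accepted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import rdflib

from .errors import SerializationError, ViewError, ViewParseError
from .schema_model import ColumnRef, ConnectionMeta, RelationalSchema, validate_schema

#: Vocabulary namespaces.  ``d2rq:`` is the D2RQ mapping language; ``dr:`` is
#: this project's relationship vocabulary (the enrichment labels); ``rdf:``
#: is the standard RDF namespace (the subclass label is written
#: ``rdf:subClassOf`` in the mapping dialect).
D2RQ_NS = "http://www.wiwiss.fu-berlin.de/suhl/bizer/D2RQ/0.1#"
DR_NS = "http://semview.org/relationships#"
RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
DEFAULT_BASE_URI = "http://semview.org/views/"


def expand_curie(curie: str, namespaces: dict[str, str]) -> str:
    """CURIE → full URI using the document's prefix map."""
    if curie.startswith("<") and curie.endswith(">"):
        return curie[1:-1]
    prefix, sep, local = curie.partition(":")
    if not sep or prefix not in namespaces:
        raise SerializationError(f"unresolvable prefix in {curie!r}")
    return namespaces[prefix] + local


def compact_uri(uri: str, namespaces: dict[str, str]) -> str:
    """Full URI → CURIE under the longest matching namespace, else ``<uri>``."""
    best = None
    for prefix, ns in namespaces.items():
        if uri.startswith(ns) and (best is None or len(ns) > len(namespaces[best])):
            best = prefix
    if best is None:
        return f"<{uri}>"
    return f"{best}:{uri[len(namespaces[best]):]}"


@dataclass(frozen=True)
class Join:
    """FK join condition: ordered (source, target) column pairs."""

    pairs: tuple[tuple[ColumnRef, ColumnRef], ...]

    @property
    def source_table(self) -> str:
        return self.pairs[0][0].table

    @property
    def target_table(self) -> str:
        return self.pairs[0][1].table


@dataclass
class ClassMap:
    """Maps one table to an RDF class (``map:{table}``)."""

    uri: str
    table: str
    primary_key: tuple[str, ...]


@dataclass
class PropertyBridge:
    """Maps one column to an RDF property (``map:{table}_{column}``).

    FK columns carry a ``join`` plus a structural ``predicate``
    (``vocab:{table}_{column}``); annotation terms land in
    ``property_terms`` (kept sorted for canonical output).
    """

    uri: str
    column: ColumnRef
    class_map: str
    property_terms: list[str] = field(default_factory=list)
    predicate: str | None = None
    join: Join | None = None
    refers_to: str | None = None


@dataclass(frozen=True)
class EnrichmentLabel:
    """One enrichment triple on a ClassMap subject."""

    subject: str  # ClassMap curie
    kind: str  # "associatedTo" | "arity" | "subClassOf"
    value: str | int

    def __post_init__(self):
        if self.kind == "arity":
            if not isinstance(self.value, int) or self.value < 2:
                raise ViewError("arity labels require an integer value >= 2")
        elif self.kind == "subClassOf":
            if self.subject == self.value:
                raise ViewError("subClassOf label with subject == value")
        elif self.kind != "associatedTo":
            raise ViewError(f"unknown enrichment label kind {self.kind!r}")


@dataclass
class MappingDocument:
    view_name: str
    namespaces: dict[str, str]
    class_maps: dict[str, ClassMap]  # table name -> ClassMap
    property_bridges: dict[str, PropertyBridge]  # bridge curie -> bridge
    enrichment_labels: list[EnrichmentLabel] = field(default_factory=list)
    connection: ConnectionMeta | None = None

    def class_map_for(self, table: str) -> ClassMap:
        try:
            return self.class_maps[table]
        except KeyError:
            raise ViewError(f"no ClassMap for table {table!r}") from None

    def bridge_for(self, column: ColumnRef) -> PropertyBridge:
        for bridge in self.property_bridges.values():
            if bridge.column == column:
                return bridge
        raise ViewError(f"no PropertyBridge for column {column}")

    def bridges_of(self, table: str) -> list[PropertyBridge]:
        return sorted(
            (b for b in self.property_bridges.values() if b.column.table == table),
            key=lambda b: b.column.column,
        )

    def table_of_class_map(self, curie: str) -> str:
        for table, cm in self.class_maps.items():
            if cm.uri == curie:
                return table
        raise ViewError(f"no table for ClassMap {curie!r}")


# ---------------------------------------------------------------------------
# Building
# ---------------------------------------------------------------------------

def build_rdf_view(schema: RelationalSchema, base_uri: str = DEFAULT_BASE_URI) -> MappingDocument:
    """Create the (un-enriched) mapping document for a schema.

    Naming: class map ``map:{table}``; bridge ``map:{table}_{column}``; FK
    bridges get the structural predicate ``vocab:{table}_{fk_column}`` and a
    join condition.  Enrichment labels are added by a separate, later stage.
    """
    errors = [d for d in validate_schema(schema) if d.severity == "error"]
    if errors:
        raise ViewError(
            "schema is invalid: " + "; ".join(d.message for d in errors)
        )
    if not base_uri.endswith("/"):
        base_uri += "/"
    namespaces = {
        "d2rq": D2RQ_NS,
        "dr": DR_NS,
        "map": f"{base_uri}{schema.name}/map#",
        "rdf": RDF_NS,
        "vocab": f"{base_uri}{schema.name}/vocab#",
    }
    class_maps: dict[str, ClassMap] = {}
    bridges: dict[str, PropertyBridge] = {}
    for tname in sorted(schema.tables):
        table = schema.tables[tname]
        class_maps[tname] = ClassMap(f"map:{tname}", tname, table.primary_key)
        # one FK bridge per foreign key, attached to its first source column
        fk_by_first_col = {}
        for fk in table.foreign_keys:
            fk_by_first_col.setdefault(fk.source_columns[0].column, fk)
        for col in table.columns:
            uri = f"map:{tname}_{col.name}"
            ref = ColumnRef(tname, col.name)
            fk = fk_by_first_col.get(col.name)
            if fk is not None:
                bridges[uri] = PropertyBridge(
                    uri, ref, f"map:{tname}",
                    predicate=f"vocab:{tname}_{col.name}",
                    join=Join(tuple(sorted(zip(fk.source_columns, fk.target_columns),
                                           key=lambda p: str(p[0])))),
                    refers_to=f"map:{fk.target_table}",
                )
            else:
                bridges[uri] = PropertyBridge(uri, ref, f"map:{tname}")
    return MappingDocument(
        view_name=schema.name,
        namespaces=namespaces,
        class_maps=class_maps,
        property_bridges=bridges,
        enrichment_labels=[],
        connection=schema.connection,
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _check_resolvable(curie: str, namespaces: dict[str, str]) -> str:
    expand_curie(curie, namespaces)  # raises SerializationError if not
    return curie


def serialize_rdf_view(doc: MappingDocument) -> str:
    """Render the document as canonical Turtle (byte-stable)."""
    ns = doc.namespaces
    lines: list[str] = []
    for prefix in sorted(ns):
        lines.append(f"@prefix {prefix}: <{ns[prefix]}> .")
    lines.append("")

    def block(subject: str, pairs: list[tuple[str, str]]):
        lines.append(f"{_check_resolvable(subject, ns)} {pairs[0][0]} {pairs[0][1]};")
        for pred, obj in pairs[1:]:
            lines.append(f"    {pred} {obj};")
        lines.append("    .")
        lines.append("")

    block("map:view", [("a", "dr:View"), ("dr:name", _quote(doc.view_name))])
    if doc.connection is not None:
        pairs = [
            ("a", "d2rq:Database"),
            ("d2rq:jdbcDSN", _quote(doc.connection.uri)),
            ("d2rq:jdbcDriver", _quote(doc.connection.engine)),
        ]
        if doc.connection.credentials:
            user, password = doc.connection.credentials
            pairs.append(("d2rq:username", _quote(user)))
            pairs.append(("d2rq:password", _quote(password)))
        block("map:database", pairs)

    labels_by_subject: dict[str, list[EnrichmentLabel]] = {}
    for label in doc.enrichment_labels:
        labels_by_subject.setdefault(label.subject, []).append(label)

    for tname in sorted(doc.class_maps):
        cm = doc.class_maps[tname]
        pairs = [("a", "d2rq:ClassMap")]
        if cm.primary_key:
            pk = ",".join(f"{tname}.{c}" for c in cm.primary_key)
            pairs.append(("d2rq:primaryKey", _quote(pk)))
        for label in sorted(
            labels_by_subject.get(cm.uri, []), key=lambda l: (l.kind, str(l.value))
        ):
            if label.kind == "associatedTo":
                pairs.append(("dr:associatedTo", _check_resolvable(str(label.value), ns)))
            elif label.kind == "arity":
                pairs.append(("dr:arity", str(label.value)))
            else:
                pairs.append(("rdf:subClassOf", _check_resolvable(str(label.value), ns)))
        block(cm.uri, pairs)
        for bridge in doc.bridges_of(tname):
            pairs = [
                ("a", "d2rq:PropertyBridge"),
                ("d2rq:column", _quote(str(bridge.column))),
            ]
            if bridge.predicate:
                pairs.append(("d2rq:property", _check_resolvable(bridge.predicate, ns)))
            for term in sorted(bridge.property_terms):
                pairs.append(("d2rq:property", _check_resolvable(term, ns)))
            if bridge.refers_to:
                pairs.append(("d2rq:refersToClassMap", _check_resolvable(bridge.refers_to, ns)))
            if bridge.join:
                for src, dst in sorted(bridge.join.pairs, key=lambda p: str(p[0])):
                    pairs.append(("d2rq:join", _quote(f"{src} => {dst}")))
            pairs.append(("d2rq:belongsToClassMap", _check_resolvable(bridge.class_map, ns)))
            block(bridge.uri, pairs)
    return "\n".join(lines)


def _quote(text: str) -> str:
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"') + '"'


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_PREFIX_RE = re.compile(
    r"^\s*(?:@prefix|PREFIX)\s+([A-Za-z][\w.-]*)?:\s*<([^>]*)>", re.MULTILINE
)


def parse_rdf_view(text: str, view_name: str | None = None) -> MappingDocument:
    """Parse Turtle text into a :class:`MappingDocument`.

    Externally produced D2RQ mappings (without ``dr:`` labels or a view-name
    triple) are accepted; missing pieces default sensibly.  A document with
    no ClassMap at all is rejected as structurally invalid.
    """
    graph = rdflib.Graph()
    try:
        graph.parse(data=text, format="turtle")
    except Exception as exc:
        raise ViewParseError(f"Turtle syntax error: {exc}") from exc

    namespaces = {m.group(1) or "": m.group(2) for m in _PREFIX_RE.finditer(text)}
    namespaces.pop("", None)
    namespaces.setdefault("d2rq", D2RQ_NS)
    namespaces.setdefault("dr", DR_NS)
    namespaces.setdefault("rdf", RDF_NS)

    d2rq = rdflib.Namespace(D2RQ_NS)
    dr = rdflib.Namespace(DR_NS)
    rdfns = rdflib.Namespace(RDF_NS)

    def cc(uri) -> str:
        return compact_uri(str(uri), namespaces)

    # view name and connection
    name = view_name
    for s in graph.subjects(rdflib.RDF.type, dr.View):
        for o in graph.objects(s, dr.name):
            name = str(o)
    connection = None
    for s in graph.subjects(rdflib.RDF.type, d2rq.Database):
        uri = next((str(o) for o in graph.objects(s, d2rq.jdbcDSN)), None)
        engine = next((str(o) for o in graph.objects(s, d2rq.jdbcDriver)), "sqlite")
        user = next((str(o) for o in graph.objects(s, d2rq.username)), None)
        password = next((str(o) for o in graph.objects(s, d2rq.password)), None)
        if uri:
            creds = (user, password) if user is not None else None
            connection = ConnectionMeta(engine, uri, creds)

    class_maps: dict[str, ClassMap] = {}
    cm_uri_to_table: dict[str, str] = {}
    for s in sorted(graph.subjects(rdflib.RDF.type, d2rq.ClassMap), key=str):
        curie = cc(s)
        pk_literal = next((str(o) for o in graph.objects(s, d2rq.primaryKey)), None)
        if pk_literal:
            refs = [ColumnRef.parse(p.strip()) for p in pk_literal.split(",")]
            table = refs[0].table
            pk = tuple(r.column for r in refs)
        else:
            table = curie.partition(":")[2] or str(s)
            pk = ()
        class_maps[table] = ClassMap(curie, table, pk)
        cm_uri_to_table[curie] = table
    if not class_maps:
        raise ViewParseError("document contains no d2rq:ClassMap")

    vocab_ns = namespaces.get("vocab")
    bridges: dict[str, PropertyBridge] = {}
    for s in sorted(graph.subjects(rdflib.RDF.type, d2rq.PropertyBridge), key=str):
        curie = cc(s)
        col_literal = next((str(o) for o in graph.objects(s, d2rq.column)), None)
        if col_literal is None:
            continue  # bridges without a column are outside the dialect
        column = ColumnRef.parse(col_literal)
        belongs = next((cc(o) for o in graph.objects(s, d2rq.belongsToClassMap)), None)
        if belongs is None:
            belongs = class_maps.get(column.table, ClassMap(f"map:{column.table}", column.table, ())).uri
        predicate = None
        terms: list[str] = []
        for o in graph.objects(s, getattr(d2rq, "property")):
            ouri = str(o)
            if vocab_ns and ouri.startswith(vocab_ns):
                predicate = cc(o)
            else:
                terms.append(cc(o))
        refers = next((cc(o) for o in graph.objects(s, d2rq.refersToClassMap)), None)
        join_pairs = []
        for o in graph.objects(s, d2rq["join"]):  # .join would hit str.join
            left, _, right = str(o).partition("=>")
            join_pairs.append((ColumnRef.parse(left.strip()), ColumnRef.parse(right.strip())))
        join = Join(tuple(sorted(join_pairs, key=lambda p: str(p[0])))) if join_pairs else None
        bridges[curie] = PropertyBridge(
            curie, column, belongs, sorted(terms), predicate, join, refers
        )

    labels: list[EnrichmentLabel] = []
    for table, cm in class_maps.items():
        subject = rdflib.URIRef(expand_curie(cm.uri, namespaces))
        for o in graph.objects(subject, dr.associatedTo):
            labels.append(EnrichmentLabel(cm.uri, "associatedTo", cc(o)))
        for o in graph.objects(subject, dr.arity):
            labels.append(EnrichmentLabel(cm.uri, "arity", int(o)))
        for o in graph.objects(subject, rdfns.subClassOf):
            labels.append(EnrichmentLabel(cm.uri, "subClassOf", cc(o)))
    labels.sort(key=lambda l: (l.subject, l.kind, str(l.value)))

    return MappingDocument(
        view_name=name or "view",
        namespaces=namespaces,
        class_maps=dict(sorted(class_maps.items())),
        property_bridges=bridges,
        enrichment_labels=labels,
        connection=connection,
    )
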