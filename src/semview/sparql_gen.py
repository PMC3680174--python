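"""SPARQL SELECT synthesis from an aggregated query path.

The query shape is fixed: ``SELECT DISTINCT`` over exactly two variables
(input then output), the input anchor triple, a ``FILTER regex`` on the
input variable as the third line, then one block of triple patterns per
path branch, UNION-joined when there is more than one branch.

Variable naming is canonical: ``?{table}_id`` for table instances,
``?{concept}_name`` for the two anchored literals and a fresh ``?key{n}``
per association hop (each block gets fresh key variables; under UNION this
is semantically equivalent to reusing one ``?key`` name across blocks).

A pattern without regex metacharacters is treated as a literal and
anchored (``^…$``); anything else passes through as a raw regex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import AnchorError, FilterError, SemviewError
from .pathfinder import QueryPath
from .rdf_view import MappingDocument, expand_curie
from .schema_model import ColumnRef

_REGEX_METACHARACTERS = set(".^$*+?{}[]()|\\")


def is_literal_pattern(pattern: str) -> bool:
    return not any(ch in _REGEX_METACHARACTERS for ch in pattern)


@dataclass(frozen=True)
class TriplePattern:
    subject: str
    predicate: str
    object: str

    def __post_init__(self):
        if not self.subject.startswith("?") or not self.object.startswith("?"):
            raise SemviewError("triple pattern variables must start with '?'")

    def render(self) -> str:
        return f"{self.subject} {self.predicate} {self.object}."


@dataclass
class SparqlQuery:
    select_vars: list[str]  # [input var, output var]
    filter_var: str
    input_pattern: str  # raw user pattern
    filter_regex: str  # anchored literal or passthrough regex
    shared_prefix: list[TriplePattern]
    union_blocks: list[list[TriplePattern]]
    namespaces: dict[str, str]
    input_anchor: ColumnRef
    output_anchor: ColumnRef
    input_term: str  # CURIE
    output_term: str  # CURIE
    extra_clauses: list[str] = field(default_factory=list)
    text: str = ""

    @property
    def is_literal_filter(self) -> bool:
        return self.filter_regex.startswith("^") and self.filter_regex.endswith("$") \
            and is_literal_pattern(self.filter_regex[1:-1])


def generate_sparql(path: QueryPath, doc: MappingDocument, input_pattern: str) -> SparqlQuery:
    """Build the unique SPARQL query for an aggregated path.

    Raises :class:`FilterError` on an empty pattern and
    :class:`AnchorError` if either anchor column lost its annotation.
    """
    if not input_pattern:
        raise FilterError("input filter pattern must be non-empty")
    in_uri, in_col = path.input
    out_uri, out_col = path.output
    in_curie = _anchor_curie(doc, in_col, in_uri, "input")
    out_curie = _anchor_curie(doc, out_col, out_uri, "output")

    in_var = f"?{in_curie.partition(':')[2]}_name"
    out_var = f"?{out_curie.partition(':')[2]}_name"
    if out_var == in_var:
        out_var = f"?{out_curie.partition(':')[2]}_out_name"

    shared = [TriplePattern(_instance_var(in_col.table), in_curie, in_var)]
    key_counter = 0
    blocks: list[list[TriplePattern]] = []
    for branch in path.branches:
        triples: list[TriplePattern] = []
        for i, hop in enumerate(branch.hops):
            cur, nxt = branch.nodes[i], branch.nodes[i + 1]
            if hop.kind in ("fk", "subclass"):
                triples.append(
                    TriplePattern(_instance_var(hop.u), hop.predicate, _instance_var(hop.v))
                )
            else:  # association
                key_counter += 1
                key = f"?key{key_counter}"
                half_cur = hop.half_u if hop.u == cur else hop.half_v
                half_nxt = hop.half_u if hop.u == nxt else hop.half_v
                triples.append(TriplePattern(key, half_cur.predicate, _instance_var(cur)))
                triples.append(TriplePattern(key, half_nxt.predicate, _instance_var(nxt)))
        triples.append(TriplePattern(_instance_var(out_col.table), out_curie, out_var))
        blocks.append(triples)

    filter_regex = f"^{input_pattern}$" if is_literal_pattern(input_pattern) else input_pattern
    used_prefixes = set()
    for tp in shared + [t for b in blocks for t in b]:
        prefix = tp.predicate.partition(":")[0]
        if prefix in doc.namespaces:
            used_prefixes.add(prefix)
    query = SparqlQuery(
        select_vars=[in_var, out_var],
        filter_var=in_var,
        input_pattern=input_pattern,
        filter_regex=filter_regex,
        shared_prefix=shared,
        union_blocks=blocks,
        namespaces={p: doc.namespaces[p] for p in sorted(used_prefixes)},
        input_anchor=in_col,
        output_anchor=out_col,
        input_term=in_curie,
        output_term=out_curie,
    )
    query.text = render(query)
    return query


def _instance_var(table: str) -> str:
    return f"?{table}_id"


def _anchor_curie(doc: MappingDocument, col: ColumnRef, term_uri: str, role: str) -> str:
    bridge = doc.bridge_for(col)
    for curie in bridge.property_terms:
        if expand_curie(curie, doc.namespaces) == term_uri:
            return curie
    raise AnchorError(f"{role} anchor column {col} lacks annotation {term_uri}")


def render(query: SparqlQuery) -> str:
    """Canonical text: one pattern per line, UNION between braced blocks.

    Rendering is byte-stable; the text carries PREFIX declarations so it
    parses standalone under the SPARQL 1.1 grammar.
    """
    if not query.union_blocks:
        raise SemviewError("query has no union blocks")
    lines = [f"PREFIX {p}: <{u}>" for p, u in sorted(query.namespaces.items())]
    lines.append(f"SELECT DISTINCT {query.select_vars[0]} {query.select_vars[1]} WHERE {{")
    for tp in query.shared_prefix:
        lines.append(tp.render())
    lines.append(f'FILTER regex({query.filter_var},"{query.filter_regex}").')
    if len(query.union_blocks) == 1:
        for tp in query.union_blocks[0]:
            lines.append(tp.render())
    else:
        for i, block in enumerate(query.union_blocks):
            lines.append("{" if i == 0 else "UNION {")
            for tp in block:
                lines.append(tp.render())
            lines.append("}")
    for clause in query.extra_clauses:
        lines.append(clause)
    lines.append("}")
    return "\n".join(lines) + "\n"
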