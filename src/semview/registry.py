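"""Ontology-term annotation and the repository of annotated views.

Annotation is the one manual step of the pipeline: a curator attaches
ontology-term URIs (EDAM, Trait Ontology, domain-model concepts, ...) to
individual columns of a view.  Terms are opaque URIs — no ontology file is
parsed and no term-hierarchy reasoning happens.

The registry stores annotated views (in memory, optionally persisted as a
directory of Turtle files, one ``<view_name>.ttl`` per view) and maintains
an inverted index term → (view, bridge) that concept-pair resolution uses.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

from .errors import AnnotationTargetError, SelfJoinError
from .rdf_view import (
    MappingDocument,
    expand_curie,
    parse_rdf_view,
    serialize_rdf_view,
)
from .schema_model import ColumnRef

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConceptTerm:
    """An ontology term as a CURIE plus its full URI."""

    prefix: str
    local: str
    uri: str

    def __post_init__(self):
        if not self.uri:
            raise ValueError("ConceptTerm.uri must be non-empty")

    @property
    def curie(self) -> str:
        return f"{self.prefix}:{self.local}"

    @classmethod
    def from_curie(cls, curie: str, namespaces: dict[str, str]) -> "ConceptTerm":
        prefix, _, local = curie.partition(":")
        return cls(prefix, local, expand_curie(curie, namespaces))


def annotate(doc: MappingDocument, target: ColumnRef, term: ConceptTerm) -> MappingDocument:
    """Attach ``term`` to the property bridge of ``target`` (idempotent).

    The term's prefix is registered in the document namespaces so that the
    annotation serializes as a resolvable CURIE (a ``d2rq:property`` line).
    Annotating a FK bridge is allowed but logged as a warning: the query
    synthesizer only anchors on literal (non-join) bridges.
    """
    try:
        bridge = doc.bridge_for(target)
    except Exception:
        raise AnnotationTargetError(f"no PropertyBridge for column {target}") from None
    if bridge.join is not None:
        logger.warning(
            "annotating FK bridge %s; query synthesis ignores join-bearing anchors",
            bridge.uri,
        )
    ns_base = term.uri[: len(term.uri) - len(term.local)]
    existing = doc.namespaces.get(term.prefix)
    if existing is None:
        doc.namespaces[term.prefix] = ns_base
    if term.curie not in bridge.property_terms:
        bridge.property_terms.append(term.curie)
        bridge.property_terms.sort()
    return doc


def annotations_of(doc: MappingDocument) -> list[tuple[ColumnRef, ConceptTerm]]:
    """All (column, term) annotations of a view, deterministically ordered."""
    out = []
    for uri in sorted(doc.property_bridges):
        bridge = doc.property_bridges[uri]
        for curie in bridge.property_terms:
            prefix, _, local = curie.partition(":")
            out.append(
                (bridge.column, ConceptTerm(prefix, local, expand_curie(curie, doc.namespaces)))
            )
    return out


@dataclass
class ViewRegistry:
    views: dict[str, MappingDocument] = field(default_factory=dict)
    #: term URI -> set of (view_name, bridge curie); rebuilt on every mutation
    index: dict[str, set[tuple[str, str]]] = field(default_factory=dict)

    def _rebuild_index(self) -> None:
        self.index = {}
        for view_name, doc in self.views.items():
            for column, term in annotations_of(doc):
                bridge = doc.bridge_for(column)
                self.index.setdefault(term.uri, set()).add((view_name, bridge.uri))


def register_view(reg: ViewRegistry, doc: MappingDocument) -> ViewRegistry:
    """Store (or replace) a view under its view_name; index is rebuilt."""
    reg.views[doc.view_name] = doc
    reg._rebuild_index()
    return reg


def _term_uri(reg: ViewRegistry, term: "ConceptTerm | str") -> str:
    if isinstance(term, ConceptTerm):
        return term.uri
    if ":" in term and not term.startswith(("http://", "https://")):
        # CURIE: resolve against any registered view's namespaces
        for doc in reg.views.values():
            try:
                return expand_curie(term, doc.namespaces)
            except Exception:
                continue
    return term


def find_views(
    reg: ViewRegistry, input_term: "ConceptTerm | str", output_term: "ConceptTerm | str"
) -> list[str]:
    """Views annotated with both concepts, name-sorted.

    Identical input and output concepts are rejected: the path search joins
    two distinct nodes, so self-join queries cannot be synthesized.
    """
    in_uri = _term_uri(reg, input_term)
    out_uri = _term_uri(reg, output_term)
    if in_uri == out_uri:
        raise SelfJoinError(
            f"input and output concept are identical ({in_uri}); self joins are unsupported"
        )
    having_in = {v for v, _ in reg.index.get(in_uri, set())}
    having_out = {v for v, _ in reg.index.get(out_uri, set())}
    return sorted(having_in & having_out)


def list_terms(reg: ViewRegistry) -> list[ConceptTerm]:
    """Deduplicated, sorted concept terms used across all registered views."""
    seen: dict[str, ConceptTerm] = {}
    for doc in reg.views.values():
        for _, term in annotations_of(doc):
            seen[term.uri] = term
    return sorted(seen.values(), key=lambda t: (t.curie, t.uri))


# ---------------------------------------------------------------------------
# Persistence: a directory of Turtle files
# ---------------------------------------------------------------------------

def save_registry(reg: ViewRegistry, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    for view_name in sorted(reg.views):
        path = os.path.join(directory, f"{view_name}.ttl")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(serialize_rdf_view(reg.views[view_name]))


def load_registry(directory: str) -> ViewRegistry:
    reg = ViewRegistry()
    if not os.path.isdir(directory):
        return reg
    for fname in sorted(os.listdir(directory)):
        if not fname.endswith(".ttl"):
            continue
        with open(os.path.join(directory, fname), encoding="utf-8") as fh:
            doc = parse_rdf_view(fh.read(), view_name=fname[:-4])
        register_view(reg, doc)
    return reg
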