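"""Weighted query graph and the shortest-path-with-conditions search.

The enriched view is read as an undirected weighted graph whose nodes are
the entity tables.  Edge types and default weights:

===============  ======================================  =======
kind             meaning                                 weight
===============  ======================================  =======
fk               plain foreign-key join                  10
association      hop through an arity-k association      10 + 5·(k−2)
                 table (the table itself is an edge,
                 not a node)
subclass         inheritance / identifying relationship  2
===============  ======================================  =======

Binary associations are therefore favoured over higher-arity ones, and
subclass hops are cheap so the search readily enters inheritance
hierarchies.  The search itself is a single-pair Dijkstra; ties between
equal-cost paths are broken by the lexicographically smallest node-URI
sequence.  After the primary (minimum-cost) branch is found, every
subclass hop on an accepted branch triggers probing of the sibling
children of the same parent; each sibling that still reaches the target
contributes an additional branch.  The aggregated branches become the
UNION blocks of the synthesized query.  Nothing is cached: paths are
recomputed from the view on every call.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from itertools import product

from .errors import AnchorError, NoPathError, SelfJoinError, SemviewError
from .rdf_view import MappingDocument, expand_curie
from .registry import ConceptTerm
from .schema_model import ColumnRef

WEIGHT_FK = 10
WEIGHT_SUBCLASS = 2
ASSOCIATION_BASE = 10
ASSOCIATION_ARITY_PENALTY = 5


def association_weight(arity: int) -> int:
    """10 for binary association tables, +5 per extra foreign key."""
    return ASSOCIATION_BASE + ASSOCIATION_ARITY_PENALTY * (arity - 2)


@dataclass(frozen=True)
class EdgeHalf:
    """One FK of an association table: predicate + (assoc col, member col) pairs."""

    predicate: str
    pairs: tuple[tuple[ColumnRef, ColumnRef], ...]

    @property
    def target_table(self) -> str:
        return self.pairs[0][1].table


@dataclass(frozen=True)
class Edge:
    kind: str  # "fk" | "association" | "subclass"
    u: str  # fk/subclass: child table
    v: str  # fk/subclass: parent (referenced) table
    weight: int
    predicate: str | None = None  # fk/subclass: vocab predicate of the child FK
    pairs: tuple[tuple[ColumnRef, ColumnRef], ...] = ()  # fk/subclass join pairs
    via: str | None = None  # association: the association table
    arity: int | None = None
    half_u: EdgeHalf | None = None  # association: FK half toward u
    half_v: EdgeHalf | None = None  # association: FK half toward v

    def other(self, node: str) -> str:
        return self.v if node == self.u else self.u

    def key(self) -> tuple:
        return (self.kind, self.u, self.v, self.via or "", self.predicate or "")


@dataclass
class QueryGraph:
    nodes: tuple[str, ...]
    edges: tuple[Edge, ...]
    anchors: dict[str, list[tuple[str, ColumnRef]]]  # term URI -> anchored columns
    doc: MappingDocument
    subclass_children: dict[str, list[str]]  # parent -> children

    def adjacent(self, node: str) -> list[Edge]:
        return self._adj.get(node, [])

    def __post_init__(self):
        adj: dict[str, list[Edge]] = {}
        for edge in self.edges:
            adj.setdefault(edge.u, []).append(edge)
            adj.setdefault(edge.v, []).append(edge)
        for lst in adj.values():
            lst.sort(key=lambda e: (e.weight,) + e.key())
        self._adj = adj

    def edge_between(self, a: str, b: str) -> Edge | None:
        """Cheapest edge joining a and b (deterministic among ties)."""
        for edge in self.adjacent(a):
            if edge.other(a) == b:
                return edge
        return None


@dataclass(frozen=True)
class PathBranch:
    nodes: tuple[str, ...]
    hops: tuple[Edge, ...]
    cost: int

    def rendered_nodes(self) -> tuple[str, ...]:
        """Node sequence with association via-tables re-expanded.

        This is the human-facing rendering: an association hop is shown as
        passing *through* its link table even though the graph models the
        table as an edge.
        """
        out = [self.nodes[0]]
        for i, hop in enumerate(self.hops):
            if hop.kind == "association" and hop.via:
                out.append(hop.via)
            out.append(self.nodes[i + 1])
        return tuple(out)

    def display(self, prefix: str = "map:") -> str:
        return " -> ".join(prefix + n for n in self.rendered_nodes())


@dataclass(frozen=True)
class QueryPath:
    input: tuple[str, ColumnRef]  # (term URI, anchored column)
    output: tuple[str, ColumnRef]
    branches: tuple[PathBranch, ...]

    @property
    def source(self) -> str:
        return self.branches[0].nodes[0]

    @property
    def target(self) -> str:
        return self.branches[0].nodes[-1]


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def build_query_graph(doc: MappingDocument) -> QueryGraph:
    """Derive the weighted query graph from an enriched mapping document."""
    arity_of: dict[str, int] = {}
    subclass_pairs: set[tuple[str, str]] = set()
    for label in doc.enrichment_labels:
        table = doc.table_of_class_map(label.subject)
        if label.kind == "arity":
            arity_of[table] = int(label.value)
        elif label.kind == "subClassOf":
            subclass_pairs.add((table, doc.table_of_class_map(str(label.value))))

    association_tables = set(arity_of)
    nodes = tuple(sorted(t for t in doc.class_maps if t not in association_tables))
    node_set = set(nodes)
    edges: list[Edge] = []

    # association edges: pairwise between the FK targets of each association table
    for atable in sorted(association_tables):
        halves = []
        for bridge in doc.bridges_of(atable):
            if bridge.join is not None and bridge.predicate is not None:
                halves.append(EdgeHalf(bridge.predicate, bridge.join.pairs))
        halves.sort(key=lambda h: h.predicate)
        arity = arity_of[atable]
        for i, j in ((i, j) for i in range(len(halves)) for j in range(i + 1, len(halves))):
            ta, tb = halves[i].target_table, halves[j].target_table
            if ta == tb or ta not in node_set or tb not in node_set:
                continue  # self-association or member outside the entity nodes
            u, v = sorted((ta, tb))
            hu, hv = (halves[i], halves[j]) if halves[i].target_table == u else (halves[j], halves[i])
            edges.append(
                Edge("association", u, v, association_weight(arity),
                     via=atable, arity=arity, half_u=hu, half_v=hv)
            )

    # fk and subclass edges from join-bearing bridges of entity tables
    subclass_made: set[tuple[str, str]] = set()
    for uri in sorted(doc.property_bridges):
        bridge = doc.property_bridges[uri]
        child = bridge.column.table
        if bridge.join is None or child in association_tables:
            continue
        parent = bridge.join.target_table
        if parent not in node_set or parent == child:
            continue
        if (child, parent) in subclass_pairs and (child, parent) not in subclass_made:
            kind, weight = "subclass", WEIGHT_SUBCLASS
            subclass_made.add((child, parent))
        else:
            kind, weight = "fk", WEIGHT_FK
        edges.append(
            Edge(kind, child, parent, weight,
                 predicate=bridge.predicate, pairs=bridge.join.pairs)
        )

    anchors: dict[str, list[tuple[str, ColumnRef]]] = {}
    for uri in sorted(doc.property_bridges):
        bridge = doc.property_bridges[uri]
        if bridge.join is not None or bridge.column.table not in node_set:
            continue
        for curie in bridge.property_terms:
            term_uri = expand_curie(curie, doc.namespaces)
            anchors.setdefault(term_uri, []).append((bridge.column.table, bridge.column))

    children: dict[str, list[str]] = {}
    for child, parent in sorted(subclass_pairs):
        children.setdefault(parent, []).append(child)
    return QueryGraph(nodes, tuple(edges), anchors, doc, children)


# ---------------------------------------------------------------------------
# Search primitives
# ---------------------------------------------------------------------------

def _dijkstra_cost(graph: QueryGraph, src: str, dst: str, avoid: frozenset = frozenset()):
    """Minimum path cost src→dst (None if unreachable), skipping ``avoid`` nodes."""
    if src == dst:
        return 0
    dist = {src: 0}
    heap = [(0, src)]
    while heap:
        d, node = heapq.heappop(heap)
        if node == dst:
            return d
        if d > dist.get(node, float("inf")):
            continue
        for edge in graph.adjacent(node):
            nxt = edge.other(node)
            if nxt in avoid:
                continue
            nd = d + edge.weight
            if nd < dist.get(nxt, float("inf")):
                dist[nxt] = nd
                heapq.heappush(heap, (nd, nxt))
    return None


def _lex_min_path(graph: QueryGraph, src: str, dst: str, bound: int,
                  avoid: frozenset = frozenset()):
    """Lexicographically smallest simple path of cost exactly ``bound``.

    Depth-first search in sorted-neighbour order emits node sequences in
    lexicographic order, so the first complete path that attains the
    minimum cost is the canonical one.  Branches whose running cost
    exceeds the bound are pruned (all weights are positive).
    """
    if src == dst:
        return (src,), ()
    path = [src]
    hops: list[Edge] = []
    on_path = {src}

    def dfs_lex(node: str, cost: int):
        if node == dst:
            return cost == bound
        neighbors: dict[str, list[Edge]] = {}
        for edge in graph.adjacent(node):
            neighbors.setdefault(edge.other(node), []).append(edge)
        for nxt in sorted(neighbors):
            if nxt in on_path or nxt in avoid:
                continue
            edge = min(neighbors[nxt], key=lambda e: (e.weight,) + e.key())
            if cost + edge.weight > bound:
                continue
            path.append(nxt)
            hops.append(edge)
            on_path.add(nxt)
            if dfs_lex(nxt, cost + edge.weight):
                return True
            on_path.discard(nxt)
            hops.pop()
            path.pop()
        return False

    if dfs_lex(src, 0):
        return tuple(path), tuple(hops)
    return None


def _shortest_branch(graph: QueryGraph, src: str, dst: str,
                     avoid: frozenset = frozenset()) -> PathBranch | None:
    cost = _dijkstra_cost(graph, src, dst, avoid)
    if cost is None:
        return None
    found = _lex_min_path(graph, src, dst, cost, avoid)
    if found is None:  # pragma: no cover - dijkstra and DFS agree by construction
        return None
    nodes, hops = found
    return PathBranch(nodes, hops, cost)


# ---------------------------------------------------------------------------
# find_path with branch aggregation
# ---------------------------------------------------------------------------

def _resolve_term(graph: QueryGraph, term) -> str:
    if isinstance(term, ConceptTerm):
        return term.uri
    text = str(term)
    if text.startswith(("http://", "https://", "urn:")):
        return text
    try:
        return expand_curie(text, graph.doc.namespaces)
    except SemviewError:
        return text


def find_path(graph: QueryGraph, input_term, output_term) -> QueryPath:
    """Aggregated shortest path between two annotated concepts.

    Raises :class:`SelfJoinError` for identical concepts,
    :class:`AnchorError` for a concept without a literal-column anchor and
    :class:`NoPathError` when no join chain links the two concepts.
    """
    in_uri = _resolve_term(graph, input_term)
    out_uri = _resolve_term(graph, output_term)
    if in_uri == out_uri:
        raise SelfJoinError(
            f"input and output concept are identical ({in_uri}); self joins are unsupported"
        )
    for uri, label in ((in_uri, "input"), (out_uri, "output")):
        if not graph.anchors.get(uri):
            raise AnchorError(f"{label} concept {uri} is not anchored in the view")

    best = None  # (cost, len(nodes), nodes, branch, src_anchor, dst_anchor)
    for src_anchor, dst_anchor in product(
        sorted(graph.anchors[in_uri], key=lambda a: str(a[1])),
        sorted(graph.anchors[out_uri], key=lambda a: str(a[1])),
    ):
        branch = _shortest_branch(graph, src_anchor[0], dst_anchor[0])
        if branch is None:
            continue
        key = (branch.cost, len(branch.nodes), branch.nodes)
        if best is None or key < best[0]:
            best = (key, branch, src_anchor, dst_anchor)
    if best is None:
        raise NoPathError(f"no path links {in_uri} to {out_uri} in the view")
    _, primary, src_anchor, dst_anchor = best

    branches = [primary]
    seen = {(primary.nodes, tuple(h.key() for h in primary.hops))}
    queue = [primary]
    probed: set[tuple] = set()
    while queue:
        branch = queue.pop(0)
        for i, hop in enumerate(branch.hops):
            if hop.kind != "subclass":
                continue
            child, parent = hop.u, hop.v
            for sibling in graph.subclass_children.get(parent, []):
                if sibling == child:
                    continue
                cand = _probe_sibling(graph, branch, i, parent, sibling)
                if cand is None:
                    continue
                probe_key = (parent, sibling, cand.nodes)
                if probe_key in probed:
                    continue
                probed.add(probe_key)
                key = (cand.nodes, tuple(h.key() for h in cand.hops))
                if key not in seen:
                    seen.add(key)
                    branches.append(cand)
                    queue.append(cand)
    ordered = [primary] + sorted(branches[1:], key=lambda b: b.nodes)
    return QueryPath((in_uri, src_anchor[1]), (out_uri, dst_anchor[1]), tuple(ordered))


def _probe_sibling(graph: QueryGraph, branch: PathBranch, hop_index: int,
                   parent: str, sibling: str) -> PathBranch | None:
    """Swap the subclass child at ``hop_index`` for ``sibling`` and re-route.

    The portion of the branch on the parent's side of the subclass hop is
    kept; the search resumes from the sibling toward the branch endpoint on
    the child's side, avoiding the kept nodes.
    """
    link = None
    for edge in graph.adjacent(parent):
        if edge.kind == "subclass" and edge.other(parent) == sibling:
            link = edge
            break
    if link is None:
        return None
    nodes, hops = branch.nodes, branch.hops
    if nodes[hop_index] == parent:
        # traversal parent -> child: keep the prefix up to the parent
        prefix_nodes, prefix_hops = nodes[: hop_index + 1], hops[:hop_index]
        if sibling in prefix_nodes:
            return None
        avoid = frozenset(prefix_nodes)
        rest = _shortest_branch(graph, sibling, nodes[-1], avoid)
        if rest is None:
            return None
        cand_nodes = prefix_nodes + rest.nodes
        cand_hops = prefix_hops + (link,) + rest.hops
    else:
        # traversal child -> parent: keep the suffix from the parent on
        suffix_nodes, suffix_hops = nodes[hop_index + 1:], hops[hop_index + 1:]
        if sibling in suffix_nodes:
            return None
        avoid = frozenset(suffix_nodes)
        head = _shortest_branch(graph, nodes[0], sibling, avoid)
        if head is None:
            return None
        cand_nodes = head.nodes + suffix_nodes
        cand_hops = head.hops + (link,) + suffix_hops
    if len(set(cand_nodes)) != len(cand_nodes):
        return None
    cost = sum(h.weight for h in cand_hops)
    return PathBranch(cand_nodes, cand_hops, cost)


# ---------------------------------------------------------------------------
# Exhaustive oracle (tests only)
# ---------------------------------------------------------------------------

def brute_force_paths(graph: QueryGraph, source: str, target: str,
                      max_nodes: int = 15) -> list[PathBranch]:
    """Exhaustively enumerate all simple paths source→target with costs.

    Deliberately naive (plain recursive enumeration, exponential in the
    node count) so it can serve as an independent oracle for the Dijkstra
    search; refuses graphs above ``max_nodes`` nodes.
    """
    if len(graph.nodes) > max_nodes:
        raise SemviewError(
            f"brute_force_paths refuses graphs with more than {max_nodes} nodes"
        )
    results: list[PathBranch] = []

    def recurse(node, path, hops, cost, visited):
        if node == target:
            results.append(PathBranch(tuple(path), tuple(hops), cost))
            return
        neighbors: dict[str, list[Edge]] = {}
        for edge in graph.adjacent(node):
            neighbors.setdefault(edge.other(node), []).append(edge)
        for nxt in sorted(neighbors):
            if nxt in visited:
                continue
            edge = min(neighbors[nxt], key=lambda e: (e.weight,) + e.key())
            recurse(nxt, path + [nxt], hops + [edge], cost + edge.weight,
                    visited | {nxt})

    if source in graph._adj or source == target:
        recurse(source, [source], [], 0, {source})
    return sorted(results, key=lambda b: (b.cost, b.nodes))
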