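# Methods

## The model

`semview` treats a relational schema as an undirected graph whose nodes
are tables and whose edges are the relationships a conceptual model would
have drawn between them. The pipeline has two decoupled phases. The
provider publishes a database: the schema is introspected, rendered as a
D2RQ-dialect RDF view (Turtle), automatically enriched with relationship
metadata and manually annotated with ontology-term URIs. The consumer
builds services: given an input concept and an output concept, the
annotated view is searched for the join chain linking them, the chain is
rendered as a SPARQL query, the query is translated to SQL and executed
live against the source database (no data are ever exported into the
view), and the result is optionally wrapped in a SAWSDL-annotated WSDL
descriptor.

### Enrichment rules

The relationship classification is purely structural — no name
heuristics:

* **Association table**: ≥ 2 foreign keys, and every column belongs to a
  foreign key or to the primary key. A single surrogate PK column is
  tolerated. The *arity* is the FK count. Whether a real reverse-
  engineering algorithm should tolerate free attribute columns on link
  tables is genuinely open; this tolerance is this package's choice, made
  for predictability, and is asserted in tests rather than inferred from
  any external source.
* **Subclass**: for a non-association child table with an FK to a parent,
  PK = FK columns → inheritance (one-table-per-class mapping);
  FK ⊊ PK → identifying relationship (aggregation/composition). Both are
  labelled with the same `rdf:subClassOf` property; the finding records
  which rule fired. Tables without a primary key are retained in the
  schema (with a warning diagnostic) but are ineligible as subclass
  parents.

The two classes are disjoint by construction: association tables are
excluded from subclass detection.

### Weight scheme and search

Edge weights: foreign-key hop **10**; hop through an arity-k association
table **10 + 5·(k−2)** (binary = 10, ternary = 15); subclass hop **2**.
The literature behind this design states the *preference* (favour binary
associations, follow inheritance) but not numbers; these values realise
the preference, keep subclass traversal cheap enough that hierarchies are
always entered when useful, and make accidental ties rare. Association
tables are edges, not nodes: entity paths never "stop" at a link table,
though the human-facing rendering re-expands the via-table
(`map:a -> map:link -> map:b`).

The search is a single-pair Dijkstra over this graph (edges traversable
in both directions — FKs are joins, not arrows). Ties between equal-cost
paths are broken by the lexicographically smallest node-URI sequence,
implemented as: Dijkstra establishes the minimum cost, then a
depth-first branch-and-bound in sorted-neighbour order returns the first
(hence lexicographically smallest) simple path attaining it. Parallel
edges between two tables are resolved to the cheapest edge, ties by a
deterministic edge key. When one concept anchors several columns, the
search runs over every anchor pair and the global minimum wins.

**Branch aggregation.** Subclasses partition their parent's instances, so
a path through one subclass sees only part of the data. For every
subclass hop on an accepted branch, every sibling child of the same
parent is probed: the branch is kept up to the parent side of the hop,
the child is swapped for the sibling, and the search resumes from the
sibling to the branch endpoint (avoiding the kept nodes). Every sibling
that still reaches the target contributes a branch, recursively (probes
are memoised, so aggregation terminates). Sibling-derived branches are
aggregated regardless of their cost — the alternative (aggregate only
near-minimal siblings) would silently drop complementary data, which is
exactly what aggregation exists to prevent. Branches are ordered primary
first, then lexicographically. Nothing is cached: paths are recomputed
from the view on every call.

### Query synthesis

The SPARQL shape is fixed: `SELECT DISTINCT ?<in>_name ?<out>_name`, the
input anchor triple, a `FILTER regex` on the input variable as the third
line of the query body, then one block per branch (UNION-joined when
there are at least two). FK and subclass hops render as one triple
(`?child vocab:{child}_{fkcol} ?parent` — the predicate always belongs to
the FK-owning table, whichever direction the hop was traversed);
association hops render as two triples sharing a fresh `?key{n}`
variable. Variable naming is canonical (`?{table}_id` for instances,
`?{concept}_name` for anchors); each block gets fresh key variables,
which under UNION is semantically equivalent to reusing one `?key` name
across blocks. A pattern containing no regex metacharacter is treated as
a literal and anchored `^…$`; anything else passes through verbatim. The
rendered text carries PREFIX declarations so it parses standalone under
the SPARQL 1.1 grammar (checked in tests with rdflib's parser).

### SQL translation and execution

Only the fragment above is translatable; anything else (OPTIONAL, GROUP
BY, …) raises a named unsupported-construct error. Each block becomes
`SELECT input_col, output_col FROM <join chain> WHERE <FK equalities>`;
blocks are combined with SQL `UNION`, whose set semantics mirror
`SELECT DISTINCT` (a single block gets an explicit `DISTINCT`). An
anchored literal filter becomes a SQL equality; a genuine regex is
applied as a row-level post-filter in Python after fetching — SQLite has
no native REGEXP, and pushing regexes into large scans is a known memory
hazard, so post-filtering bounds the risk while preserving SPARQL
`regex()` (unanchored search) semantics. Result rows are stringified,
deduplicated and sorted; SQL and SPARQL leave row order open, and the
imposed order makes executions reproducible.

Only SQLite is wired in as an engine (introspection via `PRAGMA`,
execution via stdlib `sqlite3`); `ConnectionMeta.engine` is the hook for
other dialects.

### Serialization

Turtle output is canonical and byte-stable: prefixes sorted, the view and
database blocks first, class maps sorted by table name, each followed by
its bridges sorted by column name; annotation terms sorted within a
bridge; composite primary keys kept as one ordered
`d2rq:primaryKey "t.a,t.b"` literal (RDF triples are unordered, so a
single literal preserves column order). Parsing goes through rdflib, so
externally produced D2RQ mappings are accepted; missing `dr:` labels
simply yield an empty enrichment set. `parse ∘ serialize` is the
identity on documents the package builds, and `serialize ∘ parse` is a
fixpoint on canonical text. The `dr:` relationship vocabulary is pinned
to `http://semview.org/relationships#`; the subclass label is written
`rdf:subClassOf` (the mapping dialect's spelling) even though the URI
lives outside RDFS. Composite FKs are modelled but treated as a single
edge by enrichment and search (the method reasons at the
table-relationship level); the multi-column join attaches to the bridge
of the FK's first source column.

## Parameters

| parameter | default | meaning |
|---|---|---|
| FK hop weight | 10 | baseline join cost |
| association hop | 10 + 5·(k−2) | arity-k link table; binary preferred |
| subclass hop | 2 | hierarchies are near-free to enter |
| `FixtureSpec.row_counts` | 3 studies, 5 germplasms | worked-example population |
| `FixtureSpec.overlap_fraction` | 0.5 | germplasms reachable via both branches |
| `random_schema(p_association, p_subclass)` | 0.3 / 0.3 | per-table chance of link-table / subclass role |
| `brute_force_paths(max_nodes)` | 15 | exponential-enumeration guard |

## Synthetic data: what it does and does not emulate

The fixture generator reproduces the *topology* that exercises every code
path — inheritance (PK = FK), binary association tables, a plain FK
chain, and branch-complementary row populations with a controllable
overlap — with readable slug values so failures are debuggable.
Randomized schemas (≤ 15 tables) add structural variety: random FK
spanning structure, link tables and subclass links placed with the given
probabilities, always connected and always valid. They do **not** emulate
real crop-database content or scale (tens of millions of records),
composite natural keys, NULL-able FK data quality, or schemas whose
inheritance is encoded single-table; passing tests therefore demonstrate
correctness of the mapping/search/translation logic, not performance or
robustness to dirty production schemas. Problem sizes in the test suite
and acceptance script (100 random schemas for the path oracle, 20
populated schemas for the SQL oracle, 50 for round-trips) were chosen as
comfortable desk-scale checks of properties that are size-independent.

## Numerical and degenerate-input choices

* Tie-breaks are everywhere lexicographic (node sequences, edge keys,
  anchor order), making every stage deterministic and insertion-order
  independent.
* A concept pair anchored on the *same* table yields a single-node,
  zero-hop branch (two anchor triples, no joins).
* Two FKs from one association table to the same target would create a
  self-edge and are skipped (self joins are out of scope end-to-end:
  identical input/output concepts are rejected with a dedicated error).
* FKs pointing *into* an association table from outside its member set
  are ignored by graph construction (the link table is an edge, not a
  node).
* Annotating a join-bearing (FK) bridge is allowed but logged as a
  warning; anchors are collected from literal bridges only.
* Empty filter patterns are rejected; an empty database is valid and
  yields empty results, not errors.

## Known limitations

* Single input concept, single output concept; no self joins; no k-best
  path choice surfaced to the user.
* Only the restricted SPARQL fragment the generator emits is executable;
  user additions beyond extra FILTER lines are rejected.
* D2RQ language coverage is limited to the constructs listed above
  (no translation tables, no conditional bridges).
* Ontology terms are opaque URIs: no OBO/OWL parsing, no subsumption
  reasoning over annotations.
* Service descriptors are emitted, not deployed; the WSDL template
  (string pattern in, row list out) is this package's own.
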