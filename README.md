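# semview

Semantic RDF views over relational databases, with automatic SPARQL query
synthesis and SAWSDL-annotated service descriptors.

Biological data for one organism are typically scattered across
independently designed relational databases. A practitioner who wants
"the germplasms used in a given study" must know each schema, write the
joins by hand, and repeat the work for every database. `semview`
implements an ontology-based data-access pipeline that removes the schema
knowledge from the consumer side:

1. **Publish** (provider): introspect a relational schema and render it as
   an RDF *view* — a D2RQ-dialect Turtle mapping with one `d2rq:ClassMap`
   per table and one `d2rq:PropertyBridge` per column. No data are
   exported; the view describes how to reach them.
2. **Enrich** (automatic): detect association tables (≥ 2 foreign keys and
   no free attribute columns; their *arity* is the FK count) and
   subclass-like relationships (child PK = FK to parent → inheritance;
   FK ⊊ PK → identifying aggregation/composition), written into the view
   as `dr:associatedTo`, `dr:arity` and `rdf:subClassOf` labels.
3. **Annotate** (the one manual step): a curator flags columns with
   ontology-term URIs (EDAM, Trait Ontology, domain-model concepts …).
4. **Synthesize** (consumer): given an input and an output concept, the
   annotated view is read as a weighted graph over its tables (foreign-key
   hop = 10, hop through an arity-k association table = 10 + 5·(k−2),
   subclass hop = 2) and a Dijkstra-style single-pair search finds the
   cheapest join chain; binary associations are favoured by construction.
   For every subclass hop used, sibling subclasses of the same parent are
   probed and each viable alternative becomes an extra branch — the
   branches are complementary, not redundant, so they are aggregated into
   one `SELECT DISTINCT … WHERE { … } UNION { … }` SPARQL query with an
   anchored `FILTER regex` on the input.
5. **Execute / wrap**: the restricted SPARQL fragment is translated to SQL
   (one SELECT per branch, set-`UNION`ed) and run against the source
   database, and the query can be wrapped in a WSDL 1.1 descriptor whose
   input/output elements carry `sawsdl:modelReference` annotations with
   the chosen concept URIs.

Identical input and output concepts are rejected (the search joins two
distinct nodes; self joins are out of scope), as are concepts with no
literal-column anchor in the view.

## Worked example

The bundled fixture generator builds a seven-table crop-study database: a
`study` specialised into `genotypingstudy` and `phenotypingstudy`
(PK = FK), germplasms reachable from the genotyping side through DNA
samples and a binary association table, and from the phenotyping side
through a second association table.

```bash
semview fixture --out demo --seed 1
semview view --db demo/gcp.sqlite --name gcp -o demo/gcp.ttl
semview enrich -i demo/gcp.ttl --db demo/gcp.sqlite -o demo/gcp.ttl
semview annotate -i demo/gcp.ttl --manifest demo/gcp.manifest.tsv -o demo/gcp.ttl
semview plan -i demo/gcp.ttl --in gcpdm:study --out gcpdm:germplasm
```

prints the two aggregated branches:

```
Path 1 (cost 12): map:study -> map:phenotypingstudy -> map:germplasmphenotypingstudy -> map:germplasm
Path 2 (cost 22): map:study -> map:genotypingstudy -> map:dnasamplegenotypingstudy -> map:dnasample -> map:germplasm
```

The phenotyping branch is cheaper (one subclass hop + one binary
association); the genotyping branch adds a DNA-sample indirection. Both
are kept because the two subclasses hold complementary rows. Then

```bash
semview run -i demo/gcp.ttl --in gcpdm:study --out gcpdm:germplasm --pattern study_001
```

executes the synthesized query and prints every germplasm reachable from
`study_001` through *either* branch, deduplicated and sorted:

```
study_001	germplasm_001
study_001	germplasm_002
study_001	germplasm_003
study_001	germplasm_004
study_001	germplasm_005
```

`semview query-gen` writes the SPARQL text itself and `semview wsdl`
emits the annotated service descriptor. Every command is a thin wrapper
over the library API (`semview.build_rdf_view`, `enrich_view`,
`annotate`, `find_path`, `generate_sparql`, `translate_to_sql`,
`execute`, `emit_descriptor`).

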