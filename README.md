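# phenoc

A compiler and processing pipeline for **computable species descriptions**:
taxonomic descriptions written in a small semantic-phenotype language are
compiled into an OWL knowledge graph of ontology individuals (an ABox),
shape-validated, enriched by a materializing reasoner, rendered back into
annotated natural language, queried for trait counts, and packaged as
nanopublications.

## Who this is for

Taxonomists and biodiversity informaticians who want species descriptions
that are FAIR and machine-queryable rather than free text. The package uses
dung beetles of the genus *Grebennikovius* (Coleoptera, Scarabaeinae) as its
worked example: four complete species descriptions are bundled as fixtures,
together with a curated mini-ontology standing in for the AISM, COLAO,
PATO, BSPO, UBERON, IAO and RO vocabularies.

## The model

A description is a set of statements, each a node–edge chain in a knowledge
graph. Nodes are ontology terms written `prefix-local_name`; edges are
object properties, abbreviated by operator glyphs:

| glyph | property |
|-------|----------|
| `>`   | has_part |
| `<`   | part_of (BFO:0000050, transitive) |
| `>>`  | has_characteristic |
| `<<`  | characteristic_of |
| `\|>\|` | increased_in_magnitude_relative_to |
| `\|<\|` | decreased_in_magnitude_relative_to |
| `!>`  | negated has_part (absence) |

Any registered property can be written in dotted form
(`.iao-is_quality_measured_as`). Statements end with `;`. Identity tags
(`aism-pronotum:id-1549f8`) merge occurrences of one individual across
statements; `[exclude = True]` marks nodes that belong to another species
inside a cross-species comparison; parenthesised node lists distribute the
incoming edge over every item.

Compilation turns every term occurrence into a typed OWL individual. The
reasoner materializes subclass and transitive-parthood closures, mints
skolem parts for "with N parts" logical definitions (a
`maxillary_palpus_with_4_palpomeres` individual entails four palpomere
parts), classifies individuals into body-region defined classes
`X or (part_of some X)`, and reports clashes — e.g. an asserted part whose
existence an absence statement denies.

## Worked example

Compile the bundled *Grebennikovius* descriptions and run the whole
pipeline:

```
$ phenoc run --goldens -o out
ok; artifacts in out
```

`out/description_grebennikovius_armiger.txt` then contains, among ~90
generated lines:

```
male organism, posterior longitudinal hypomeral carina: absent;
male organism, clypeus, anterior region, setigerous cuticular puncture: diameter smaller than diameter of setigerous cuticular puncture of frons
male organism, pronotum, interpunctural distance = 1.5, unit: diameter of ocellate setigerous cuticular puncture;
the length of the hind wing is smaller than that of the male of G. basilewskyi;
male organism, length = 4.5, unit: millimeter;
```

i.e. absence, relative comparison, relative measurement, cross-species
comparison and absolute measurement statements rendered from the graph —
the organism is 4.5 mm long, its hind wing is shorter than that of
*G. basilewskyi*, and the hypomeral carina is absent. The query tables
report counts of individuals per quality parent and per body region, for
example (`out/table_regions.tsv`):

```
entity	grebennikovius_armiger	grebennikovius_basilewskyi	grebennikovius_lupanganus	grebennikovius_pafelo
head_or_part	24	24	19	19
thorax_or_part	38	43	32	40
abdomen_or_part	17	20	17	16
leg_or_part	29	32	27	31
```

`out/nanopubs.trig` packages one "inhabits a forest environment"
nanopublication per species (four named graphs each: head, assertion,
provenance, pubinfo).

Library use mirrors the CLI:

```python
from phenoc import (build_fixture_ontology, parse_document,
                    compile_document, materialize, generate)
from phenoc.synth import golden_document_source

tbox = build_fixture_ontology()
doc = parse_document(golden_document_source(), "title: Grebennikovius")
graph = compile_document(doc, tbox)          # 754 individuals
inferred = materialize(graph, tbox)          # consistent
print(generate(inferred, "grebennikovius_armiger").text())
```

## Layout

- `src/phenoc/` — parser, compiler, shape validator, reasoner, NL
  generator, query engine, nanopub emitter, pipeline and CLI
- `src/phenoc/data/` — fixture mini-ontology and the four golden
  descriptions
- `docs/methods.md` — model, assumptions, numerical and design choices
- `tests/` — unit, property and acceptance suites
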