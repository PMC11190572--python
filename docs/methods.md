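# Methods

## The individual-based (ABox) model

A species description is modelled as a knowledge graph of ontology
*individuals*: every mention of an anatomical entity, quality, measurement
datum or unit in the source text becomes one typed individual, and the
relations between mentions become property assertions. This contrasts with
class-based (TBox) phenotype annotation, where each phenotype is a class
expression; the individual level keeps the description close to the
specimen actually examined and makes counting ("how many individuals are
classified under *shape* for this species?") a direct graph query.

Identity is the central modelling decision:

- The organism class (default `uberon-male_organism`, configurable) always
  denotes the single per-species organism individual. This is what makes a
  description one connected graph rather than a bag of fragments.
- An alphanumeric tag (`:id-…`, `:md-…`; the two prefixes carry no semantic
  difference) merges occurrences into one individual across statements —
  needed, e.g., for a measurement whose datum is defined on one line and
  given its value on the next.
- Untagged occurrences are chain-scoped: repeating `aism-pronotum` in a
  second statement mints a second pronotum individual. Tags exist precisely
  to override this.
- In a cross-species comparison, `[exclude = True]` nodes belong to the
  foreign species named by the OTU binding in the same statement; they
  count toward the foreign species' individual tally, not the focal one's.
  A single-colon suffix that names a declared species is accepted as an
  OTU binding alongside the double-colon form, since both spellings occur
  in published sources.

Absence is modelled at the class level: `organism !> C` asserts the
organism to be an instance of `ObjectComplementOf(has_part some C)`.
Individual-level absence has no direct OWL construct, and the complement
restriction is exactly what a later asserted (or inferred) part of class
`C` contradicts.

Skolem identifiers are deterministic — `<otu>/s<stmt>/p<pos>` for untagged
occurrences, `<otu>/<tag>` for tagged ones, `…/skolem/<class>` for
reasoner-minted parts — so every serialization is byte-stable and
diff-friendly. Turtle output is written by a canonical writer (sorted
subjects, no blank nodes; OWL restrictions get derived IRIs) for the same
reason. Assertion provenance (owning species, statement index, in-statement
order) rides on reification nodes whose IRIs encode it; reloading a
serialized graph reconstructs the compiler's exact output, which the
round-trip tests check.

Measurement values are carried as `decimal.Decimal`, not floats: the
printed precision ("1.0" vs "3") is part of the description and must
survive compile → serialize → reload → narrate.

## The fixture vocabulary

`data/fixture_tbox.yaml` is the single curated data file behind
`build_fixture_ontology()`. It declares ~180 classes: a quality spine
(colour / shape / size / texture under a quality root), spatial regions and
margins, body-region roots (head, thorax, abdomen, leg) with class-level
`part_of` chains placing each anatomical term, "with N parts" logical
definitions (palpi, tarsi), four body-region defined classes, and one
disjointness pair used by the clash tests. Placement follows anatomically
consistent conventions for scarab beetles — the tooth-bearing protibial
margin is the *dorsal* side of the leg, genitalia are abdominal structures.
Where the published identifier of a term is unambiguous (parthood, the four
quality parents, the four body regions) the real OBO IRI is kept so graphs
stay joinable; other fixture terms are minted under a project namespace.

Quality placement is curation, not ontology gospel: e.g. `dilated`,
`sloped` and `protruding` sit under *shape*, `interpunctural_distance`
under *size*. Different placements would shift the per-parent query counts;
the brute-force oracles in the tests are placement-independent.

The elytron class `elytron_with_9_striae` carries no logical definition
(unlike the palpi/tarsi) because no individually named stria classes exist
in the vocabulary; skolemizing nine anonymous striae per elytron would
inflate individual counts without adding queryable content.

## Reasoning fragment

The reasoner is a rule-based EL-style materializer rather than a full DL
reasoner: subclass closure, transitive `part_of` with `has_part`
inversion, existential skolemization with suppression (no skolem is minted
when an asserted part of the filler class already exists on the bearer),
union defined classes, complement-restriction clash detection and class
disjointness. This covers every inference the pipeline needs at desk
scale. Membership in `X or (part_of some X)` holds through either the
individual-level parthood closure or class-level parthood chains in the
TBox (an antenna individual is in the head region although no head
individual is asserted); with a transitive role the chain collapses, so
the implementation computes a reverse fixpoint over subclass ∪ part_of
edges from `X`. Materialization iterates to a fixpoint and is idempotent;
both properties are tested, the closures against naive fixpoint oracles on
200 random graphs of up to 50 nodes.

Skolem individuals are flagged and excluded from preset query counts by
default (an `include_skolems` flag adds them), so a "with 4 palpomeres"
statement contributes one countable individual, not five.

## Shape validation

Four default shapes gate the pipeline after compilation: (a) every
non-organism individual must be connected, through the assertion graph, to
a species organism; (b) every species record carries a taxon identifier;
(c) every species record carries a voucher catalog number; (d) a
measurement datum has exactly one value and at least one unit. (a) is not
expressible in core SHACL and is annotated in the project namespace when
shapes are serialized; (b)–(d) serialize as standard
`sh:targetClass`/`sh:path`/`sh:minCount`/`sh:maxCount` shapes so external
validators can re-run them. Validation is monotone (adding a defect never
removes a violation) and each generator mutation violates exactly one
shape class; both are tested.

## Natural-language generation

The generator walks each species' assertions in authoring order,
reconstructs the parthood spine of every statement and renders telegraphic
entity-quality lines. Templates: presence `…: present;`, absence
`…, X: absent;`, quality `…: q;`, measurement `…, q = value, unit: u;`
(a relative unit renders as "q of bearer"), within-species comparison
`…: q smaller/larger than q of A of B`, positional `… rel A of B`, and a
full cross-species sentence ("the length of the hind wing is smaller than
that of the male of G. basilewskyi;"). Relation spellings follow published
usage, including its inconsistencies (`medial_to` keeps the underscore,
"coincident with" does not). A `legacy_asterisk` flag reproduces the
historically truncated cross-species output (`hind wing: length;`) for
regression comparison; the full sentence is the default because the
truncation was a conversion bug, not intended behaviour.

Completeness is enforced: every compiler-minted individual that a species'
own statements mention must contribute to at least one line, or generation
fails naming the orphan. Individuals referenced from *another* species'
comparison statements are narrated in that species' description instead.
Term labels are humanized local names (underscores to spaces); every label
in a line is annotated with its ontology IRI in the Markdown/HTML
renderings, and the plain-text rendering carries no markup.

## Queries

Two preset count families: individuals per quality parent (colour, shape,
size, texture) and per body-region defined class (head, thorax, abdomen,
leg — membership is not exclusive). Counts are computed in Python over the
materialized closures and independently cross-checked by executing the
exported SPARQL texts over the exported Turtle with rdflib's SPARQL engine;
the two routes must agree exactly on every fixture, and counts are
invariant under statement reordering of the source.

## Nanopublications

Per species, one nanopublication asserts that the taxon inhabits its
recorded habitat. The habitat relation is `RO:0002303` (has habitat) and
the forest term `ENVO:01000174`, both overridable. URIs are deterministic
digests of (taxon id, habitat term); emission is file-only TriG with the
standard four named graphs, structurally validated. No signing, trusty
URIs or network publication. The creation date is omitted unless
configured, keeping re-emission byte-identical.

## Synthetic generator

`generate_description` draws statements from all nine families (presence,
absence, count/list, quality, absolute and relative measurement, within-
and between-species comparison, positional) over the fixture vocabulary
and records ground-truth tallies — individuals per species, per quality
parent, per region, and datum values — constructively while emitting. It
emulates the structural shape of real descriptions (one focal and one
reference species, organism-rooted chains, tags for recurring entities);
it does not attempt realistic trait distributions or intraspecific
variation, so passing tests demonstrate structural correctness of the
toolchain, not biological plausibility. Absence statements draw from a
dedicated pool of structures never asserted present, so a clean random
description is always consistent. Mutants (`drop-species-link`,
`drop-datum-value`, `add-clashing-part`, `duplicate-tag-conflict`) differ
from the clean output by exactly one named defect. Default size is 12
statements per description; the test suites use 10–14 statements and
25–50 seeds, which exercises every family while keeping the default run
fast.

## Golden treatments and their delta from the published data

The four bundled species descriptions were re-encoded by hand from the
*printed* natural-language treatments, not from the supplementary source
files, so the repository tests without downloads. Consequences:

- Compiling all four yields **754** individuals against the published total
  of 756; the residual stems from encoding choices the print does not pin
  down (chiefly which repeated mentions share a tag, and one cross-species
  comparison per species — the print only lets three of the four be
  reconstructed, all targeting *G. basilewskyi*).
- Of the published query table, the colour row (3/5/3/3), the texture row
  (2/1/2/2) and the leg-region row (29/32/27/31) are reproduced exactly and
  asserted in the acceptance tests. The shape, size and the other region
  rows differ by modest margins, dominated by the fixture quality-spine
  placement and by region counts in the original being computed over the
  twelve full OBO ontologies (whose parthood axioms place more generic
  structures) rather than the desk-scale fixture. These rows are checked
  against the package's own brute-force oracles, not against the published
  numbers.
- Printed nesting artefacts (bare block headers such as "male organism,
  elytron with 9 striae") re-encode as presence statements.

## Numerical and procedural choices

- Statement order is the canonical traversal order everywhere (NL,
  serialization); ties inside a statement break by in-chain position.
- TBox merge: axioms union, labels first-loaded-wins with a warning —
  desk-scale ROBOT-merge semantics.
- Subclass cycles are rejected at axiom insertion; parthood cycles in the
  ABox are tolerated (the closure is plain reachability).
- The pipeline halts after stage 2 on any shape violation and after
  stage 4 on inconsistency, keeping earlier artifacts; exit codes name the
  failing step. Re-running an unchanged configuration reproduces all
  artifacts byte-for-byte (the run report is excluded — it contains wall
  times).

## Known limitations

- The OWL fragment is deliberately small: subclass, inverse, transitivity,
  existential parthood, union defined classes, complement-of-existential
  absence, disjointness. No general class expressions, no tableau
  reasoning, no justification trees beyond the minimal clash triples.
- NL nesting/elision of the original rendering is reverse-engineered from
  four documents; the generator emits full locator chains (provably
  complete) rather than reproducing the elided block layout.
- Intervals ("1–2 diameters") have no syntax; descriptions store the
  average, matching published practice.
- Intraspecific variation is out of scope; one specimen, one description.
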