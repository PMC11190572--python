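"""Rule-based materializing reasoner over the ABox.

Implements the inference fragment the toolchain needs, in the style of an
EL materializer:

* type closure along subclass axioms;
* transitive parthood closure over individual-level ``part_of`` edges
  (``has_part`` edges contribute through inversion);
* skolemization of "with N parts" logical definitions — an individual typed
  by a class carrying existential ``has_part`` axioms receives one minted
  part per axiom, unless an asserted part of the filler class already
  exists (suppression avoids double counting);
* membership in defined classes ``X or (part_of some X)``, where the
  existential branch holds either through the individual-level parthood
  closure or through class-level parthood chains in the TBox (transitive
  roles make the chain collapse);
* clash detection: a class-level absence (negated ``has_part C``)
  contradicted by an asserted or inferred part typed ``C`` (or a subclass),
  and co-assertion of disjoint classes.

Materialization is a fixpoint and idempotent: re-running it over an already
materialized graph adds nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .compiler import ABOX_NS, Assertion, Individual, KnowledgeGraph
from .tbox import TBoxStore
from .terms import KNOWN_OBO_IRIS, TermRef

PART_OF_IRI = KNOWN_OBO_IRIS[("ro", "part_of")]
HAS_PART_IRI = KNOWN_OBO_IRIS[("ro", "has_part")]

#: statement index marking reasoner-minted assertions
SKOLEM_STMT = -2


@dataclass
class Clash:
    kind: str                 # "absence" | "disjoint"
    individual: str
    detail: str
    triples: tuple = ()       # minimal responsible triple set


@dataclass
class InferredGraph:
    base: KnowledgeGraph
    tbox: TBoxStore
    inferred_types: dict[str, set[str]] = field(default_factory=dict)
    part_closure: dict[str, set[str]] = field(default_factory=dict)
    skolems: list[Individual] = field(default_factory=list)
    defined_extensions: dict[str, set[str]] = field(default_factory=dict)
    clashes: list[Clash] = field(default_factory=list)

    @property
    def consistent(self) -> bool:
        return not self.clashes

    def types_of(self, ind_id: str) -> set[str]:
        return self.inferred_types.get(ind_id, set())

    def wholes_of(self, ind_id: str) -> set[str]:
        return self.part_closure.get(ind_id, set())


def _direct_part_edges(graph: KnowledgeGraph) -> set[tuple[str, str]]:
    """(part, whole) pairs from positive parthood assertions."""
    edges: set[tuple[str, str]] = set()
    for a in graph.assertions:
        if a.negated or not isinstance(a.object, str):
            continue
        iri = a.predicate.ref.iri
        if iri == PART_OF_IRI:
            edges.add((a.subject, a.object))
        elif iri == HAS_PART_IRI:
            edges.add((a.object, a.subject))
    return edges


def transitive_closure(edges: set[tuple[str, str]]) -> dict[str, set[str]]:
    """Naive reachability closure (part -> all wholes)."""
    adj: dict[str, set[str]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
    out: dict[str, set[str]] = {}
    for start in adj:
        seen: set[str] = set()
        stack = list(adj[start])
        while stack:
            n = stack.pop()
            if n in seen:
                continue
            seen.add(n)
            stack.extend(adj.get(n, ()))
        out[start] = seen
    return out


def materialize(graph: KnowledgeGraph, tbox: TBoxStore) -> InferredGraph:
    """Compute the inferred graph; never raises on inconsistency."""
    # work on a shallow structural copy so the input graph stays untouched
    work = KnowledgeGraph(
        individuals=dict(graph.individuals),
        assertions=list(graph.assertions),
        otus=dict(graph.otus),
    )
    inf = InferredGraph(base=work, tbox=tbox)

    changed = True
    while changed:
        changed = False
        inf.inferred_types = {
            i.id: set(tbox.ancestors(i.cls.iri))
            for i in work.individuals.values()
        }
        edges = _direct_part_edges(work)
        inf.part_closure = transitive_closure(edges)
        direct_parts: dict[str, set[str]] = {}
        for part, whole in edges:
            direct_parts.setdefault(whole, set()).add(part)

        has_part_prop = tbox.properties.get(HAS_PART_IRI)
        for ind in list(work.individuals.values()):
            for typ in sorted(inf.inferred_types[ind.id]):
                for prop_iri, filler_iri in tbox.logical_defs.get(typ, []):
                    if prop_iri != HAS_PART_IRI:
                        continue
                    satisfied = any(
                        filler_iri in inf.inferred_types.get(p, set())
                        for p in direct_parts.get(ind.id, ())
                    )
                    if satisfied:
                        continue
                    filler = tbox.classes[filler_iri]
                    sk_id = f"{ind.id}/skolem/{filler.local}"
                    if sk_id in work.individuals:
                        continue
                    sk = Individual(id=sk_id, cls=filler,
                                    owner_otu=ind.owner_otu,
                                    origin=ind.origin, skolem=True)
                    work.individuals[sk_id] = sk
                    work.assertions.append(Assertion(
                        subject=ind.id, predicate=has_part_prop, object=sk_id,
                        otu=ind.owner_otu, stmt_index=SKOLEM_STMT))
                    inf.skolems.append(sk)
                    changed = True

    for name, dc in tbox.defined_classes.items():
        region = tbox.region_classes(dc.base.iri)
        ext: set[str] = set()
        for ind_id in work.individuals:
            scope = {ind_id} | inf.part_closure.get(ind_id, set())
            if any(inf.inferred_types.get(w, set()) & region for w in scope):
                ext.add(ind_id)
        inf.defined_extensions[name] = ext

    inf.clashes = _find_clashes(inf)
    return inf


def _find_clashes(inf: InferredGraph) -> list[Clash]:
    clashes: list[Clash] = []
    work = inf.base
    parts_of: dict[str, set[str]] = {}
    for part, wholes in inf.part_closure.items():
        for w in wholes:
            parts_of.setdefault(w, set()).add(part)

    for a in work.assertions:
        if not a.negated:
            continue
        denied = a.object
        assert isinstance(denied, TermRef)
        for p in sorted(parts_of.get(a.subject, ())):
            if denied.iri in inf.inferred_types.get(p, set()):
                clashes.append(Clash(
                    kind="absence",
                    individual=a.subject,
                    detail=(f"{a.subject} denies has_part {denied.curie} but "
                            f"{p} is such a part"),
                    triples=((a.subject, "not(has_part)", denied.curie),
                             (p, "part_of", a.subject),
                             (p, "a", denied.curie)),
                ))

    for x, y in sorted(inf.tbox.disjoint_axioms):
        for ind_id, types in sorted(inf.inferred_types.items()):
            if x in types and y in types:
                clashes.append(Clash(
                    kind="disjoint",
                    individual=ind_id,
                    detail=(f"{ind_id} typed by disjoint classes "
                            f"{inf.tbox.label_for(x)} / {inf.tbox.label_for(y)}"),
                    triples=((ind_id, "a", x), (ind_id, "a", y)),
                ))
    return clashes


def check_consistency(inf: InferredGraph) -> tuple[bool, list[Clash]]:
    """Recompute the clash list for a materialized graph."""
    clashes = _find_clashes(inf)
    return (not clashes, clashes)


def classify_into(inf: InferredGraph, defined_class: str) -> set[str]:
    """Extension of a registered defined class (set of individual ids)."""
    if defined_class not in inf.defined_extensions:
        if defined_class not in inf.tbox.defined_classes:
            raise KeyError(f"unknown defined class: {defined_class!r}")
        # registered after materialization: compute on demand
        dc = inf.tbox.defined_classes[defined_class]
        region = inf.tbox.region_classes(dc.base.iri)
        ext = {
            ind_id
            for ind_id in inf.base.individuals
            if any(inf.inferred_types.get(w, set()) & region
                   for w in ({ind_id} | inf.part_closure.get(ind_id, set())))
        }
        inf.defined_extensions[defined_class] = ext
    return set(inf.defined_extensions[defined_class])


def serialize_inferred(inf: InferredGraph) -> str:
    """Turtle for base + inferred triples, inferred ones flagged."""
    from .compiler import serialize_abox

    base_ttl = serialize_abox(inf.base, inf.tbox)
    lines = [base_ttl.rstrip("\n"), ""]
    lines.append("# inferred triples")
    for ind_id in sorted(inf.inferred_types):
        asserted = inf.base.individuals[ind_id].cls.iri
        for t in sorted(inf.inferred_types[ind_id]):
            if t == asserted:
                continue
            lines.append(f"<{ABOX_NS}{ind_id}> a <{t}> .")
            lines.append(
                f"<{ABOX_NS}{ind_id}> "
                f"<https://w3id.org/phenoc/vocab/core#inferred> \"true\" .")
    for name in sorted(inf.defined_extensions):
        dc = inf.tbox.defined_classes[name]
        for ind_id in sorted(inf.defined_extensions[name]):
            lines.append(f"<{ABOX_NS}{ind_id}> a <{dc.ref.iri}> .")
    for part, wholes in sorted(inf.part_closure.items()):
        for w in sorted(wholes):
            lines.append(f"<{ABOX_NS}{part}> <{PART_OF_IRI}> <{ABOX_NS}{w}> .")
    return "\n".join(lines) + "\n"
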