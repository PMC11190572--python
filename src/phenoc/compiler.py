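"""Compile parsed descriptions into an ABox knowledge graph.

Each ontology-term occurrence in a statement chain becomes an ontology
*individual* typed by its class; edges become property *assertions* between
individuals.  Identity rules:

* the organism class always maps to the single per-species organism
  individual (that is what makes the description one connected graph);
* a tagged occurrence (``aism-pronotum:id-1549f8``) merges with every other
  occurrence of the same tag in the same species;
* untagged occurrences are chain-scoped — repeating a class in another
  statement mints a fresh individual;
* ``[exclude = True]`` nodes belong to the foreign species named by the
  OTU binding in the same statement and are excluded from the focal
  species' tally.

Negated ``has_part`` edges (``!>``) deny existence at the class level: the
subject is asserted to be an instance of
``ObjectComplementOf(has_part some C)``.  Skolem identifiers are
deterministic (``<otu>/s<stmt>/p<pos>`` untagged, ``<otu>/<tag>`` tagged),
so compiling the same source twice yields byte-identical Turtle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Optional, Union

import rdflib
from rdflib import Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

from .parser import Document, EdgeExpr, NodeExpr, StatementAST
from .tbox import PHENOC_NS, TBoxStore, ref_from_iri
from .terms import PropertyDef, TermRef, TermResolutionError

ABOX_NS = "https://w3id.org/phenoc/abox/"


class CompileError(ValueError):
    pass


class TagConflictError(CompileError):
    pass


class UnknownOTUError(CompileError):
    pass


@dataclass
class Individual:
    id: str                      # skolem path, e.g. "armiger/s3/p2"
    cls: TermRef
    owner_otu: str
    tag: Optional[str] = None
    origin: tuple[int, int] = (-1, -1)   # (statement index, chain position)
    skolem: bool = False         # minted by the reasoner, not the compiler

    @property
    def iri(self) -> str:
        return ABOX_NS + self.id


@dataclass(frozen=True)
class Assertion:
    subject: str                          # individual id
    predicate: PropertyDef
    object: Union[str, Decimal, TermRef]  # individual id | literal | class
    polarity: str = "positive"            # "positive" | "negated"
    otu: str = ""
    stmt_index: int = -1
    order: int = 0

    @property
    def negated(self) -> bool:
        return self.polarity == "negated"

    def key(self) -> tuple:
        if isinstance(self.object, TermRef):
            obj = ("cls", self.object.iri)
        elif isinstance(self.object, Decimal):
            obj = ("lit", str(self.object))
        else:
            obj = ("ind", self.object)
        return (self.subject, self.predicate.ref.iri, obj, self.polarity,
                self.otu, self.stmt_index, self.order)


@dataclass
class OTURecord:
    otu_id: str
    label: str = ""
    taxon_id: str = ""
    catalog_number: str = ""
    parent_name_usage_id: str = ""
    habitat: str = ""
    organism_id: str = ""


@dataclass
class KnowledgeGraph:
    individuals: dict[str, Individual] = field(default_factory=dict)
    assertions: list[Assertion] = field(default_factory=list)
    otus: dict[str, OTURecord] = field(default_factory=dict)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return (
            {i.id: (i.cls.iri, i.owner_otu, i.tag, i.skolem)
             for i in self.individuals.values()}
            == {i.id: (i.cls.iri, i.owner_otu, i.tag, i.skolem)
                for i in other.individuals.values()}
            and sorted(a.key() for a in self.assertions)
            == sorted(a.key() for a in other.assertions)
            and self.otus == other.otus
        )

    def base_individuals(self, otu: Optional[str] = None) -> list[Individual]:
        """Compiler-minted (non-skolem) individuals, optionally per species."""
        return [i for i in self.individuals.values()
                if not i.skolem and (otu is None or i.owner_otu == otu)]

    def assertions_for(self, otu: str) -> list[Assertion]:
        return [a for a in self.assertions if a.otu == otu]


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------

class _Compiler:
    def __init__(self, doc: Document, tbox: TBoxStore) -> None:
        self.doc = doc
        self.tbox = tbox
        self.graph = KnowledgeGraph()
        self.missing: set[str] = set()
        self.organism_curie = doc.config.organism_class

    def resolve_class(self, curie: str) -> Optional[TermRef]:
        try:
            ref = self.tbox.term(curie)
        except TermResolutionError:
            self.missing.add(curie)
            return None
        if ref.iri not in self.tbox.classes:
            self.missing.add(curie)
            return None
        return ref

    def resolve_property(self, edge: EdgeExpr) -> PropertyDef:
        if edge.dotted:
            prop = self.tbox.properties.by_curie(edge.property)
            if prop is None:
                raise CompileError(f"unknown property: .{edge.property}")
            return prop
        prop = self.tbox.properties.by_alias(edge.property)
        if prop is None:
            raise CompileError(f"no property registered for alias {edge.property!r}")
        return prop

    def _organism(self, otu_id: str) -> Individual:
        ind_id = f"{otu_id}/organism"
        if ind_id not in self.graph.individuals:
            cls = self.resolve_class(self.organism_curie)
            if cls is None:
                raise CompileError(
                    f"organism class not in TBox: {self.organism_curie}")
            self.graph.individuals[ind_id] = Individual(
                id=ind_id, cls=cls, owner_otu=otu_id, origin=(-1, -1))
        return self.graph.individuals[ind_id]

    def _tagged(self, owner: str, tag: str, cls: TermRef,
                origin: tuple[int, int]) -> Individual:
        ind_id = f"{owner}/{tag}"
        existing = self.graph.individuals.get(ind_id)
        if existing is not None:
            if existing.cls.iri != cls.iri:
                raise TagConflictError(
                    f"tag {tag!r} reused with conflicting class: "
                    f"{existing.cls.curie} vs {cls.curie}")
            return existing
        ind = Individual(id=ind_id, cls=cls, owner_otu=owner, tag=tag,
                         origin=origin)
        self.graph.individuals[ind_id] = ind
        return ind

    def _foreign_otu(self, stmt: StatementAST, focal: str) -> Optional[str]:
        for node in stmt.nodes:
            items = node.items if node.kind == "list" else [node]
            for n in items:
                if n.exclude and n.otu_binding:
                    return n.otu_binding
        return None

    def _make_individual(self, node: NodeExpr, focal: str, foreign: Optional[str],
                         stmt_index: int, pos: int) -> Individual:
        assert node.kind == "term" and node.term is not None
        cls = self.resolve_class(node.term)
        if cls is None:
            # placeholder; compile() raises after the full missing list is known
            cls = TermRef("phenoc", "unresolved", PHENOC_NS + "unresolved")
        owner = focal
        if node.exclude:
            if foreign is None:
                raise UnknownOTUError(
                    f"excluded node {node.term} has no OTU binding in its "
                    f"statement")
            owner = foreign
        elif node.otu_binding and node.otu_binding != focal:
            # a non-excluded binding to another species is a reference to
            # that species' organism; anything else is an authoring error
            if node.term != self.organism_curie:
                raise CompileError(
                    f"node {node.term} bound to foreign OTU "
                    f"{node.otu_binding!r} without exclude")
            owner = node.otu_binding
        if owner not in self.doc.statements:
            raise UnknownOTUError(f"undeclared OTU: {owner!r}")
        if node.exclude and owner == focal:
            raise CompileError(
                f"exclude used on a node of the focal OTU {focal!r}")
        if node.term == self.organism_curie:
            return self._organism(owner)
        origin = (stmt_index, pos)
        if node.tag:
            return self._tagged(owner, node.tag, cls, origin)
        ind_id = f"{owner}/s{stmt_index}/p{pos}"
        ind = Individual(id=ind_id, cls=cls, owner_otu=owner, origin=origin)
        self.graph.individuals[ind_id] = ind
        return ind

    def compile_statement(self, otu_id: str, stmt_index: int,
                          stmt: StatementAST) -> None:
        foreign = self._foreign_otu(stmt, otu_id)
        if foreign is not None and foreign not in self.doc.statements:
            raise UnknownOTUError(f"exclude references undeclared OTU {foreign!r}")
        pos = 0
        order = 0
        current: list[Individual] = []
        pending: Optional[tuple[PropertyDef, bool]] = None  # (prop, negated)

        for el in stmt.elements:
            if isinstance(el, EdgeExpr):
                pending = (self.resolve_property(el), el.negated)
                continue
            node = el
            if node.kind == "literal":
                if pending is None:
                    raise CompileError("literal node without a property")
                prop, negated = pending
                if negated:
                    raise CompileError("negation cannot target a literal")
                for subj in current:
                    self.graph.assertions.append(Assertion(
                        subject=subj.id, predicate=prop, object=node.value,
                        otu=otu_id, stmt_index=stmt_index, order=order))
                    order += 1
                current = []
                pending = None
                continue

            items = node.items if node.kind == "list" else [node]
            if pending is not None and pending[1]:
                # absence: class-level denial, no individual minted
                prop, _ = pending
                for item in items:
                    cls = self.resolve_class(item.term or "")
                    if cls is None:
                        continue
                    for subj in current:
                        self.graph.assertions.append(Assertion(
                            subject=subj.id, predicate=prop, object=cls,
                            polarity="negated", otu=otu_id,
                            stmt_index=stmt_index, order=order))
                        order += 1
                current = []
                pending = None
                continue

            new_inds: list[Individual] = []
            for item in items:
                ind = self._make_individual(item, otu_id, foreign,
                                            stmt_index, pos)
                pos += 1
                new_inds.append(ind)
            if pending is not None:
                prop, _ = pending
                for subj in current:
                    for obj in new_inds:
                        self.graph.assertions.append(Assertion(
                            subject=subj.id, predicate=prop, object=obj.id,
                            otu=otu_id, stmt_index=stmt_index, order=order))
                        order += 1
            current = new_inds
            pending = None

    def run(self) -> KnowledgeGraph:
        for otu in self.doc.otus:
            organism = self._organism(otu.otu_id)
            self.graph.otus[otu.otu_id] = OTURecord(
                otu_id=otu.otu_id,
                label=otu.label,
                taxon_id=otu.metadata.get("taxon_id", ""),
                catalog_number=otu.metadata.get("catalog_number", ""),
                parent_name_usage_id=otu.metadata.get("parent_name_usage_id", ""),
                habitat=otu.metadata.get("habitat", ""),
                organism_id=organism.id,
            )
        for otu in self.doc.otus:
            for idx, stmt in enumerate(self.doc.statements.get(otu.otu_id, [])):
                self.compile_statement(otu.otu_id, idx, stmt)
        if self.missing:
            raise CompileError(
                "unresolved terms: " + ", ".join(sorted(self.missing)))
        return self.graph


def compile_document(doc: Document, tbox: TBoxStore) -> KnowledgeGraph:
    """Compile a parsed description into its ABox knowledge graph."""
    return _Compiler(doc, tbox).run()


def resolve_cross_otu(graph: KnowledgeGraph, tag: str, foreign_otu: str) -> Individual:
    """Look up the foreign-owned individual an excluded node compiled to."""
    ind = graph.individuals.get(f"{foreign_otu}/{tag}")
    if ind is None:
        raise UnknownOTUError(
            f"no individual tagged {tag!r} owned by {foreign_otu!r}")
    return ind


# ---------------------------------------------------------------------------
# Turtle serialization (deterministic, reload-equal)
# ---------------------------------------------------------------------------

_P = PHENOC_NS


def _esc(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def _fmt_literal(v: Decimal) -> str:
    return f'"{v}"^^<http://www.w3.org/2001/XMLSchema#decimal>'


def serialize_abox(graph: KnowledgeGraph, tbox: TBoxStore) -> str:
    """Canonically ordered Turtle for an ABox graph.

    Negated assertions appear as a type assertion of a named complement
    class ``ObjectComplementOf(has_part some C)``; assertion provenance
    (owning species, statement index, in-statement order) is carried by
    reification nodes whose IRIs encode it, so a reload reconstructs the
    exact :class:`KnowledgeGraph`.
    """
    lines: list[str] = []
    lines.append("@prefix owl: <http://www.w3.org/2002/07/owl#> .")
    lines.append("@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .")
    lines.append("@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .")
    lines.append(f"@prefix phenoc: <{_P}> .")
    lines.append(f"@prefix abox: <{ABOX_NS}> .")
    lines.append("")

    for otu_id in sorted(graph.otus):
        rec = graph.otus[otu_id]
        s = f"<{ABOX_NS}{otu_id}>"
        lines.append(f"{s} a phenoc:OTU ;")
        lines.append(f'    rdfs:label "{_esc(rec.label)}" ;')
        lines.append(f"    phenoc:organism <{ABOX_NS}{rec.organism_id}> .")
        for pred, val in (("taxonID", rec.taxon_id),
                          ("catalogNumber", rec.catalog_number),
                          ("parentNameUsageID", rec.parent_name_usage_id),
                          ("habitat", rec.habitat)):
            if val:
                lines.append(f'{s} phenoc:{pred} "{_esc(val)}" .')

    for ind_id in sorted(graph.individuals):
        ind = graph.individuals[ind_id]
        lines.append(f"<{ind.iri}> a owl:NamedIndividual, <{ind.cls.iri}> .")
        lines.append(f'<{ind.iri}> phenoc:ownerOTU "{_esc(ind.owner_otu)}" .')
        if ind.skolem:
            lines.append(f'<{ind.iri}> phenoc:skolem "true" .')

    neg_seen: set[str] = set()
    for a in sorted(graph.assertions, key=Assertion.key):
        subj = graph.individuals[a.subject]
        prov = (f"{ABOX_NS}prov/{a.otu}/s{a.stmt_index}/o{a.order}")
        if a.negated:
            cls = a.object
            assert isinstance(cls, TermRef)
            neg_iri = f"{ABOX_NS}neg/{a.otu}/s{a.stmt_index}/o{a.order}"
            if neg_iri not in neg_seen:
                neg_seen.add(neg_iri)
                lines.append(f"<{neg_iri}> a owl:Class ;")
                lines.append(f"    owl:complementOf <{neg_iri}/r> .")
                lines.append(f"<{neg_iri}/r> a owl:Restriction ;")
                lines.append(f"    owl:onProperty <{a.predicate.ref.iri}> ;")
                lines.append(f"    owl:someValuesFrom <{cls.iri}> .")
            lines.append(f"<{subj.iri}> a <{neg_iri}> .")
            continue
        if isinstance(a.object, Decimal):
            obj_txt = _fmt_literal(a.object)
        else:
            obj_txt = f"<{ABOX_NS}{a.object}>"
        lines.append(f"<{subj.iri}> <{a.predicate.ref.iri}> {obj_txt} .")
        lines.append(f"<{prov}> a rdf:Statement ;")
        lines.append(f"    rdf:subject <{subj.iri}> ;")
        lines.append(f"    rdf:predicate <{a.predicate.ref.iri}> ;")
        lines.append(f"    rdf:object {obj_txt} .")
    return "\n".join(lines) + "\n"


def load_abox(text: str, tbox: TBoxStore) -> KnowledgeGraph:
    """Parse ABox Turtle produced by :func:`serialize_abox` back to a graph."""
    g = Graph()
    g.parse(data=text, format="turtle")
    return load_abox_graph(g, tbox)


def load_abox_graph(g: Graph, tbox: TBoxStore) -> KnowledgeGraph:
    kg = KnowledgeGraph()
    P = rdflib.Namespace(_P)

    for s in g.subjects(RDF.type, P.OTU):
        otu_id = str(s)[len(ABOX_NS):]
        org = g.value(s, P.organism)
        kg.otus[otu_id] = OTURecord(
            otu_id=otu_id,
            label=str(g.value(s, RDFS.label) or ""),
            taxon_id=str(g.value(s, P.taxonID) or ""),
            catalog_number=str(g.value(s, P.catalogNumber) or ""),
            parent_name_usage_id=str(g.value(s, P.parentNameUsageID) or ""),
            habitat=str(g.value(s, P.habitat) or ""),
            organism_id=str(org)[len(ABOX_NS):] if org else "",
        )

    neg_info: dict[str, tuple[PropertyDef, TermRef, str, int, int]] = {}
    for s in g.subjects(RDF.type, OWL.Class):
        iri = str(s)
        if not iri.startswith(ABOX_NS + "neg/"):
            continue
        comp = g.value(s, OWL.complementOf)
        prop_iri = str(g.value(comp, OWL.onProperty))
        filler_iri = str(g.value(comp, OWL.someValuesFrom))
        prop = tbox.properties.get(prop_iri)
        if prop is None:
            raise CompileError(f"negation uses unknown property {prop_iri}")
        filler = tbox.ref_for_iri(filler_iri)
        path = iri[len(ABOX_NS) + 4:]          # "otu/s3/o1"
        otu, spart, opart = path.split("/")
        neg_info[iri] = (prop, filler, otu, int(spart[1:]), int(opart[1:]))

    for s in g.subjects(RDF.type, OWL.NamedIndividual):
        ind_id = str(s)[len(ABOX_NS):]
        cls_iri = None
        for t in g.objects(s, RDF.type):
            t = str(t)
            if t in (str(OWL.NamedIndividual),) or t.startswith(ABOX_NS):
                continue
            cls_iri = t
        if cls_iri is None:
            raise CompileError(f"individual without class: {ind_id}")
        parts = ind_id.split("/")
        otu = parts[0]
        tag = None
        origin = (-1, -1)
        if len(parts) == 3:
            origin = (int(parts[1][1:]), int(parts[2][1:]))
        elif len(parts) == 2 and parts[1] not in ("organism",):
            tag = parts[1]
        skolem = (s, P.skolem, Literal("true")) in g
        kg.individuals[ind_id] = Individual(
            id=ind_id, cls=tbox.ref_for_iri(cls_iri), owner_otu=otu,
            tag=tag, origin=origin, skolem=skolem)

    # negated assertions
    for s in g.subjects(RDF.type, OWL.NamedIndividual):
        for t in g.objects(s, RDF.type):
            info = neg_info.get(str(t))
            if info is None:
                continue
            prop, filler, otu, stmt, order = info
            kg.assertions.append(Assertion(
                subject=str(s)[len(ABOX_NS):], predicate=prop, object=filler,
                polarity="negated", otu=otu, stmt_index=stmt, order=order))

    # positive assertions, provenance from reification IRIs
    for prov in g.subjects(RDF.type, RDF.Statement):
        path = str(prov)[len(ABOX_NS) + 5:]    # "otu/s3/o1"
        otu, spart, opart = path.split("/")
        subj = str(g.value(prov, RDF.subject))[len(ABOX_NS):]
        pred_iri = str(g.value(prov, RDF.predicate))
        prop = tbox.properties.get(pred_iri)
        if prop is None:
            raise CompileError(f"assertion uses unknown property {pred_iri}")
        obj_node = g.value(prov, RDF.object)
        obj: Union[str, Decimal]
        if isinstance(obj_node, Literal):
            obj = Decimal(str(obj_node))
        else:
            obj = str(obj_node)[len(ABOX_NS):]
        kg.assertions.append(Assertion(
            subject=subj, predicate=prop, object=obj, otu=otu,
            stmt_index=int(spart[1:]), order=int(opart[1:])))
    kg.assertions.sort(key=Assertion.key)
    return kg
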