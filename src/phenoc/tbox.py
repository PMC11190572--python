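"""TBox storage: classes, subclass/parthood axioms, properties, defined classes.

The TBox is the terminological half of a computable species description: the
class hierarchy and axioms that the assertional graph (ABox) of individuals
is typed against.  At desk scale we support the OWL fragment the toolchain
actually reasons over:

* class declarations with labels,
* named subclass axioms,
* existential restrictions ``C subClassOf (p some D)`` — used both for
  class-level parthood (``metafemur part_of some insect_leg``) and for
  "with N parts" logical definitions (``maxillary_palpus_with_4_palpomeres
  subClassOf has_part some maxillary_palpomere_I`` ... one per palpomere),
* union defined classes ``D equivalentTo (X or part_of some X)`` for
  body-region queries,
* object properties with transitivity, inverses and operator aliases,
* class disjointness.

Everything round-trips through Turtle; the serializer is deterministic
(sorted subjects, skolem-free apart from inline anonymous restrictions) so
two runs over the same store are byte-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import rdflib
from rdflib import BNode, Graph, Literal, URIRef
from rdflib.collection import Collection
from rdflib.namespace import OWL, RDF, RDFS

from .terms import (
    ALIAS_TABLE,
    DEFAULT_PREFIX_BASES,
    KNOWN_OBO_IRIS,
    PrefixMap,
    PropertyDef,
    PropertyRegistry,
    TermRef,
    TermResolutionError,
)

PHENOC_NS = "https://w3id.org/phenoc/vocab/core#"
ALIAS_PRED = URIRef(PHENOC_NS + "alias")


class TBoxError(ValueError):
    """Malformed or conflicting TBox content."""


@dataclass(frozen=True)
class DefinedClass:
    """A region-style defined class: ``X or (part_of some X)``."""

    ref: TermRef
    base: TermRef


@dataclass
class TBoxStore:
    prefixes: PrefixMap = field(default_factory=lambda: PrefixMap(DEFAULT_PREFIX_BASES))
    classes: dict[str, TermRef] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)
    subclass_axioms: set[tuple[str, str]] = field(default_factory=set)
    partof_axioms: set[tuple[str, str]] = field(default_factory=set)
    properties: PropertyRegistry = field(default_factory=PropertyRegistry)
    logical_defs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    defined_classes: dict[str, DefinedClass] = field(default_factory=dict)
    disjoint_axioms: set[tuple[str, str]] = field(default_factory=set)

    # -- construction ------------------------------------------------------

    def term(self, curie: str) -> TermRef:
        return self.prefixes.parse_curie(curie)

    def declare_class(self, ref: TermRef, label: Optional[str] = None) -> TermRef:
        existing_label = self.labels.get(ref.iri)
        self.classes.setdefault(ref.iri, ref)
        if label is not None:
            if existing_label is not None and existing_label != label:
                warnings.warn(
                    f"label conflict for {ref.curie}: keeping {existing_label!r}, "
                    f"ignoring {label!r}",
                    stacklevel=2,
                )
            else:
                self.labels[ref.iri] = label
        else:
            self.labels.setdefault(ref.iri, ref.label)
        return ref

    def _require_class(self, ref: TermRef) -> None:
        if ref.iri not in self.classes:
            raise TermResolutionError(f"class not declared: {ref.curie}")

    def add_subclass(self, child: TermRef, parent: TermRef) -> None:
        self._require_class(child)
        self._require_class(parent)
        self.subclass_axioms.add((child.iri, parent.iri))
        if self._reachable(parent.iri, child.iri, self._subclass_edges()):
            self.subclass_axioms.discard((child.iri, parent.iri))
            raise TBoxError(f"subclass cycle: {child.curie} <-> {parent.curie}")

    def add_partof(self, part: TermRef, whole: TermRef) -> None:
        self._require_class(part)
        self._require_class(whole)
        self.partof_axioms.add((part.iri, whole.iri))

    def add_logical_part(self, cls: TermRef, prop: TermRef, filler: TermRef) -> None:
        self._require_class(cls)
        self._require_class(filler)
        self.logical_defs.setdefault(cls.iri, []).append((prop.iri, filler.iri))

    def add_disjoint(self, a: TermRef, b: TermRef) -> None:
        self._require_class(a)
        self._require_class(b)
        self.disjoint_axioms.add(tuple(sorted((a.iri, b.iri))))

    def add_property(self, prop: PropertyDef) -> None:
        self.properties.add(prop)

    def add_defined_class(self, name: str, base: TermRef) -> DefinedClass:
        """Register ``name`` as the defined class ``base or part_of some base``.

        Re-registering an existing name replaces it with a warning.
        """
        if base.iri not in self.classes:
            raise TermResolutionError(
                f"defined class {name!r}: base not declared: {base.curie}"
            )
        ref = self.prefixes.resolve("phenoc", name)
        if name in self.defined_classes:
            warnings.warn(f"replacing defined class {name!r}", stacklevel=2)
        dc = DefinedClass(ref=ref, base=base)
        self.defined_classes[name] = dc
        return dc

    # -- closures ----------------------------------------------------------

    def _subclass_edges(self) -> dict[str, set[str]]:
        edges: dict[str, set[str]] = {}
        for c, d in self.subclass_axioms:
            edges.setdefault(c, set()).add(d)
        return edges

    @staticmethod
    def _reachable(src: str, dst: str, edges: dict[str, set[str]]) -> bool:
        seen, stack = {src}, [src]
        while stack:
            n = stack.pop()
            if n == dst:
                return True
            for m in edges.get(n, ()):
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        return False

    def ancestors(self, iri: str, reflexive: bool = True) -> set[str]:
        """All superclasses of ``iri`` (reflexive by default)."""
        edges = self._subclass_edges()
        out: set[str] = {iri} if reflexive else set()
        stack = [iri]
        seen = {iri}
        while stack:
            n = stack.pop()
            for m in edges.get(n, ()):
                if m not in seen:
                    seen.add(m)
                    out.add(m)
                    stack.append(m)
        return out

    def descendants(self, iri: str, reflexive: bool = True) -> set[str]:
        rev: dict[str, set[str]] = {}
        for c, d in self.subclass_axioms:
            rev.setdefault(d, set()).add(c)
        out: set[str] = {iri} if reflexive else set()
        stack, seen = [iri], {iri}
        while stack:
            n = stack.pop()
            for m in rev.get(n, ()):
                if m not in seen:
                    seen.add(m)
                    out.add(m)
                    stack.append(m)
        return out

    def region_classes(self, base_iri: str) -> set[str]:
        """Classes whose instances are entailed to lie in region ``base``.

        A class C is in the region of X when C reaches X through any
        interleaving of subclass and class-level part_of steps.  Computed as
        a reverse fixpoint from X.
        """
        rev: dict[str, set[str]] = {}
        for c, d in self.subclass_axioms:
            rev.setdefault(d, set()).add(c)
        for c, d in self.partof_axioms:
            rev.setdefault(d, set()).add(c)
        out, stack = {base_iri}, [base_iri]
        while stack:
            n = stack.pop()
            for m in rev.get(n, ()):
                if m not in out:
                    out.add(m)
                    stack.append(m)
        return out

    # -- merge -------------------------------------------------------------

    def merge(self, other: "TBoxStore") -> "TBoxStore":
        """Union axioms; first-loaded-wins for labels (ROBOT-merge style)."""
        for prefix, base in other.prefixes.bases.items():
            self.prefixes.bases.setdefault(prefix, base)
        for iri, ref in other.classes.items():
            self.declare_class(ref, other.labels.get(iri))
        self.subclass_axioms |= other.subclass_axioms
        self.partof_axioms |= other.partof_axioms
        for p in other.properties:
            if p.ref.iri not in self.properties:
                self.properties.add(p)
        for cls, axs in other.logical_defs.items():
            mine = self.logical_defs.setdefault(cls, [])
            for ax in axs:
                if ax not in mine:
                    mine.append(ax)
        for name, dc in other.defined_classes.items():
            self.defined_classes.setdefault(name, dc)
        self.disjoint_axioms |= other.disjoint_axioms
        return self

    # -- term lookup helpers ------------------------------------------------

    def ref_for_iri(self, iri: str) -> TermRef:
        if iri in self.classes:
            return self.classes[iri]
        p = self.properties.get(iri)
        if p is not None:
            return p.ref
        for dc in self.defined_classes.values():
            if dc.ref.iri == iri:
                return dc.ref
        raise TermResolutionError(f"unknown IRI: {iri}")

    def label_for(self, iri: str) -> str:
        lab = self.labels.get(iri)
        if lab is not None:
            return lab
        return self.ref_for_iri(iri).label


def standard_properties() -> PropertyRegistry:
    """The object-property registry shared by all descriptions.

    part_of is transitive; part_of/has_part are mutual inverses; the six
    operator glyphs alias the six core relations.
    """
    pm = PrefixMap(DEFAULT_PREFIX_BASES)
    reg = PropertyRegistry()

    def make(curie: str, transitive=False, inverse: Optional[str] = None,
             alias: Optional[str] = None) -> PropertyDef:
        ref = pm.parse_curie(curie)
        inv = pm.parse_curie(inverse) if inverse else None
        return PropertyDef(ref=ref, transitive=transitive, inverse=inv, alias=alias)

    reg.add(make("ro-has_part", transitive=True, inverse="ro-part_of", alias=">"))
    reg.add(make("ro-part_of", transitive=True, inverse="ro-has_part", alias="<"))
    reg.add(make("ro-has_characteristic", inverse="ro-characteristic_of", alias=">>"))
    reg.add(make("ro-characteristic_of", inverse="ro-has_characteristic", alias="<<"))
    reg.add(make("ro-increased_in_magnitude_relative_to", alias="|>|"))
    reg.add(make("ro-decreased_in_magnitude_relative_to", alias="|<|"))
    reg.add(make("ro-similar_in_magnitude_relative_to"))
    reg.add(make("ro-coincident_with"))
    reg.add(make("aism-medial_to"))
    reg.add(make("aism-lateral_to"))
    reg.add(make("aism-distal_to"))
    reg.add(make("iao-is_quality_measured_as"))
    reg.add(make("aism-has_unit"))
    reg.add(make("iao-has_measurement_value"))
    return reg


# ---------------------------------------------------------------------------
# Turtle I/O
# ---------------------------------------------------------------------------

_REVERSE_OBO = {iri: key for key, iri in KNOWN_OBO_IRIS.items()}


def _iri_to_key(iri: str, prefixes: PrefixMap) -> tuple[str, str]:
    if iri in _REVERSE_OBO:
        return _REVERSE_OBO[iri]
    best: Optional[tuple[str, str]] = None
    for prefix, base in prefixes.bases.items():
        if iri.startswith(base):
            local = iri[len(base):]
            if best is None or len(base) > len(prefixes.bases[best[0]]):
                best = (prefix, local)
    if best is None:
        raise TermResolutionError(f"IRI outside every registered namespace: {iri}")
    return best


def ref_from_iri(iri: str, prefixes: PrefixMap) -> TermRef:
    prefix, local = _iri_to_key(iri, prefixes)
    return TermRef(prefix, local, iri)


def _ttl_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def serialize_tbox(store: TBoxStore) -> str:
    """Deterministic Turtle for a :class:`TBoxStore`."""
    lines: list[str] = []
    lines.append("@prefix owl: <http://www.w3.org/2002/07/owl#> .")
    lines.append("@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .")
    lines.append(f"@prefix phenoc: <{PHENOC_NS}> .")
    for prefix in sorted(store.prefixes.bases):
        lines.append(f"@prefix ns{prefix}: <{store.prefixes.bases[prefix]}> .")
    lines.append("")

    part_of_iri = KNOWN_OBO_IRIS[("ro", "part_of")]

    for iri in sorted(store.classes):
        label = store.labels.get(iri, "")
        lines.append(f"<{iri}> a owl:Class ;")
        lines.append(f'    rdfs:label "{_ttl_escape(label)}" .')
        for c, d in sorted(store.subclass_axioms):
            if c == iri:
                lines.append(f"<{iri}> rdfs:subClassOf <{d}> .")
        for c, d in sorted(store.partof_axioms):
            if c == iri:
                lines.append(
                    f"<{iri}> rdfs:subClassOf [ a owl:Restriction ; "
                    f"owl:onProperty <{part_of_iri}> ; owl:someValuesFrom <{d}> ] ."
                )
        for prop_iri, filler_iri in sorted(store.logical_defs.get(iri, [])):
            lines.append(
                f"<{iri}> rdfs:subClassOf [ a owl:Restriction ; "
                f"owl:onProperty <{prop_iri}> ; owl:someValuesFrom <{filler_iri}> ] ."
            )
        for a, b in sorted(store.disjoint_axioms):
            if a == iri:
                lines.append(f"<{iri}> owl:disjointWith <{b}> .")

    for prop in sorted(store.properties, key=lambda p: p.ref.iri):
        lines.append(f"<{prop.ref.iri}> a owl:ObjectProperty ;")
        lines.append(f'    rdfs:label "{_ttl_escape(prop.ref.label)}" .')
        if prop.transitive:
            lines.append(f"<{prop.ref.iri}> a owl:TransitiveProperty .")
        if prop.inverse is not None:
            lines.append(f"<{prop.ref.iri}> owl:inverseOf <{prop.inverse.iri}> .")
        if prop.alias is not None:
            lines.append(f'<{prop.ref.iri}> phenoc:alias "{_ttl_escape(prop.alias)}" .')

    for name in sorted(store.defined_classes):
        dc = store.defined_classes[name]
        lines.append(f"<{dc.ref.iri}> a owl:Class ;")
        lines.append(f'    rdfs:label "{_ttl_escape(name)}" ;')
        lines.append(
            "    owl:equivalentClass [ a owl:Class ; owl:unionOf ( "
            f"<{dc.base.iri}> "
            f"[ a owl:Restriction ; owl:onProperty <{part_of_iri}> ; "
            f"owl:someValuesFrom <{dc.base.iri}> ] ) ] ."
        )

    return "\n".join(lines) + "\n"


def _parse_restriction(g: Graph, node) -> Optional[tuple[str, str]]:
    if (node, RDF.type, OWL.Restriction) not in g:
        return None
    prop = g.value(node, OWL.onProperty)
    filler = g.value(node, OWL.someValuesFrom)
    if prop is None or filler is None or not isinstance(filler, URIRef):
        return None
    return (str(prop), str(filler))


def load_tbox_graph(g: Graph, source_name: str = "<graph>",
                    prefixes: Optional[PrefixMap] = None) -> TBoxStore:
    """Build a :class:`TBoxStore` from an already parsed RDF graph."""
    pm = (prefixes or PrefixMap(DEFAULT_PREFIX_BASES)).copy()
    for prefix, ns in g.namespaces():
        if prefix.startswith("ns") and len(prefix) > 2:
            pm.bases.setdefault(prefix[2:], str(ns))
    store = TBoxStore(prefixes=pm)
    part_of_iri = KNOWN_OBO_IRIS[("ro", "part_of")]

    # properties first, so alias/inverse metadata is available
    for s in sorted(set(g.subjects(RDF.type, OWL.ObjectProperty))):
        if not isinstance(s, URIRef):
            continue
        ref = ref_from_iri(str(s), pm)
        transitive = (s, RDF.type, OWL.TransitiveProperty) in g
        inv_node = g.value(s, OWL.inverseOf)
        inverse = ref_from_iri(str(inv_node), pm) if isinstance(inv_node, URIRef) else None
        alias_node = g.value(s, ALIAS_PRED)
        alias = str(alias_node) if alias_node is not None else None
        store.add_property(PropertyDef(ref=ref, transitive=transitive,
                                       inverse=inverse, alias=alias))

    class_nodes = [s for s in set(g.subjects(RDF.type, OWL.Class))
                   if isinstance(s, URIRef)]
    union_defs: dict[str, tuple[str, str]] = {}

    for s in sorted(class_nodes):
        eq = g.value(s, OWL.equivalentClass)
        union = g.value(eq, OWL.unionOf) if eq is not None else None
        if union is not None:
            operands = list(Collection(g, union))
            named = [str(o) for o in operands if isinstance(o, URIRef)]
            if len(named) == 1:
                label = g.value(s, RDFS.label)
                union_defs[str(s)] = (str(label) if label else ref_from_iri(str(s), pm).local,
                                      named[0])
            continue
        ref = ref_from_iri(str(s), pm)
        label = g.value(s, RDFS.label)
        store.declare_class(ref, str(label) if label is not None else None)

    for s in sorted(class_nodes):
        if str(s) in union_defs:
            continue
        for o in g.objects(s, RDFS.subClassOf):
            if isinstance(o, URIRef):
                child = store.classes.get(str(s))
                parent = store.classes.get(str(o))
                if child is None or parent is None:
                    raise TBoxError(
                        f"{source_name}: subclass axiom references undeclared "
                        f"class: {s} / {o}"
                    )
                store.add_subclass(child, parent)
            else:
                rest = _parse_restriction(g, o)
                if rest is None:
                    continue
                prop_iri, filler_iri = rest
                cls_ref = store.classes[str(s)]
                filler_ref = store.classes.get(filler_iri)
                if filler_ref is None:
                    raise TBoxError(
                        f"{source_name}: restriction filler undeclared: {filler_iri}"
                    )
                if prop_iri == part_of_iri:
                    store.add_partof(cls_ref, filler_ref)
                else:
                    store.add_logical_part(cls_ref, ref_from_iri(prop_iri, pm),
                                           filler_ref)
        for o in g.objects(s, OWL.disjointWith):
            if isinstance(o, URIRef) and str(o) in store.classes:
                store.add_disjoint(store.classes[str(s)], store.classes[str(o)])

    for dc_iri, (name, base_iri) in sorted(union_defs.items()):
        base_ref = store.classes.get(base_iri)
        if base_ref is None:
            raise TBoxError(f"{source_name}: defined class base undeclared: {base_iri}")
        ref = ref_from_iri(dc_iri, pm)
        store.defined_classes[name] = DefinedClass(ref=ref, base=base_ref)
    return store


def load_tbox(paths: Sequence[str | Path]) -> TBoxStore:
    """Load and merge one or more Turtle TBox files.

    Axioms union; labels first-loaded-wins (a conflicting later label only
    warns).  An unparsable file raises with the file named.
    """
    merged: Optional[TBoxStore] = None
    for path in paths:
        path = Path(path)
        g = Graph()
        try:
            g.parse(path, format="turtle")
        except Exception as exc:  # rdflib raises several parse error types
            raise TBoxError(f"cannot parse {path}: {exc}") from exc
        store = load_tbox_graph(g, source_name=str(path))
        merged = store if merged is None else merged.merge(store)
    if merged is None:
        raise TBoxError("no TBox files given")
    return merged


def loads_tbox(text: str) -> TBoxStore:
    g = Graph()
    g.parse(data=text, format="turtle")
    return load_tbox_graph(g)
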