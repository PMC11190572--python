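"""Natural-language generation from the materialized knowledge graph.

Walks each species' assertions in authoring (statement) order, reconstructs
the parthood spine of every statement and renders one telegraphic line per
trait, in the entity-quality style of taxonomic descriptions:

* presence      ``male organism, glossa: present;``
* absence       ``male organism, posterior longitudinal hypomeral carina: absent;``
* quality       ``male organism, gena: sharp;``
* measurement   ``male organism, length = 4.5, unit: millimeter;``
* comparison    ``..., setigerous cuticular puncture: diameter smaller than
  diameter of setigerous cuticular puncture of frons``
* positional    ``..., anatomical margin coincident with cuticular groove of
  abdominal tergite VIII``
* between-species ``the length of the hind wing is smaller than that of the
  male of G. basilewskyi;``

A compatibility flag reproduces the historically truncated between-species
output (``hind wing: length;``) for regression comparison.  Term labels can
be annotated with hyperlinks to their ontology IRIs (Markdown or HTML); the
plain-text rendering carries no markup.
"""

from __future__ import annotations

import html as _html
from dataclasses import dataclass, field
from decimal import Decimal
from typing import Optional

from .compiler import Assertion, Individual, KnowledgeGraph
from .reasoner import HAS_PART_IRI, PART_OF_IRI, SKOLEM_STMT, InferredGraph
from .tbox import TBoxStore


class GenerationError(ValueError):
    pass


#: relation spellings as used in published treatments (some keep their
#: underscore, an inconsistency we preserve deliberately)
_REL_WORDS = {
    "decreased_in_magnitude_relative_to": "smaller than",
    "increased_in_magnitude_relative_to": "larger than",
    "similar_in_magnitude_relative_to": "similar in magnitude relative to",
    "medial_to": "medial_to",
    "lateral_to": "lateral_to",
    "distal_to": "distal to",
    "coincident_with": "coincident with",
}

_COMPARISON_PROPS = {
    "decreased_in_magnitude_relative_to",
    "increased_in_magnitude_relative_to",
    "similar_in_magnitude_relative_to",
}
_POSITIONAL_PROPS = {"medial_to", "lateral_to", "distal_to", "coincident_with"}

_CHAR_IRI_LOCAL = "has_characteristic"
_CHAROF_LOCAL = "characteristic_of"
_MEASURED_LOCAL = "is_quality_measured_as"
_UNIT_LOCAL = "has_unit"
_VALUE_LOCAL = "has_measurement_value"


@dataclass
class NLLine:
    locators: list[str]
    payload: str            # presence|absence|quality|measurement|comparison|
                            # between_species|positional
    text: str
    links: dict[str, str] = field(default_factory=dict)
    contributes: set[str] = field(default_factory=set)
    depth: int = 0
    terminated: bool = True  # comparison/positional lines carry no ';'


@dataclass
class NLDocument:
    otu_id: str
    header: list[str]
    lines: list[NLLine]

    def text(self) -> str:
        return "\n".join(self.header + [ln.text for ln in self.lines]) + "\n"


class _StatementView:
    """Index of one statement's assertions by subject and local name."""

    def __init__(self, assertions: list[Assertion]) -> None:
        self.assertions = sorted(assertions, key=lambda a: a.order)
        self.by_subject: dict[str, list[Assertion]] = {}
        for a in self.assertions:
            self.by_subject.setdefault(a.subject, []).append(a)

    def outgoing(self, ind_id: str, *locals_: str) -> list[Assertion]:
        return [a for a in self.by_subject.get(ind_id, [])
                if a.predicate.ref.local in locals_ and not a.negated]

    def negated_from(self, ind_id: str) -> list[Assertion]:
        return [a for a in self.by_subject.get(ind_id, []) if a.negated]


class _Generator:
    def __init__(self, inf: InferredGraph, otu_id: str,
                 legacy_asterisk: bool = False) -> None:
        if otu_id not in inf.base.otus:
            raise GenerationError(f"unknown OTU: {otu_id!r}")
        self.inf = inf
        self.graph: KnowledgeGraph = inf.base
        self.tbox: TBoxStore = inf.tbox
        self.otu_id = otu_id
        self.legacy = legacy_asterisk
        self.lines: list[NLLine] = []
        # datum values may be asserted in a later statement than the datum
        self.datum_values: dict[str, Decimal] = {
            a.subject: a.object for a in self.graph.assertions
            if isinstance(a.object, Decimal)
            and a.predicate.ref.local == _VALUE_LOCAL
        }

    # -- helpers ----------------------------------------------------------

    def _ind(self, ind_id: str) -> Individual:
        return self.graph.individuals[ind_id]

    def _label(self, ind_id: str) -> str:
        return self.tbox.label_for(self._ind(ind_id).cls.iri)

    def _link(self, ind_id: str) -> tuple[str, str]:
        ind = self._ind(ind_id)
        return (self.tbox.label_for(ind.cls.iri), ind.cls.iri)

    def _bearer_chain(self, view: _StatementView, start: str) -> list[str]:
        """Follow characteristic_of / part_of links from a quality node."""
        chain: list[str] = []
        current = start
        seen = {start}
        while True:
            nxt = view.outgoing(current, _CHAROF_LOCAL, "part_of")
            nxt = [a for a in nxt if isinstance(a.object, str)
                   and a.object not in seen]
            if not nxt:
                return chain
            current = nxt[0].object
            seen.add(current)
            chain.append(current)

    def _emit(self, locators_ids: list[str], payload: str, text: str,
              extra_ids: tuple[str, ...] = (), terminated: bool = True) -> None:
        line = NLLine(
            locators=[self._label(i) for i in locators_ids],
            payload=payload, text=text, terminated=terminated)
        for i in list(locators_ids) + list(extra_ids):
            label, iri = self._link(i)
            line.links[label] = iri
            line.contributes.add(i)
        self.lines.append(line)

    # -- payload renderers -------------------------------------------------

    def _quality_line(self, path: list[str], q: str) -> None:
        text = ", ".join(self._label(i) for i in path) + f": {self._label(q)};"
        self._emit(path, "quality", text, extra_ids=(q,))

    def _absence_line(self, path: list[str], a: Assertion) -> None:
        denied = a.object
        label = self.tbox.label_for(denied.iri)
        text = (", ".join(self._label(i) for i in path)
                + f", {label}: absent;")
        line_ids = list(path)
        line = NLLine(locators=[self._label(i) for i in line_ids] + [label],
                      payload="absence",
                      text=text)
        for i in line_ids:
            lab, iri = self._link(i)
            line.links[lab] = iri
            line.contributes.add(i)
        line.links[label] = denied.iri
        self.lines.append(line)

    def _measurement_line(self, path: list[str], q: str, datum: str,
                          view: _StatementView) -> None:
        value = self.datum_values.get(datum)
        if value is None:
            raise GenerationError(f"measurement datum {datum} has no value")
        unit_assertions = view.outgoing(datum, _UNIT_LOCAL)
        extra = [q, datum]
        if unit_assertions:
            unit_id = unit_assertions[0].object
            unit_ind = self._ind(unit_id)
            extra.append(unit_id)
            if unit_ind.cls.prefix == "unit":
                unit_label = self.tbox.label_for(unit_ind.cls.iri)
            else:
                bearers = self._bearer_chain(view, unit_id)
                unit_label = self.tbox.label_for(unit_ind.cls.iri)
                if bearers:
                    unit_label += " of " + self._label(bearers[0])
                    extra.append(bearers[0])
        else:
            unit_label = ""
        text = (", ".join(self._label(i) for i in path)
                + f", {self._label(q)} = {value}")
        text += f", unit: {unit_label};" if unit_label else ";"
        self._emit(path, "measurement", text, extra_ids=tuple(extra))

    def _comparison_line(self, path: list[str], q1: str, a: Assertion,
                         view: _StatementView) -> None:
        q2 = a.object
        rel = _REL_WORDS[a.predicate.ref.local]
        if self._ind(q2).owner_otu != self.otu_id:
            self._between_species_line(path, q1, a)
            return
        tail_ids = [q2] + self._bearer_chain(view, q2)
        tail = " of ".join(self._label(i) for i in tail_ids)
        text = (", ".join(self._label(i) for i in path)
                + f": {self._label(q1)} {rel} {tail}")
        self._emit(path, "comparison", text,
                   extra_ids=tuple([q1] + tail_ids), terminated=False)

    def _between_species_line(self, path: list[str], q1: str,
                              a: Assertion) -> None:
        q2 = a.object
        foreign_ind = self._ind(q2)
        foreign_otu = self.graph.otus.get(foreign_ind.owner_otu)
        if foreign_otu is None:
            raise GenerationError(
                f"comparison references unknown OTU {foreign_ind.owner_otu!r}")
        if self.legacy:
            text = (", ".join(self._label(i) for i in path)
                    + f": {self._label(q1)};")
            self._emit(path, "between_species", text, extra_ids=(q1,))
            return
        rel = a.predicate.ref.local
        cmp_word = {"decreased_in_magnitude_relative_to": "smaller",
                    "increased_in_magnitude_relative_to": "larger"}.get(
                        rel, "similar")
        bearer = path[-1]
        text = (f"the {self._label(q1)} of the {self._label(bearer)} is "
                f"{cmp_word} than that of the male of {foreign_otu.label};")
        self._emit(path, "between_species", text, extra_ids=(q1, q2))

    def _positional_line(self, path: list[str], a: Assertion,
                         view: _StatementView) -> None:
        rel = _REL_WORDS[a.predicate.ref.local]
        obj = a.object
        tail_ids = [obj] + self._bearer_chain(view, obj)
        tail = " of ".join(self._label(i) for i in tail_ids)
        text = ", ".join(self._label(i) for i in path) + f" {rel} {tail}"
        self._emit(path, "positional", text, extra_ids=tuple(tail_ids),
                   terminated=False)

    # -- traversal ---------------------------------------------------------

    def _walk(self, view: _StatementView, node: str, path: list[str]) -> None:
        path = path + [node]
        produced = False

        for a in view.outgoing(node, _CHAR_IRI_LOCAL):
            q = a.object
            cmp_edges = [c for c in view.by_subject.get(q, [])
                         if c.predicate.ref.local in _COMPARISON_PROPS]
            measured = view.outgoing(q, _MEASURED_LOCAL)
            if cmp_edges:
                self._comparison_line(path, q, cmp_edges[0], view)
            elif measured:
                self._measurement_line(path, q, measured[0].object, view)
            else:
                self._quality_line(path, q)
            produced = True

        for a in view.negated_from(node):
            self._absence_line(path, a)
            produced = True

        for a in self.by_local(view, node, _POSITIONAL_PROPS):
            self._positional_line(path, a, view)
            produced = True

        children = [a.object for a in view.outgoing(node, "has_part")
                    if isinstance(a.object, str)]
        for child in children:
            self._walk(view, child, path)
        if not produced and not children:
            text = ", ".join(self._label(i) for i in path) + ": present;"
            self._emit(path, "presence", text)

    @staticmethod
    def by_local(view: _StatementView, node: str,
                 locals_: set[str]) -> list[Assertion]:
        return [a for a in view.by_subject.get(node, [])
                if a.predicate.ref.local in locals_ and not a.negated]

    def run(self) -> NLDocument:
        rec = self.graph.otus[self.otu_id]
        organism_label = self.tbox.label_for(
            self._ind(rec.organism_id).cls.iri)
        header = [organism_label]
        if rec.catalog_number:
            header.append(f"Catalog Number: {rec.catalog_number}")
        header.append(f"{organism_label} has role in modeling TU denotes species")
        if rec.taxon_id:
            header.append(f"species Taxon ID: {rec.taxon_id}")
        if rec.parent_name_usage_id:
            header.append(f"species Parent Name Usage ID: "
                          f"{rec.parent_name_usage_id}")

        by_stmt: dict[int, list[Assertion]] = {}
        for a in self.graph.assertions:
            if a.otu == self.otu_id and a.stmt_index != SKOLEM_STMT:
                by_stmt.setdefault(a.stmt_index, []).append(a)

        for idx in sorted(by_stmt):
            stmt_assertions = by_stmt[idx]
            # datum-value statements render as part of the measurement line
            if all(isinstance(a.object, Decimal) for a in stmt_assertions):
                continue
            view = _StatementView(stmt_assertions)
            root = view.assertions[0].subject
            self._walk(view, root, [])

        doc = NLDocument(otu_id=self.otu_id, header=header, lines=self.lines)
        self._check_completeness(doc)
        return doc

    def _check_completeness(self, doc: NLDocument) -> None:
        covered: set[str] = set()
        for line in doc.lines:
            covered |= line.contributes
        rec = self.graph.otus[self.otu_id]
        # individuals minted by another species' statements (cross-species
        # comparisons) are narrated in that species' description instead
        local: set[str] = set()
        for a in self.graph.assertions:
            if a.otu == self.otu_id:
                local.add(a.subject)
                if isinstance(a.object, str):
                    local.add(a.object)
        for ind in self.graph.base_individuals(self.otu_id):
            if ind.id == rec.organism_id or ind.id not in local:
                continue
            if ind.id not in covered:
                raise GenerationError(
                    f"individual {ind.id} contributes to no generated line "
                    f"(orphan not caught by validation?)")


def generate(inf: InferredGraph, otu_id: str,
             legacy_asterisk: bool = False) -> NLDocument:
    """Generate the species description for one OTU."""
    return _Generator(inf, otu_id, legacy_asterisk=legacy_asterisk).run()


def render_between_species(inf: InferredGraph, assertion: Assertion) -> NLLine:
    """Render one cross-species comparison assertion as a full sentence."""
    gen = _Generator(inf, assertion.otu)
    q1_bearers = [a.subject for a in inf.base.assertions
                  if isinstance(a.object, str) and a.object == assertion.subject
                  and a.predicate.ref.local == _CHAR_IRI_LOCAL]
    if not q1_bearers:
        raise GenerationError("comparison subject has no bearer")
    gen._between_species_line([q1_bearers[0]], assertion.subject, assertion)
    return gen.lines[-1]


# ---------------------------------------------------------------------------
# Link annotation
# ---------------------------------------------------------------------------

def annotate_links(doc: NLDocument, fmt: str = "markdown") -> str:
    """Render with each term label wrapped in a hyperlink to its IRI.

    ``fmt`` is ``"markdown"``, ``"html"`` or ``"text"`` (no markup).
    """
    if fmt == "text":
        return doc.text()
    out: list[str] = list(doc.header)
    for line in doc.lines:
        text = line.text
        # two-pass sentinel substitution: longer labels first, so a label
        # that is a substring of another never corrupts an earlier link
        sentinels: dict[str, str] = {}
        for k, label in enumerate(sorted(line.links, key=len, reverse=True)):
            sentinel = f"\x00{k}\x00"
            text = text.replace(label, sentinel)
            sentinels[sentinel] = label
        for sentinel, label in sentinels.items():
            iri = line.links[label]
            if fmt == "markdown":
                repl = f"[{label}]({iri})"
            else:
                repl = f'<a href="{_html.escape(iri)}">{label}</a>'
            text = text.replace(sentinel, repl)
        out.append(text)
    body = "\n".join(out) + "\n"
    if fmt == "html":
        return "<p>\n" + body.replace("\n", "<br/>\n") + "</p>\n"
    return body
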