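"""Shape validation of the compiled ABox (pipeline gate before reasoning).

Shapes are a SHACL subset: a target class, property constraints with
``minCount`` / ``maxCount`` and an expected object class or datatype, plus
one non-core connectivity constraint (every phenotype individual must be
linked, through the assertion graph, to a species' organism — the rule
that "all phenotypes are linked to species names").  Shapes serialize to
SHACL-vocabulary Turtle so an external validator can re-run the core ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal
from typing import Optional

from .compiler import KnowledgeGraph
from .tbox import PHENOC_NS, TBoxStore

SH = "http://www.w3.org/ns/shacl#"


class ShapeDefinitionError(ValueError):
    """A shape references an unknown property or class (not a violation)."""


@dataclass(frozen=True)
class Constraint:
    path: str                       # property curie, or "otu:<field>" pseudo-path
    min_count: int = 0
    max_count: Optional[int] = None
    expected_class: Optional[str] = None     # object class curie
    expected_datatype: Optional[str] = None  # "decimal"

    def __post_init__(self) -> None:
        if self.min_count < 0 or (self.max_count is not None and self.max_count < 0):
            raise ShapeDefinitionError("counts must be non-negative")


@dataclass(frozen=True)
class Shape:
    id: str
    target_class: Optional[str] = None   # focus: individuals of this class
    target_otu: bool = False             # focus: OTU records
    connectivity: bool = False           # species-linkage rule
    constraints: tuple[Constraint, ...] = ()


@dataclass(frozen=True)
class Violation:
    shape_id: str
    focus: str
    constraint: str
    message: str


@dataclass
class ValidationReport:
    conforms: bool
    violations: list[Violation]


def default_shapes() -> list[Shape]:
    """The shapes every compiled description must satisfy.

    (a) every non-organism individual is connected to a species organism;
    (b) every species record carries a taxon identifier;
    (c) every species record carries a voucher catalog number;
    (d) a measurement datum has exactly one value and at least one unit.
    """
    return [
        Shape(id="species-linkage", connectivity=True),
        Shape(id="otu-taxon-id", target_otu=True,
              constraints=(Constraint(path="otu:taxon_id", min_count=1),)),
        Shape(id="organism-catalog-number", target_otu=True,
              constraints=(Constraint(path="otu:catalog_number", min_count=1),)),
        Shape(id="measurement-datum", target_class="iao-measurement_datum",
              constraints=(
                  Constraint(path="iao-has_measurement_value", min_count=1,
                             max_count=1, expected_datatype="decimal"),
                  Constraint(path="aism-has_unit", min_count=1),
              )),
    ]


def _connected_ids(graph: KnowledgeGraph) -> set[str]:
    """Individuals reachable (undirected) from any organism individual."""
    adj: dict[str, set[str]] = {}
    for a in graph.assertions:
        if a.negated or not isinstance(a.object, str):
            continue
        adj.setdefault(a.subject, set()).add(a.object)
        adj.setdefault(a.object, set()).add(a.subject)
    seen: set[str] = set()
    stack = [rec.organism_id for rec in graph.otus.values() if rec.organism_id]
    seen.update(stack)
    while stack:
        n = stack.pop()
        for m in adj.get(n, ()):
            if m not in seen:
                seen.add(m)
                stack.append(m)
    return seen


def validate(graph: KnowledgeGraph, shapes: list[Shape],
             tbox: TBoxStore) -> ValidationReport:
    """Check every focus node of every shape; report is deterministic."""
    violations: list[Violation] = []

    for shape in shapes:
        if shape.connectivity:
            connected = _connected_ids(graph)
            organisms = {rec.organism_id for rec in graph.otus.values()}
            for ind_id in sorted(graph.individuals):
                if ind_id in organisms:
                    continue
                if ind_id not in connected:
                    violations.append(Violation(
                        shape.id, ind_id, "connectivity",
                        f"individual {ind_id} is not linked to any species "
                        f"organism"))
            continue

        if shape.target_otu:
            for otu_id in sorted(graph.otus):
                rec = graph.otus[otu_id]
                for c in shape.constraints:
                    if not c.path.startswith("otu:"):
                        raise ShapeDefinitionError(
                            f"shape {shape.id}: OTU shape path must be "
                            f"otu:<field>, got {c.path!r}")
                    value = getattr(rec, c.path[4:], None)
                    if value is None:
                        raise ShapeDefinitionError(
                            f"shape {shape.id}: unknown OTU field {c.path!r}")
                    n = 1 if value else 0
                    if n < c.min_count:
                        violations.append(Violation(
                            shape.id, otu_id, f"minCount({c.path})",
                            f"species {otu_id} lacks {c.path[4:]}"))
            continue

        assert shape.target_class is not None
        try:
            target_ref = tbox.term(shape.target_class)
        except Exception as exc:
            raise ShapeDefinitionError(
                f"shape {shape.id}: unknown target class "
                f"{shape.target_class!r}") from exc
        target_desc = tbox.descendants(target_ref.iri)

        for c in shape.constraints:
            prop = tbox.properties.by_curie(c.path)
            if prop is None:
                raise ShapeDefinitionError(
                    f"shape {shape.id}: unknown property {c.path!r}")

        for ind_id in sorted(graph.individuals):
            ind = graph.individuals[ind_id]
            if ind.cls.iri not in target_desc:
                continue
            for c in shape.constraints:
                prop = tbox.properties.by_curie(c.path)
                values = [a.object for a in graph.assertions
                          if a.subject == ind_id and not a.negated
                          and a.predicate.ref.iri == prop.ref.iri]
                if len(values) < c.min_count:
                    violations.append(Violation(
                        shape.id, ind_id, f"minCount({c.path})",
                        f"{ind_id} has {len(values)} < {c.min_count} "
                        f"values for {c.path}"))
                if c.max_count is not None and len(values) > c.max_count:
                    violations.append(Violation(
                        shape.id, ind_id, f"maxCount({c.path})",
                        f"{ind_id} has {len(values)} > {c.max_count} "
                        f"values for {c.path}"))
                if c.expected_datatype == "decimal":
                    for v in values:
                        if not isinstance(v, Decimal):
                            violations.append(Violation(
                                shape.id, ind_id, f"datatype({c.path})",
                                f"{ind_id}: value {v!r} is not a decimal"))
                if c.expected_class is not None:
                    exp = tbox.term(c.expected_class)
                    allowed = tbox.descendants(exp.iri)
                    for v in values:
                        if isinstance(v, str):
                            obj = graph.individuals.get(v)
                            if obj is not None and obj.cls.iri not in allowed:
                                violations.append(Violation(
                                    shape.id, ind_id, f"class({c.path})",
                                    f"{ind_id}: object {v} is not a "
                                    f"{c.expected_class}"))

    violations.sort(key=lambda v: (v.shape_id, v.focus, v.constraint))
    return ValidationReport(conforms=not violations, violations=violations)


# ---------------------------------------------------------------------------
# SHACL Turtle serialization
# ---------------------------------------------------------------------------

def serialize_shapes(shapes: list[Shape], tbox: TBoxStore) -> str:
    """SHACL-compatible Turtle for the shape set.

    Core property shapes use the standard vocabulary; the connectivity rule
    and the OTU pseudo-paths are annotated in the project namespace since
    core SHACL cannot express them.
    """
    lines = [
        f"@prefix sh: <{SH}> .",
        f"@prefix phenoc: <{PHENOC_NS}> .",
        "@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .",
        "",
    ]
    base = PHENOC_NS + "shape/"
    for shape in shapes:
        s = f"<{base}{shape.id}>"
        lines.append(f"{s} a sh:NodeShape .")
        if shape.connectivity:
            lines.append(f'{s} phenoc:connectedToOrganism "true" .')
            continue
        if shape.target_otu:
            lines.append(f"{s} sh:targetClass phenoc:OTU .")
        elif shape.target_class:
            lines.append(f"{s} sh:targetClass <{tbox.term(shape.target_class).iri}> .")
        for k, c in enumerate(shape.constraints):
            p = f"<{base}{shape.id}/c{k}>"
            lines.append(f"{s} sh:property {p} .")
            if c.path.startswith("otu:"):
                lines.append(f'{p} sh:path phenoc:{c.path[4:]} .')
            else:
                lines.append(f"{p} sh:path <{tbox.term(c.path).iri}> .")
            if c.min_count:
                lines.append(f"{p} sh:minCount {c.min_count} .")
            if c.max_count is not None:
                lines.append(f"{p} sh:maxCount {c.max_count} .")
            if c.expected_datatype:
                lines.append(f"{p} sh:datatype xsd:{c.expected_datatype} .")
            if c.expected_class:
                lines.append(f"{p} sh:class <{tbox.term(c.expected_class).iri}> .")
    return "\n".join(lines) + "\n"


def report_to_dict(report: ValidationReport) -> dict:
    return {
        "conforms": report.conforms,
        "violations": [
            {"shape": v.shape_id, "focus": v.focus,
             "constraint": v.constraint, "message": v.message}
            for v in report.violations
        ],
    }
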