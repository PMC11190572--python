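"""Semantic count queries over the materialized knowledge graph.

Two preset families mirror the published analysis:

* **characteristics** — the number of individuals per species classified
  under each of the quality parents colour, shape, size and texture;
* **regions** — the number of individuals per species belonging to one of
  the four body-region defined classes (head / thorax / abdomen / leg,
  each "X or part_of some X").

Counts cover compiler-minted individuals owned by each species; reasoner
skolems are excluded by default (a flag includes them).  An export bundle
writes the inferred graph as Turtle plus equivalent SPARQL texts so an
external engine reproduces the counts exactly.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import rdflib

from .reasoner import InferredGraph, serialize_inferred
from .tbox import PHENOC_NS

CHARACTERISTIC_PRESET = ["pato-colour", "pato-shape", "pato-size", "pato-texture"]
REGION_PRESET = ["head_or_part", "thorax_or_part", "abdomen_or_part", "leg_or_part"]


class QueryError(ValueError):
    pass


@dataclass
class QueryResult:
    rows: list[tuple[str, str, int]]       # (class label, otu id, count)
    query_id: str = ""
    timestamp: str = ""
    graph_hash: str = ""
    metadata: dict = field(default_factory=dict)

    def count(self, class_label: str, otu: str) -> int:
        for lab, o, n in self.rows:
            if lab == class_label and o == otu:
                return n
        raise KeyError((class_label, otu))

    def to_table(self) -> dict[str, dict[str, int]]:
        """Nested mapping: class label -> otu -> count."""
        table: dict[str, dict[str, int]] = {}
        for lab, otu, n in self.rows:
            table.setdefault(lab, {})[otu] = n
        return table

    def to_tsv(self) -> str:
        otus = sorted({o for _, o, _ in self.rows})
        table = self.to_table()
        lines = ["\t".join(["entity"] + otus)]
        for lab in table:
            lines.append("\t".join([lab] + [str(table[lab].get(o, 0))
                                            for o in otus]))
        return "\n".join(lines) + "\n"

    def to_json(self) -> str:
        return json.dumps(
            {"query": self.query_id, "timestamp": self.timestamp,
             "graph_hash": self.graph_hash, "table": self.to_table()},
            indent=2, sort_keys=True)


def _graph_hash(inf: InferredGraph) -> str:
    from .compiler import serialize_abox
    return hashlib.sha256(
        serialize_abox(inf.base, inf.tbox).encode()).hexdigest()[:16]


def _result(inf: InferredGraph, query_id: str,
            rows: list[tuple[str, str, int]]) -> QueryResult:
    return QueryResult(
        rows=rows, query_id=query_id,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        graph_hash=_graph_hash(inf))


def count_by_class(inf: InferredGraph, classes: Sequence[str],
                   otus: Optional[Sequence[str]] = None,
                   include_skolems: bool = False) -> QueryResult:
    """Individuals per species whose inferred types include each class.

    ``classes`` are term curies; subclass instances count through the
    materialized type closure.
    """
    otu_ids = list(otus) if otus is not None else sorted(inf.base.otus)
    rows: list[tuple[str, str, int]] = []
    for curie in classes:
        ref = inf.tbox.term(curie)
        if ref.iri not in inf.tbox.classes:
            raise QueryError(f"unknown class: {curie}")
        label = inf.tbox.label_for(ref.iri)
        for otu in otu_ids:
            n = sum(
                1 for ind in inf.base.individuals.values()
                if ind.owner_otu == otu
                and (include_skolems or not ind.skolem)
                and ref.iri in inf.types_of(ind.id)
            )
            rows.append((label, otu, n))
    return _result(inf, "count_by_class", rows)


def count_by_region(inf: InferredGraph,
                    regions: Optional[Sequence[str]] = None,
                    otus: Optional[Sequence[str]] = None,
                    include_skolems: bool = False) -> QueryResult:
    """Individuals per species in each body-region defined class."""
    region_names = list(regions) if regions is not None else REGION_PRESET
    otu_ids = list(otus) if otus is not None else sorted(inf.base.otus)
    rows: list[tuple[str, str, int]] = []
    for name in region_names:
        if name not in inf.tbox.defined_classes:
            raise QueryError(f"unknown defined class: {name}")
        ext = inf.defined_extensions.get(name, set())
        for otu in otu_ids:
            n = sum(
                1 for ind_id in ext
                if (ind := inf.base.individuals[ind_id]).owner_otu == otu
                and (include_skolems or not ind.skolem)
            )
            rows.append((name, otu, n))
    return _result(inf, "count_by_region", rows)


# ---------------------------------------------------------------------------
# SPARQL export / cross-engine check
# ---------------------------------------------------------------------------

_SPARQL_TEMPLATE = """\
PREFIX phenoc: <{ns}>
SELECT ?otu (COUNT(DISTINCT ?i) AS ?n) WHERE {{
  ?i a <{cls}> ;
     phenoc:ownerOTU ?otu .
  FILTER NOT EXISTS {{ ?i phenoc:skolem "true" }}
}}
GROUP BY ?otu
ORDER BY ?otu
"""


def sparql_for_class(cls_iri: str) -> str:
    return _SPARQL_TEMPLATE.format(ns=PHENOC_NS, cls=cls_iri)


def run_sparql_counts(ttl_text: str, query: str) -> dict[str, int]:
    """Execute one exported count query with an independent SPARQL engine."""
    g = rdflib.Graph()
    g.parse(data=ttl_text, format="turtle")
    return {str(row[0]): int(row[1]) for row in g.query(query)}


def export_sparql_bundle(inf: InferredGraph, outdir: str | Path,
                         presets: Sequence[str] = ("characteristics", "regions"),
                         ) -> dict[str, Path]:
    """Write the inferred Turtle plus the preset SPARQL query texts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    ttl = serialize_inferred(inf)
    graph_path = outdir / "inferred.ttl"
    graph_path.write_text(ttl, encoding="utf-8")
    files["graph"] = graph_path
    for preset in presets:
        if preset == "characteristics":
            targets = [(c.split("-", 1)[1], inf.tbox.term(c).iri)
                       for c in CHARACTERISTIC_PRESET]
        elif preset == "regions":
            targets = [(name, inf.tbox.defined_classes[name].ref.iri)
                       for name in REGION_PRESET]
        else:
            raise QueryError(f"unknown preset: {preset}")
        for name, iri in targets:
            path = outdir / f"{preset}_{name}.rq"
            path.write_text(sparql_for_class(iri), encoding="utf-8")
            files[f"{preset}:{name}"] = path
    return files
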