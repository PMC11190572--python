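"""Bundled fixture vocabulary.

``build_fixture_ontology`` materializes the curated mini-TBox shipped in
``data/fixture_tbox.yaml``.  It covers every term used by the example
statements and the four re-encoded species descriptions, a quality spine
(colour / shape / size / texture under a quality root), body-region
parthood chains (head / thorax / abdomen / leg) and the "with N parts"
logical definitions that the reasoner skolemizes.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .tbox import TBoxStore, standard_properties


def _data_text(name: str) -> str:
    return resources.files("phenoc.data").joinpath(name).read_text(encoding="utf-8")


def build_fixture_ontology() -> TBoxStore:
    """Deterministic mini-TBox standing in for the production ontologies."""
    spec = yaml.safe_load(_data_text("fixture_tbox.yaml"))
    store = TBoxStore()
    store.properties = standard_properties()

    entries = spec.get("classes", {})
    for curie in entries:
        store.declare_class(store.term(curie))
    for curie, opts in entries.items():
        opts = opts or {}
        ref = store.term(curie)
        if opts.get("subclass"):
            store.add_subclass(ref, store.term(opts["subclass"]))
        if opts.get("part_of"):
            store.add_partof(ref, store.term(opts["part_of"]))

    has_part = store.term("ro-has_part")
    for curie, fillers in (spec.get("logical_defs") or {}).items():
        cls = store.term(curie)
        for filler in fillers:
            store.add_logical_part(cls, has_part, store.term(filler))

    for name, base in (spec.get("defined_classes") or {}).items():
        store.add_defined_class(name, store.term(base))

    for a, b in spec.get("disjoint") or []:
        store.add_disjoint(store.term(a), store.term(b))
    return store


def load_defined_classes(store: TBoxStore, text: str) -> None:
    """Apply a small YAML spec of defined classes (``name: base-curie``)."""
    spec = yaml.safe_load(text) or {}
    for name, base in spec.items():
        store.add_defined_class(name, store.term(base))
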