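"""Materialization: closures, skolemization, defined classes, clashes.

The parthood closure and defined-class extensions are checked against
naive fixpoint oracles on randomly generated graphs.
"""

import random

import pytest

from phenoc.compiler import Assertion, Individual, KnowledgeGraph, OTURecord
from phenoc.parser import parse_document
from phenoc.compiler import compile_document
from phenoc.reasoner import (check_consistency, classify_into, materialize,
                             transitive_closure)


def compile_src(src: str, tbox):
    return compile_document(parse_document(src, "title: t"), tbox)


def _doc(body: str) -> str:
    return f'otu sp_a {{ taxon_id = "t" catalog_number = "c"\n{body}\n}}'


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def oracle_closure(edges):
    """Fixpoint matrix closure, independent of the DFS implementation."""
    reach = {a: {b} for a, b in edges}
    for a, b in edges:
        reach.setdefault(a, set()).add(b)
    changed = True
    while changed:
        changed = False
        for a in list(reach):
            new = set()
            for b in reach[a]:
                new |= reach.get(b, set())
            if not new <= reach[a]:
                reach[a] |= new
                changed = True
    return reach


def oracle_defined_extension(inf, base_iri):
    """Naive member test straight from the union-rule semantics."""
    region = inf.tbox.region_classes(base_iri)
    out = set()
    for ind_id in inf.base.individuals:
        scope = {ind_id} | inf.part_closure.get(ind_id, set())
        for w in scope:
            if inf.inferred_types.get(w, set()) & region:
                out.add(ind_id)
                break
    return out


def random_graph(tbox, rng, n_nodes=30):
    classes = sorted(tbox.classes)
    kg = KnowledgeGraph()
    kg.otus["sp_r"] = OTURecord(otu_id="sp_r", organism_id="sp_r/organism")
    part_of = tbox.properties.by_curie("ro-part_of")
    has_part = tbox.properties.by_curie("ro-has_part")
    ids = []
    for k in range(n_nodes):
        cls_iri = rng.choice(classes)
        ind = Individual(id=f"sp_r/n{k}", cls=tbox.classes[cls_iri],
                         owner_otu="sp_r")
        kg.individuals[ind.id] = ind
        ids.append(ind.id)
    for _ in range(n_nodes):
        a, b = rng.choice(ids), rng.choice(ids)
        if a == b:
            continue
        prop = rng.choice([part_of, has_part])
        kg.assertions.append(Assertion(subject=a, predicate=prop, object=b,
                                       otu="sp_r", stmt_index=0))
    return kg


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def test_subclass_type_closure(tbox):
    kg = compile_src(_doc("uberon-male_organism > aism-gena >> pato-red_brown;"),
                     tbox)
    inf = materialize(kg, tbox)
    quality = [i for i in kg.individuals.values()
               if i.cls.local == "red_brown"][0]
    types = {tbox.label_for(t) for t in inf.types_of(quality.id)}
    assert {"red brown", "colour", "quality"} <= types


def test_part_closure_transitive_through_inversion(tbox):
    kg = compile_src(_doc(
        "uberon-male_organism > aism-antenna > aism-antennal_club "
        "> aism-flagellomere_5;"), tbox)
    inf = materialize(kg, tbox)
    flag = [i for i in kg.individuals.values()
            if i.cls.local == "flagellomere_5"][0]
    wholes = {kg.individuals[w].cls.local for w in inf.wholes_of(flag.id)}
    assert wholes == {"antennal_club", "antenna", "male_organism"}


def test_skolemization_mints_one_part_per_axiom(tbox):
    kg = compile_src(_doc(
        "uberon-male_organism > aism-maxillary_palpus_with_4_palpomeres;"), tbox)
    inf = materialize(kg, tbox)
    palpus = [i for i in kg.individuals.values()
              if i.cls.local.startswith("maxillary_palpus")][0]
    sk = [s for s in inf.skolems if s.id.startswith(palpus.id + "/skolem/")]
    assert len(sk) == 4
    assert {s.cls.local for s in sk} == {
        "maxillary_palpomere_I", "maxillary_palpomere_II",
        "maxillary_palpomere_III", "maxillary_palpomere_IV"}
    # skolem parts are parts of the palpus and classified under the head
    heads = classify_into(inf, "head_or_part")
    for s in sk:
        assert palpus.id in inf.wholes_of(s.id)
        assert s.id in heads


def test_skolem_suppressed_by_asserted_part(tbox):
    kg = compile_src(_doc(
        "uberon-male_organism > aism-maxillary_palpus_with_4_palpomeres:id-mp "
        "> aism-maxillary_palpomere_I;"), tbox)
    inf = materialize(kg, tbox)
    sk_locals = {s.cls.local for s in inf.skolems}
    assert "maxillary_palpomere_I" not in sk_locals
    assert len([s for s in inf.skolems
                if s.id.startswith("sp_a/id-mp/skolem/")]) == 3


def test_materialization_idempotent(golden_inferred, tbox):
    again = materialize(golden_inferred.base, tbox)
    assert again.skolems == []
    assert len(again.base.individuals) == len(golden_inferred.base.individuals)
    assert again.inferred_types == golden_inferred.inferred_types
    assert again.part_closure == golden_inferred.part_closure


def test_skolemization_deterministic(tbox):
    kg1 = compile_src(_doc(
        "uberon-male_organism > aism-protarsus_with_5_protarsomeres;"), tbox)
    inf1 = materialize(kg1, tbox)
    inf2 = materialize(compile_src(_doc(
        "uberon-male_organism > aism-protarsus_with_5_protarsomeres;"), tbox),
        tbox)
    assert sorted(s.id for s in inf1.skolems) == sorted(s.id for s in inf2.skolems)


def test_defined_class_membership_via_class_level_parthood(tbox):
    # antenna individual with no head individual asserted is still
    # classified under the head region
    kg = compile_src(_doc("uberon-male_organism > aism-antenna >> pato-elongated;"),
                     tbox)
    inf = materialize(kg, tbox)
    antenna = [i for i in kg.individuals.values() if i.cls.local == "antenna"][0]
    assert antenna.id in classify_into(inf, "head_or_part")
    quality = [i for i in kg.individuals.values() if i.cls.local == "elongated"][0]
    assert quality.id not in classify_into(inf, "head_or_part")


def test_base_class_instance_is_member_and_isolated_is_not(tbox):
    kg = compile_src(_doc("uberon-male_organism > aism-insect_head;"), tbox)
    inf = materialize(kg, tbox)
    head = [i for i in kg.individuals.values() if i.cls.local == "insect_head"][0]
    assert head.id in classify_into(inf, "head_or_part")
    organism = kg.otus["sp_a"].organism_id
    assert organism not in classify_into(inf, "head_or_part")


def test_unknown_defined_class_raises(golden_inferred):
    with pytest.raises(KeyError):
        classify_into(golden_inferred, "no_such_region")


def test_part_closure_and_extensions_equal_oracles_on_random_graphs(tbox):
    rng = random.Random(20240613)
    for trial in range(200):
        kg = random_graph(tbox, rng, n_nodes=rng.randint(5, 50))
        inf = materialize(kg, tbox)
        from phenoc.reasoner import _direct_part_edges
        edges = _direct_part_edges(inf.base)
        expect = oracle_closure(edges)
        got = {k: v for k, v in inf.part_closure.items() if v}
        expect = {k: v for k, v in expect.items() if v}
        assert got == expect, trial
        for name, dc in tbox.defined_classes.items():
            assert classify_into(inf, name) \
                == oracle_defined_extension(inf, dc.base.iri), (trial, name)


def test_transitive_closure_handles_cycles():
    closure = transitive_closure({("a", "b"), ("b", "c"), ("c", "a")})
    assert closure["a"] == {"a", "b", "c"}


def test_absence_clash_detected(tbox):
    kg = compile_src(_doc(
        "uberon-male_organism > aism-protibia:id-p !> "
        "aism-dorsal_protibial_cuticular_tooth_4;\n"
        "uberon-male_organism > aism-protibia:id-p > "
        "aism-dorsal_protibial_cuticular_tooth_4;"), tbox)
    inf = materialize(kg, tbox)
    ok, clashes = check_consistency(inf)
    assert not ok
    assert clashes[0].kind == "absence"
    assert clashes[0].triples  # minimal responsible set reported


def test_absence_alone_is_consistent(tbox):
    kg = compile_src(_doc(
        "uberon-male_organism > aism-protibia !> "
        "aism-dorsal_protibial_cuticular_tooth_4;"), tbox)
    assert materialize(kg, tbox).consistent


def test_disjoint_classes_clash(tbox):
    # one quality individual typed by both members of a disjoint pair
    kg = compile_src(_doc("uberon-male_organism > aism-gena >> pato-red;"), tbox)
    quality = [i for i in kg.individuals.values() if i.cls.local == "red"][0]
    yellow = tbox.term("pato-yellow")
    # the description language cannot type one individual twice, so the
    # second type assertion is injected at the inferred level
    inf = materialize(kg, tbox)
    inf.inferred_types[quality.id] |= tbox.ancestors(yellow.iri)
    ok, clashes = check_consistency(inf)
    assert not ok and clashes[0].kind == "disjoint"
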