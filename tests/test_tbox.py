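"""Vocabulary store: loading, merging, closures, defined classes."""

import pytest

from phenoc.tbox import (TBoxError, TBoxStore, load_tbox, loads_tbox,
                         serialize_tbox, standard_properties)
from phenoc.terms import ALIAS_TABLE, TermResolutionError


def test_fixture_round_trips_through_turtle(tbox):
    ttl = serialize_tbox(tbox)
    back = loads_tbox(ttl)
    assert back.classes.keys() == tbox.classes.keys()
    assert back.subclass_axioms == tbox.subclass_axioms
    assert back.partof_axioms == tbox.partof_axioms
    assert back.disjoint_axioms == tbox.disjoint_axioms
    assert {k: sorted(v) for k, v in back.logical_defs.items()} \
        == {k: sorted(v) for k, v in tbox.logical_defs.items()}
    assert set(back.defined_classes) == set(tbox.defined_classes)
    assert serialize_tbox(back) == ttl


def test_merge_is_idempotent_union(tbox, tmp_path):
    ttl = serialize_tbox(tbox)
    a = tmp_path / "a.ttl"
    b = tmp_path / "b.ttl"
    a.write_text(ttl)
    b.write_text(ttl)
    merged = load_tbox([a, b])
    assert merged.classes.keys() == tbox.classes.keys()
    assert merged.subclass_axioms == tbox.subclass_axioms


def test_merge_label_conflict_keeps_first(tmp_path):
    common = (
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .\n"
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .\n"
        "@prefix nsaism: <https://w3id.org/phenoc/vocab/aism#> .\n"
    )
    a = tmp_path / "a.ttl"
    a.write_text(common + 'nsaism:pronotum a owl:Class ; rdfs:label "pronotum" .\n')
    b = tmp_path / "b.ttl"
    b.write_text(common + 'nsaism:pronotum a owl:Class ; rdfs:label "PRONOTUM!" .\n')
    with pytest.warns(UserWarning, match="label conflict"):
        merged = load_tbox([a, b])
    ref = merged.term("aism-pronotum")
    assert len([i for i in merged.classes if i == ref.iri]) == 1
    assert merged.labels[ref.iri] == "pronotum"


def test_unparsable_file_names_the_file(tmp_path):
    bad = tmp_path / "bad.ttl"
    bad.write_text("this is } not turtle")
    with pytest.raises(TBoxError, match="bad.ttl"):
        load_tbox([bad])


def test_part_of_declared_transitive_with_inverse(tbox):
    part_of = tbox.properties.by_curie("ro-part_of")
    has_part = tbox.properties.by_curie("ro-has_part")
    assert part_of.transitive
    assert part_of.inverse.iri == has_part.ref.iri
    assert has_part.inverse.iri == part_of.ref.iri


def test_alias_table_is_bijective_on_six_glyphs():
    reg = standard_properties()
    seen = {}
    for glyph in ALIAS_TABLE:
        prop = reg.by_alias(glyph)
        assert prop is not None, glyph
        seen[glyph] = prop.ref.iri
    assert len(set(seen.values())) == len(ALIAS_TABLE) == 6


def test_subclass_closure_acyclic_and_reflexive(tbox):
    for iri in tbox.classes:
        anc = tbox.ancestors(iri)
        assert iri in anc
        # acyclicity: no distinct ancestor also has iri as strict ancestor
        for a in anc - {iri}:
            assert iri not in tbox.ancestors(a, reflexive=False)


def test_subclass_cycle_rejected(tbox):
    a = tbox.term("pato-colour")
    b = tbox.term("pato-quality")
    with pytest.raises(TBoxError, match="cycle"):
        tbox.add_subclass(b, a)  # quality already above colour
    # store unchanged
    assert (b.iri, a.iri) not in tbox.subclass_axioms


def test_region_closure_follows_subclass_and_parthood(tbox):
    head = tbox.term("aism-insect_head").iri
    region = tbox.region_classes(head)
    # chain: flagellomere part_of antennal club part_of antenna part_of head
    assert tbox.term("aism-flagellomere_5").iri in region
    # subclass step: antenna_with_9_antennomeres subClassOf antenna
    assert tbox.term("aism-antenna_with_9_antennomeres").iri in region
    assert tbox.term("aism-protibia").iri not in region


def test_add_defined_class_registers_and_replaces():
    from phenoc.fixture import build_fixture_ontology
    store = build_fixture_ontology()
    dc = store.add_defined_class("head_or_part_2", store.term("aism-insect_head"))
    assert dc.base.curie == "aism-insect_head"
    with pytest.warns(UserWarning, match="replacing"):
        store.add_defined_class("head_or_part_2", store.term("aism-insect_head"))


def test_add_defined_class_unknown_base():
    store = TBoxStore()
    with pytest.raises(TermResolutionError):
        store.add_defined_class("x_or_part", store.term("aism-nonexistent_thing"))


def test_fixture_contains_printed_anatomy(tbox):
    # protibia is placed on the insect leg; tooth classes hang off it
    leg = tbox.term("aism-insect_leg").iri
    assert (tbox.term("aism-protibia").iri, leg) in tbox.partof_axioms
    # colour parent covers the printed colour qualities
    colour = tbox.term("pato-colour").iri
    assert colour in tbox.ancestors(tbox.term("pato-red").iri)
    # one existential part axiom per palpomere
    defs = tbox.logical_defs[tbox.term("aism-maxillary_palpus_with_4_palpomeres").iri]
    assert len(defs) == 4
    fillers = {f for _, f in defs}
    assert tbox.term("aism-maxillary_palpomere_IV").iri in fillers
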