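"""ABox compilation: identity rules, exclusion, negation, Turtle round-trip."""

import pytest

from phenoc.compiler import (CompileError, TagConflictError, UnknownOTUError,
                             compile_document, load_abox, resolve_cross_otu,
                             serialize_abox)
from phenoc.parser import parse_document
from phenoc.terms import TermRef


def _doc(body: str, extra_otus: str = "") -> str:
    return (f'otu sp_a {{ taxon_id = "t" catalog_number = "c"\n{body}\n}}\n'
            + extra_otus)


def compile_src(src: str, tbox):
    return compile_document(parse_document(src, "title: t"), tbox)


def test_node_list_distributes_incoming_edge(tbox):
    kg = compile_src(_doc(
        "uberon-male_organism > aism-protibia > "
        "(aism-dorsal_protibial_cuticular_tooth_1, "
        "aism-dorsal_protibial_cuticular_tooth_2, "
        "aism-dorsal_protibial_cuticular_tooth_3);"), tbox)
    protibia = [i for i in kg.individuals.values()
                if i.cls.local == "protibia"][0]
    teeth = [a for a in kg.assertions
             if a.subject == protibia.id and not a.negated
             and a.predicate.ref.local == "has_part"]
    assert len(teeth) == 3
    tooth_inds = {kg.individuals[a.object].cls.local for a in teeth}
    assert tooth_inds == {f"dorsal_protibial_cuticular_tooth_{k}" for k in (1, 2, 3)}


def test_tagged_datum_merges_across_statements(tbox):
    kg = compile_src(_doc(
        "uberon-male_organism >> pato-length .iao-is_quality_measured_as "
        "iao-measurement_datum:md-1 .aism-has_unit unit-millimeter;\n"
        "iao-measurement_datum:md-1 .iao-has_measurement_value 4.5;"), tbox)
    datums = [i for i in kg.individuals.values()
              if i.cls.local == "measurement_datum"]
    assert len(datums) == 1
    values = [a.object for a in kg.assertions
              if a.subject == datums[0].id
              and a.predicate.ref.local == "has_measurement_value"]
    assert [str(v) for v in values] == ["4.5"]


def test_untagged_repeats_are_distinct_individuals(tbox):
    kg = compile_src(_doc(
        "uberon-male_organism > aism-pronotum >> pato-convex;\n"
        "uberon-male_organism > aism-pronotum >> pato-ovate;"), tbox)
    pronota = [i for i in kg.individuals.values() if i.cls.local == "pronotum"]
    assert len(pronota) == 2


def test_organism_class_always_merges_to_one_individual(tbox):
    kg = compile_src(_doc(
        "uberon-male_organism >> pato-ovate;\n"
        "uberon-male_organism > aism-pronotum >> pato-width |>| pato-width "
        "<< colao-elytron < uberon-male_organism;"), tbox)
    organisms = [i for i in kg.individuals.values()
                 if i.cls.local == "male_organism"]
    assert len(organisms) == 1


def test_excluded_nodes_belong_to_foreign_otu(tbox):
    src = _doc(
        "uberon-male_organism::sp_a > aism-hind_wing >> pato-length |<| "
        "pato-length:id-q[exclude = True] << aism-hind_wing:id-w[exclude = True] "
        "< uberon-male_organism:sp_b[exclude = True];",
        'otu sp_b { taxon_id = "u" catalog_number = "d" }')
    kg = compile_src(src, tbox)
    foreign = {i.id for i in kg.individuals.values() if i.owner_otu == "sp_b"}
    assert foreign == {"sp_b/organism", "sp_b/id-q", "sp_b/id-w"}
    # focal tally excludes the foreign nodes
    assert {i.cls.local for i in kg.base_individuals("sp_a")} \
        == {"male_organism", "hind_wing", "length"}
    wing = resolve_cross_otu(kg, "id-w", "sp_b")
    assert wing.cls.local == "hind_wing"


def test_exclude_without_binding_or_on_focal_rejected(tbox):
    with pytest.raises(UnknownOTUError):
        compile_src(_doc(
            "uberon-male_organism > aism-hind_wing:id-w[exclude = True];"), tbox)
    with pytest.raises(CompileError, match="focal"):
        compile_src(_doc(
            "uberon-male_organism::sp_a[exclude = True] > aism-hind_wing;"),
            tbox)


def test_exclude_referencing_undeclared_otu(tbox):
    src = _doc(
        "uberon-male_organism::sp_a > aism-hind_wing >> pato-length |<| "
        "pato-length:id-q[exclude = True] << aism-hind_wing:id-w[exclude = True] "
        "< uberon-male_organism::sp_ghost[exclude = True];")
    with pytest.raises(UnknownOTUError):
        compile_src(src, tbox)


def test_tag_conflict_rejected(tbox):
    with pytest.raises(TagConflictError):
        compile_src(_doc(
            "uberon-male_organism > aism-pronotum:id-x;\n"
            "uberon-male_organism > aism-clypeus:id-x;"), tbox)


def test_unresolved_terms_reported_together(tbox):
    with pytest.raises(CompileError) as err:
        compile_src(_doc(
            "uberon-male_organism > aism-made_up_part >> pato-made_up_quality;"),
            tbox)
    assert "aism-made_up_part" in str(err.value)
    assert "pato-made_up_quality" in str(err.value)


def test_negation_compiles_to_class_level_denial(tbox):
    kg = compile_src(_doc(
        "uberon-male_organism > aism-protibia !> "
        "aism-dorsal_protibial_cuticular_tooth_4;"), tbox)
    neg = [a for a in kg.assertions if a.negated]
    assert len(neg) == 1
    assert isinstance(neg[0].object, TermRef)
    assert neg[0].object.local == "dorsal_protibial_cuticular_tooth_4"
    # no individual is minted for the denied class
    assert not any(i.cls.local == "dorsal_protibial_cuticular_tooth_4"
                   for i in kg.individuals.values())
    ttl = serialize_abox(kg, tbox)
    assert "owl:complementOf" in ttl and "owl:someValuesFrom" in ttl


def test_empty_document_compiles_to_otu_records_only(tbox):
    kg = compile_src('otu sp_a { taxon_id = "t" catalog_number = "c" }', tbox)
    assert set(kg.otus) == {"sp_a"}
    assert [i.cls.local for i in kg.individuals.values()] == ["male_organism"]
    assert kg.assertions == []


def test_serialization_round_trip_and_determinism(golden_graph, tbox):
    ttl = serialize_abox(golden_graph, tbox)
    assert serialize_abox(golden_graph, tbox) == ttl
    back = load_abox(ttl, tbox)
    assert back == golden_graph
    assert serialize_abox(back, tbox) == ttl


def test_individual_count_matches_term_occurrence_formula(tbox):
    # occurrences - (tag occurrences - distinct tags) - foreign + organism
    src = _doc(
        "uberon-male_organism > aism-pronotum:id-p >> pato-convex;\n"   # 3 terms
        "uberon-male_organism > aism-pronotum:id-p >> pato-ovate;\n"    # 3 terms
        "uberon-male_organism > aism-glossa;")                           # 2 terms
    kg = compile_src(src, tbox)
    # organisms merge (3 -> 1), id-p merges (2 -> 1): 8 occurrences -> 5
    assert len(kg.base_individuals("sp_a")) == 5


def test_otu_record_carries_metadata(golden_graph):
    rec = golden_graph.otus["grebennikovius_armiger"]
    assert rec.taxon_id.startswith("http://zoobank.org/")
    assert rec.catalog_number == "http://id.luomus.fi/GAC.37252"
    assert rec.habitat == "forest"
    assert rec.organism_id == "grebennikovius_armiger/organism"
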