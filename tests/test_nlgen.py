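"""Natural-language generation: faithfulness to published lines,
completeness and determinism."""

import pytest

from phenoc.compiler import compile_document
from phenoc.nlgen import GenerationError, annotate_links, generate
from phenoc.parser import parse_document
from phenoc.reasoner import materialize


ARMIGER = "grebennikovius_armiger"


@pytest.fixture(scope="module")
def armiger_text(golden_inferred):
    return generate(golden_inferred, ARMIGER).text()


#: printed description lines the generator must reproduce token-for-token
#: (whitespace-normalized; full locator chains, before nesting elision)
GOLDEN_LINES = [
    # measurement lines
    "male organism, length = 4.5, unit: millimeter;",
    ("male organism, head capsule, frons, interpunctural distance = 1.0, "
     "unit: diameter of setigerous cuticular puncture;"),
    ("male organism, pronotum, interpunctural distance = 1.5, "
     "unit: diameter of ocellate setigerous cuticular puncture;"),
    "male organism, procoxal cavity, width = 0.375, unit: width of pronotum;",
    # absence lines
    "male organism, posterior longitudinal hypomeral carina: absent;",
    "male organism, protibia, dorsal protibial cuticular tooth 4: absent;",
    "male organism, elytral interstria 5, cuticular tubercle: absent;",
    # within-species comparison lines
    ("male organism, clypeus, anterior region, setigerous cuticular puncture: "
     "diameter smaller than diameter of setigerous cuticular puncture of frons"),
    ("male organism, pronotum: width larger than width of elytron with 9 "
     "striae of male organism"),
    ("diameter smaller than diameter of cuticular puncture of anterior region "
     "of punctate cuticle"),
    ("male organism, left ventral conjunctiva of paramere: thickness similar "
     "in magnitude relative to thickness of right ventral conjunctiva of "
     "paramere of male organism"),
    # positional lines (medial_to, coincident_with)
    ("cuticular carina medial_to lateral region of elytron with 9 striae"),
    ("male organism, abdominal tergite VIII, anatomical margin coincident "
     "with cuticular groove of abdominal tergite VIII"),
]


@pytest.mark.parametrize("line", GOLDEN_LINES)
def test_printed_lines_regenerated(armiger_text, line):
    assert line in armiger_text


def test_other_species_measurements(golden_inferred):
    for otu, length in [("grebennikovius_basilewskyi", "3.8"),
                        ("grebennikovius_lupanganus", "4.0"),
                        ("grebennikovius_pafelo", "4.9")]:
        text = generate(golden_inferred, otu).text()
        assert f"male organism, length = {length}, unit: millimeter;" in text


def test_between_species_full_sentence_and_legacy(golden_inferred):
    text = generate(golden_inferred, ARMIGER).text()
    assert ("the length of the hind wing is smaller than that of the male of "
            "G. basilewskyi;") in text
    legacy = generate(golden_inferred, ARMIGER, legacy_asterisk=True).text()
    assert "male organism, hind wing: length;" in legacy
    assert "that of the male" not in legacy


def test_header_block(golden_inferred):
    doc = generate(golden_inferred, ARMIGER)
    assert doc.header[0] == "male organism"
    assert any("http://id.luomus.fi/GAC.37252" in h for h in doc.header)
    assert any("zoobank.org" in h for h in doc.header)
    assert any("Parent Name Usage ID" in h for h in doc.header)


def test_presence_and_quality_templates(golden_inferred):
    text = generate(golden_inferred, ARMIGER).text()
    assert "male organism, glossa: present;" in text
    assert "male organism, gena: sharp;" in text
    assert "male organism, vertex, posterior region, medial region: smooth;" in text
    # quality node lists expand into one line per quality
    assert "male organism, lateral clypeal tooth 1: upturned;" in text
    assert "male organism, lateral clypeal tooth 1: sharp;" in text


def test_every_locally_asserted_individual_is_narrated(golden_inferred):
    for otu in golden_inferred.base.otus:
        doc = generate(golden_inferred, otu)
        covered = set()
        for line in doc.lines:
            covered |= line.contributes
        local = set()
        for a in golden_inferred.base.assertions:
            if a.otu == otu and a.stmt_index >= 0:
                local.add(a.subject)
                if isinstance(a.object, str):
                    local.add(a.object)
        organism = golden_inferred.base.otus[otu].organism_id
        missing = {i for i in local
                   if i in golden_inferred.base.individuals
                   and not golden_inferred.base.individuals[i].skolem
                   and golden_inferred.base.individuals[i].owner_otu == otu} \
            - covered - {organism}
        assert not missing


def test_generation_deterministic(golden_inferred):
    a = generate(golden_inferred, ARMIGER).text()
    b = generate(golden_inferred, ARMIGER).text()
    assert a == b


def test_markdown_links_resolve_to_tbox_iris(golden_inferred, tbox):
    doc = generate(golden_inferred, ARMIGER)
    md = annotate_links(doc, "markdown")
    assert "[glossa](https://w3id.org/phenoc/vocab/aism#glossa)" in md
    plain = annotate_links(doc, "text")
    assert "[" not in plain and "](" not in plain
    html = annotate_links(doc, "html")
    assert '<a href="' in html
    # every line's link set covers its distinct term labels
    for line in doc.lines:
        assert line.links
        for label, iri in line.links.items():
            assert iri.startswith("http")


def test_unknown_otu_rejected(golden_inferred):
    with pytest.raises(GenerationError):
        generate(golden_inferred, "no_such_species")


def test_dangling_between_species_reference(tbox):
    # comparison whose foreign operand was never declared fails at compile,
    # leaving generation unreachable; a same-species comparison routes to the
    # ordinary template instead of the cross-species sentence
    src = ('otu sp_a { taxon_id = "t" catalog_number = "c"\n'
           "uberon-male_organism > aism-pronotum >> pato-width |>| pato-width "
           "<< colao-elytron < uberon-male_organism;\n}")
    kg = compile_document(parse_document(src, "title: t"), tbox)
    inf = materialize(kg, tbox)
    text = generate(inf, "sp_a").text()
    assert "width larger than width of elytron of male organism" in text
    assert "that of the male" not in text
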