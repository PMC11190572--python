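import pytest

from phenoc.compiler import compile_document
from phenoc.fixture import build_fixture_ontology
from phenoc.parser import parse_document
from phenoc.reasoner import materialize
from phenoc.synth import golden_document_source

#: every statement printed in the pattern overview, one per family variant
PRINTED_STATEMENTS = [
    # presence
    "uberon-male_organism > aism-metafemur > bspo-dorsal_margin > aism-cuticular_carina;",
    "uberon-male_organism > colao-elytral_interstria_5 > bspo-distal_region > aism-cuticular_tubercle;",
    "uberon-male_organism > colao-fused_axial_and_subaxial_endophallites;",
    # absence
    "uberon-male_organism !> colao-posterior_longitudinal_hypomeral_carina;",
    "uberon-male_organism > aism-protibia !> aism-dorsal_protibial_cuticular_tooth_4;",
    # count
    "uberon-male_organism > aism-maxillary_palpus_with_4_palpomeres;",
    "uberon-male_organism > (aism-protarsus_with_5_protarsomeres, "
    "aism-mesotarsus_with_5_mesotarsomeres, aism-metatarsus_with_5_metatarsomeres);",
    "uberon-male_organism > aism-protibia > (aism-dorsal_protibial_cuticular_tooth_1, "
    "aism-dorsal_protibial_cuticular_tooth_2, aism-dorsal_protibial_cuticular_tooth_3);",
    # qualitative
    "uberon-male_organism >> (pato-ovate, pato-flattened);",
    "uberon-male_organism > aism-lateral_clypeal_tooth_1 >> (pato-upturned, pato-sharp);",
    "uberon-male_organism > aism-vertex > bspo-posterior_region > bspo-medial_region >> pato-smooth;",
    "uberon-male_organism > aism-pronotum > bspo-posterior_region > aism-row_of_punctures "
    "> aism-ocellate_cuticular_puncture >> (pato-increased_size, pato-ovate);",
    "uberon-male_organism > colao-scutellar_shield >> pato-concealed;",
    "uberon-male_organism > colao-mesometaventral_sulcus > bspo-medial_region >> pato-curved;",
    "uberon-male_organism > aism-metatibia > bspo-distal_region >> pato-dilated;",
    "uberon-male_organism > aism-protibia > aism-antero-distal_margin > aism-cuticular_seta "
    ">> (pato-multiple, pato-increased_thickness);",
    "uberon-male_organism > aism-parameres >> (pato-symmetrical, pato-elongated);",
    # measurements
    "uberon-male_organism >> pato-length .iao-is_quality_measured_as "
    "iao-measurement_datum:md-c4c164 .aism-has_unit unit-millimeter;",
    "iao-measurement_datum:md-c4c164 .iao-has_measurement_value 4.5;",
    "uberon-male_organism > aism-pronotum:id-1549f8 >> aism-interpunctural_distance "
    ".iao-is_quality_measured_as iao-measurement_datum:md-1b36aa "
    ".aism-has_unit pato-diameter << aism-ocellate_setigerous_cuticular_puncture "
    "< aism-pronotum:id-1549f8;",
    "iao-measurement_datum:md-1b36aa .iao-has_measurement_value 1.5;",
    # within-species comparisons
    "uberon-male_organism > aism-clypeus > bspo-anterior_region "
    "> aism-setigerous_cuticular_puncture >> pato-diameter |<| pato-diameter "
    "<< aism-setigerous_cuticular_puncture < aism-frons;",
    "uberon-male_organism > aism-left_ventral_conjunctiva_of_paramere >> pato-thickness "
    ".ro-similar_in_magnitude_relative_to pato-thickness "
    "<< aism-right_ventral_conjunctiva_of_paramere < uberon-male_organism;",
    # between-species comparison
    "uberon-male_organism::grebennikovius_armiger > aism-hind_wing >> pato-length "
    "|<| pato-length:id-d38816[exclude = True] << aism-hind_wing:id-6b490e[exclude = True] "
    "< uberon-male_organism:grebennikovius_basilewskyi[exclude = True];",
    # positional
    "uberon-male_organism > colao-elytron_with_9_striae:id-5770f5 "
    "> colao-elytral_interstria_8 > aism-cuticular_carina "
    ".aism-medial_to bspo-lateral_region < colao-elytron_with_9_striae:id-5770f5;",
    "uberon-male_organism > aism-abdominal_tergite_VIII:id-791f84 > bspo-anatomical_margin "
    ".ro-coincident_with aism-cuticular_groove < aism-abdominal_tergite_VIII:id-791f84;",
]


@pytest.fixture(scope="session")
def tbox():
    return build_fixture_ontology()


@pytest.fixture(scope="session")
def golden_doc():
    return parse_document(golden_document_source(), "title: Grebennikovius")


@pytest.fixture(scope="session")
def golden_graph(golden_doc, tbox):
    return compile_document(golden_doc, tbox)


@pytest.fixture(scope="session")
def golden_inferred(golden_graph, tbox):
    return materialize(golden_graph, tbox)
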