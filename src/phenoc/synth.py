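"""Synthetic description generator and golden fixtures.

``generate_description`` emits a random, valid description drawn from all
statement families (presence, absence, count/list, quality, absolute and
relative measurement, within- and between-species comparison, positional)
over the fixture vocabulary, together with ground-truth tallies computed
constructively while generating — the oracle the compiler, reasoner and
query engine are checked against.  Seeded mutants differ from the clean
output by exactly one named defect.

``golden_treatments`` returns the four re-encoded *Grebennikovius* species
descriptions bundled with the package.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

MUTATIONS = (
    "drop-species-link",
    "drop-datum-value",
    "add-clashing-part",
    "duplicate-tag-conflict",
)

#: anatomical entity pools by body region (curie only; region membership
#: follows from the fixture TBox parthood chains)
_REGION_POOLS: dict[str, list[str]] = {
    "head_or_part": ["aism-clypeus", "aism-frons", "aism-vertex", "aism-gena",
                     "aism-glossa", "aism-epipharynx", "aism-antenna"],
    "thorax_or_part": ["aism-pronotum", "colao-elytron", "colao-mesoventrite",
                       "colao-metaventrite", "colao-scutellar_shield",
                       "aism-hind_wing"],
    "abdomen_or_part": ["aism-abdominal_tergite_VIII", "aism-parameres",
                        "colao-lamella_copulatrix", "colao-phallobase"],
    "leg_or_part": ["aism-protibia", "aism-mesotibia", "aism-metatibia",
                    "aism-profemur", "aism-metafemur", "aism-procoxa"],
}

_SUBPARTS = ["aism-cuticular_carina", "aism-cuticular_tubercle",
             "aism-cuticular_seta", "aism-cuticular_puncture",
             "aism-cuticular_groove"]

#: structures only ever denied, so a random description never contradicts
#: itself (absence of X alongside an asserted X would be a genuine clash)
_ABSENCE_POOL = ["colao-posterior_longitudinal_hypomeral_carina",
                 "colao-frontolateral_peripheral_endophallite",
                 "aism-dorsal_protibial_cuticular_tooth_4"]

_QUALITY_POOLS: dict[str, list[str]] = {
    "pato-colour": ["pato-red_brown", "pato-dark_brown", "pato-yellow_brown"],
    "pato-shape": ["pato-ovate", "pato-curved", "pato-convex", "pato-concave",
                   "pato-sharp", "pato-tapered", "pato-elongated"],
    "pato-size": ["pato-increased_size", "pato-increased_thickness",
                  "pato-increased_height"],
    "pato-texture": ["pato-smooth"],
}

_FAMILIES = ("presence", "absence", "count", "quality", "abs_measurement",
             "rel_measurement", "within_comparison", "between_comparison",
             "positional")


@dataclass
class GeneratorSpec:
    seed: int = 0
    n_statements: int = 12
    otu_id: str = "synthetic_species_a"
    ref_otu_id: str = "synthetic_species_b"
    mutation: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mutation is not None and self.mutation not in MUTATIONS:
            raise ValueError(f"unknown mutation {self.mutation!r}")


@dataclass
class Tallies:
    """Ground truth recorded while generating."""

    individuals: dict[str, int] = field(default_factory=dict)  # otu -> count
    by_characteristic: dict[str, dict[str, int]] = field(default_factory=dict)
    by_region: dict[str, dict[str, int]] = field(default_factory=dict)
    datum_values: list[str] = field(default_factory=list)

    def _bump(self, table: dict[str, dict[str, int]], key: str,
              otu: str, n: int = 1) -> None:
        table.setdefault(key, {})[otu] = table.get(key, {}).get(otu, 0) + n

    def add_individual(self, otu: str, n: int = 1) -> None:
        self.individuals[otu] = self.individuals.get(otu, 0) + n

    def add_quality(self, parent: str, otu: str) -> None:
        self._bump(self.by_characteristic, parent, otu)

    def add_region(self, region: str, otu: str, n: int = 1) -> None:
        self._bump(self.by_region, region, otu, n)


class _Gen:
    def __init__(self, spec: GeneratorSpec) -> None:
        self.spec = spec
        self.rng = random.Random(spec.seed)
        self.lines: list[str] = []
        self.t = Tallies()
        for region, pool in _REGION_POOLS.items():
            if not pool:
                raise ValueError(f"empty vocabulary pool for {region}")
        self.t.individuals[spec.otu_id] = 1     # the organism
        self.t.individuals[spec.ref_otu_id] = 1
        for region in _REGION_POOLS:
            self.t.by_region.setdefault(region, {})[spec.otu_id] = 0
            self.t.by_region[region][spec.ref_otu_id] = 0
        for parent in _QUALITY_POOLS:
            self.t.by_characteristic.setdefault(parent, {})[spec.otu_id] = 0
            self.t.by_characteristic[parent][spec.ref_otu_id] = 0
        self.k = 0  # fresh-tag counter

    def _tag(self) -> str:
        self.k += 1
        return f"id-g{self.k:04d}"

    def _entity(self) -> tuple[str, str]:
        region = self.rng.choice(sorted(_REGION_POOLS))
        return self.rng.choice(_REGION_POOLS[region]), region

    def _quality(self) -> tuple[str, str]:
        parent = self.rng.choice(sorted(_QUALITY_POOLS))
        return self.rng.choice(_QUALITY_POOLS[parent]), parent

    # -- families ---------------------------------------------------------

    def presence(self) -> None:
        e, region = self._entity()
        self.lines.append(f"uberon-male_organism > {e};")
        self.t.add_individual(self.spec.otu_id)
        self.t.add_region(region, self.spec.otu_id)

    def absence(self) -> None:
        e = self.rng.choice(_ABSENCE_POOL)
        self.lines.append(f"uberon-male_organism !> {e};")

    def count(self) -> None:
        e, region = self._entity()
        subs = self.rng.sample(_SUBPARTS, 3)
        self.lines.append(
            f"uberon-male_organism > {e} > ({', '.join(subs)});")
        self.t.add_individual(self.spec.otu_id, 1 + len(subs))
        self.t.add_region(region, self.spec.otu_id, 1 + len(subs))

    def quality(self) -> None:
        e, region = self._entity()
        q, parent = self._quality()
        self.lines.append(f"uberon-male_organism > {e} >> {q};")
        self.t.add_individual(self.spec.otu_id, 2)
        self.t.add_region(region, self.spec.otu_id)
        self.t.add_quality(parent, self.spec.otu_id)

    def abs_measurement(self) -> None:
        md = self._tag()
        value = f"{self.rng.randint(1, 9)}.{self.rng.randint(0, 9)}"
        self.lines.append(
            "uberon-male_organism >> pato-length "
            f".iao-is_quality_measured_as iao-measurement_datum:{md} "
            ".aism-has_unit unit-millimeter;")
        self.lines.append(
            f"iao-measurement_datum:{md} .iao-has_measurement_value {value};")
        # length quality + datum + unit individuals
        self.t.add_individual(self.spec.otu_id, 3)
        self.t.add_quality("pato-size", self.spec.otu_id)
        self.t.datum_values.append(value)

    def rel_measurement(self) -> None:
        e, region = self._entity()
        et, md = self._tag(), self._tag()
        value = f"{self.rng.randint(1, 3)}.{self.rng.choice([0, 5])}"
        self.lines.append(
            f"uberon-male_organism > {e}:{et} >> aism-interpunctural_distance "
            f".iao-is_quality_measured_as iao-measurement_datum:{md} "
            f".aism-has_unit pato-diameter << aism-cuticular_puncture < {e}:{et};")
        self.lines.append(
            f"iao-measurement_datum:{md} .iao-has_measurement_value {value};")
        # entity + distance + datum + diameter + puncture
        self.t.add_individual(self.spec.otu_id, 5)
        self.t.add_region(region, self.spec.otu_id, 2)   # entity + puncture
        self.t.add_quality("pato-size", self.spec.otu_id)  # interpunctural dist.
        self.t.add_quality("pato-size", self.spec.otu_id)  # diameter unit
        self.t.datum_values.append(value)

    def within_comparison(self) -> None:
        (e1, r1), (e2, r2) = self._entity(), self._entity()
        rel = self.rng.choice(["|<|", "|>|"])
        self.lines.append(
            f"uberon-male_organism > {e1} >> pato-width {rel} pato-width "
            f"<< {e2} < uberon-male_organism;")
        # e1 + width + width' + e2 (organism merges)
        self.t.add_individual(self.spec.otu_id, 4)
        self.t.add_region(r1, self.spec.otu_id)
        self.t.add_region(r2, self.spec.otu_id)
        self.t.add_quality("pato-size", self.spec.otu_id)
        self.t.add_quality("pato-size", self.spec.otu_id)

    def between_comparison(self) -> None:
        qt, et = self._tag(), self._tag()
        ref = self.spec.ref_otu_id
        self.lines.append(
            f"uberon-male_organism::{self.spec.otu_id} > aism-hind_wing >> "
            f"pato-length |<| pato-length:{qt}[exclude = True] << "
            f"aism-hind_wing:{et}[exclude = True] < "
            f"uberon-male_organism:{ref}[exclude = True];")
        self.t.add_individual(self.spec.otu_id, 2)   # wing + length
        self.t.add_region("thorax_or_part", self.spec.otu_id)
        self.t.add_quality("pato-size", self.spec.otu_id)
        self.t.add_individual(ref, 2)                # foreign wing + length
        self.t.add_region("thorax_or_part", ref)
        self.t.add_quality("pato-size", ref)

    def positional(self) -> None:
        e, region = self._entity()
        et = self._tag()
        self.lines.append(
            f"uberon-male_organism > {e}:{et} > aism-cuticular_carina "
            f".aism-medial_to bspo-lateral_region < {e}:{et};")
        # entity + carina + lateral region
        self.t.add_individual(self.spec.otu_id, 3)
        self.t.add_region(region, self.spec.otu_id, 3)

    # -- assembly ----------------------------------------------------------

    def run(self) -> tuple[str, Tallies]:
        for fam in _FAMILIES:           # one of each first, then random
            if len(self.lines) // 1 >= self.spec.n_statements:
                break
            getattr(self, fam)()
        while len(self.lines) < self.spec.n_statements:
            getattr(self, self.rng.choice(_FAMILIES))()

        mutated = list(self.lines)
        if self.spec.mutation == "drop-species-link":
            mutated.append("aism-cuticular_seta >> pato-smooth;")
        elif self.spec.mutation == "drop-datum-value":
            md = self._tag()
            mutated.append(
                "uberon-male_organism >> pato-width "
                f".iao-is_quality_measured_as iao-measurement_datum:{md} "
                ".aism-has_unit unit-millimeter;")
        elif self.spec.mutation == "add-clashing-part":
            mutated.append(
                "uberon-male_organism !> colao-posterior_longitudinal_hypomeral_carina;")
            mutated.append(
                "uberon-male_organism > colao-posterior_longitudinal_hypomeral_carina;")
        elif self.spec.mutation == "duplicate-tag-conflict":
            mutated.append("uberon-male_organism > aism-pronotum:id-dup;")
            mutated.append("uberon-male_organism > aism-clypeus:id-dup;")

        blocks = [
            f'otu {self.spec.otu_id} {{',
            f'  label = "Synthetic species A"',
            f'  taxon_id = "https://example.org/taxon/{self.spec.otu_id}"',
            f'  catalog_number = "https://example.org/specimen/{self.spec.seed}-a"',
            f'  habitat = "forest"',
        ]
        blocks += [f"  {ln}" for ln in mutated]
        blocks.append("}")
        blocks += [
            "",
            f"otu {self.spec.ref_otu_id} {{",
            f'  label = "Synthetic species B"',
            f'  taxon_id = "https://example.org/taxon/{self.spec.ref_otu_id}"',
            f'  catalog_number = "https://example.org/specimen/{self.spec.seed}-b"',
            f'  habitat = "forest"',
            "}",
        ]
        return "\n".join(blocks) + "\n", self.t


def generate_description(spec: GeneratorSpec) -> tuple[str, Tallies]:
    """Emit description source and the ground-truth tallies it must yield."""
    return _Gen(spec).run()


# ---------------------------------------------------------------------------
# Golden treatments
# ---------------------------------------------------------------------------

GOLDEN_OTUS = (
    "grebennikovius_armiger",
    "grebennikovius_basilewskyi",
    "grebennikovius_lupanganus",
    "grebennikovius_pafelo",
)


def golden_treatments() -> dict[str, str]:
    """The four re-encoded species descriptions (otu id -> source text)."""
    out: dict[str, str] = {}
    for otu in GOLDEN_OTUS:
        out[otu] = (resources.files("phenoc.data.goldens")
                    .joinpath(f"{otu}.phs").read_text(encoding="utf-8"))
    return out


def golden_document_source() -> str:
    """All four treatments concatenated into one description document."""
    return "\n".join(golden_treatments()[otu] for otu in GOLDEN_OTUS)
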