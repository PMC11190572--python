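"""Ontology term references and property definitions.

Every term in a semantic description is written ``prefix-local_name``, where
the prefix names the source ontology (``aism``, ``pato``, ``bspo`` ...) and
acts as a namespace.  A :class:`TermRef` is the resolved form: prefix, local
name and absolute IRI.  Object properties additionally carry transitivity,
inverse and operator-alias metadata in a :class:`PropertyDef`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


class TermResolutionError(KeyError):
    """Raised when a prefix or term cannot be resolved to an IRI."""


#: Local names that correspond to published OBO identifiers.  Fixture terms
#: are minted under a project namespace except where the community IRI is
#: unambiguous; parthood and the query-preset parents keep their OBO IRIs so
#: externally produced graphs stay joinable.
KNOWN_OBO_IRIS: dict[tuple[str, str], str] = {
    ("ro", "part_of"): "http://purl.obolibrary.org/obo/BFO_0000050",
    ("ro", "has_part"): "http://purl.obolibrary.org/obo/BFO_0000051",
    ("pato", "colour"): "http://purl.obolibrary.org/obo/PATO_0000014",
    ("pato", "shape"): "http://purl.obolibrary.org/obo/PATO_0000052",
    ("pato", "size"): "http://purl.obolibrary.org/obo/PATO_0000117",
    ("pato", "texture"): "http://purl.obolibrary.org/obo/PATO_0000150",
    ("aism", "insect_head"): "http://purl.obolibrary.org/obo/AISM_0000107",
    ("aism", "insect_thorax"): "http://purl.obolibrary.org/obo/AISM_0000108",
    ("aism", "insect_abdomen"): "http://purl.obolibrary.org/obo/AISM_0000109",
    ("aism", "insect_leg"): "http://purl.obolibrary.org/obo/AISM_0000031",
}

#: Operator glyphs available for edges, mapped to (prefix, local) of the
#: property they alias.  ``!>`` is not listed here: negation is a flag on the
#: ``>`` edge, not a seventh property.
ALIAS_TABLE: dict[str, tuple[str, str]] = {
    ">": ("ro", "has_part"),
    "<": ("ro", "part_of"),
    ">>": ("ro", "has_characteristic"),
    "<<": ("ro", "characteristic_of"),
    "|>|": ("ro", "increased_in_magnitude_relative_to"),
    "|<|": ("ro", "decreased_in_magnitude_relative_to"),
}


@dataclass(frozen=True, order=True)
class TermRef:
    """A prefix-qualified reference to an ontology class or property."""

    prefix: str
    local: str
    iri: str

    def __post_init__(self) -> None:
        if not self.local:
            raise ValueError("TermRef.local must be nonempty")

    @property
    def curie(self) -> str:
        return f"{self.prefix}-{self.local}"

    @property
    def label(self) -> str:
        """Human-readable label: local name with underscores spaced."""
        return self.local.replace("_", " ")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.curie


class PrefixMap:
    """Registry of namespace prefixes with IRI minting.

    Resolution order: explicit per-term override (published OBO ids), then
    ``base IRI + local name``.
    """

    def __init__(self, bases: Optional[dict[str, str]] = None) -> None:
        self.bases: dict[str, str] = dict(bases or {})

    def register(self, prefix: str, base_iri: str) -> None:
        self.bases[prefix] = base_iri

    def resolve(self, prefix: str, local: str) -> TermRef:
        known = KNOWN_OBO_IRIS.get((prefix, local))
        if known is not None:
            return TermRef(prefix, local, known)
        base = self.bases.get(prefix)
        if base is None:
            raise TermResolutionError(
                f"unknown prefix {prefix!r} (term {prefix}-{local})"
            )
        return TermRef(prefix, local, base + local)

    def parse_curie(self, curie: str) -> TermRef:
        """Resolve a ``prefix-local`` string (first hyphen splits)."""
        if "-" not in curie:
            raise TermResolutionError(f"not a prefixed term: {curie!r}")
        prefix, local = curie.split("-", 1)
        return self.resolve(prefix, local)

    def copy(self) -> "PrefixMap":
        return PrefixMap(self.bases)


#: Default namespace bases for the fixture vocabulary.  Minted terms live
#: under a project w3id-style namespace, one sub-namespace per prefix.
DEFAULT_PREFIX_BASES: dict[str, str] = {
    "aism": "https://w3id.org/phenoc/vocab/aism#",
    "colao": "https://w3id.org/phenoc/vocab/colao#",
    "pato": "https://w3id.org/phenoc/vocab/pato#",
    "bspo": "https://w3id.org/phenoc/vocab/bspo#",
    "uberon": "https://w3id.org/phenoc/vocab/uberon#",
    "iao": "https://w3id.org/phenoc/vocab/iao#",
    "ro": "https://w3id.org/phenoc/vocab/ro#",
    "unit": "https://w3id.org/phenoc/vocab/unit#",
    "phenoc": "https://w3id.org/phenoc/vocab/core#",
}


@dataclass(frozen=True)
class PropertyDef:
    """An object property with reasoning-relevant metadata.

    ``alias`` is the operator glyph usable in description source (one of the
    six in :data:`ALIAS_TABLE`); dotted form ``.prefix-local`` is always
    available regardless of alias.
    """

    ref: TermRef
    transitive: bool = False
    inverse: Optional[TermRef] = None
    alias: Optional[str] = None

    @property
    def iri(self) -> str:
        return self.ref.iri


@dataclass
class PropertyRegistry:
    """Lookup of :class:`PropertyDef` by IRI, curie or alias glyph."""

    by_iri: dict[str, PropertyDef] = field(default_factory=dict)

    def add(self, prop: PropertyDef) -> None:
        self.by_iri[prop.ref.iri] = prop

    def __iter__(self):
        return iter(self.by_iri.values())

    def __contains__(self, iri: str) -> bool:
        return iri in self.by_iri

    def get(self, iri: str) -> Optional[PropertyDef]:
        return self.by_iri.get(iri)

    def by_curie(self, curie: str) -> Optional[PropertyDef]:
        for p in self.by_iri.values():
            if p.ref.curie == curie:
                return p
        return None

    def by_alias(self, glyph: str) -> Optional[PropertyDef]:
        for p in self.by_iri.values():
            if p.alias == glyph:
                return p
        return None

    def inverse_of(self, prop: PropertyDef) -> Optional[PropertyDef]:
        if prop.inverse is None:
            return None
        return self.by_iri.get(prop.inverse.iri)
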