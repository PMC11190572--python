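"""Nanopublication packaging of per-species habitat assertions.

A nanopublication is a minimal citable RDF unit of four named graphs: a
*head* linking the other three, an *assertion* (here: the taxon inhabits a
habitat), *provenance* (derivation from the compiled description graph and
attribution), and *pubinfo* (licence, creator).  Emission is file-only
TriG; no signing or network publication.  URIs are deterministic functions
of the taxon identifier and habitat term, so re-emission is byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Optional

import rdflib

from .compiler import ABOX_NS, OTURecord

NP_NS = "http://www.nanopub.org/nschema#"
PROV_NS = "http://www.w3.org/ns/prov#"
DCT_NS = "http://purl.org/dc/terms/"
PUB_BASE = "https://w3id.org/phenoc/nanopub/"

#: has habitat (Relation Ontology) and a standard environment term
HABITAT_PROPERTY = "http://purl.obolibrary.org/obo/RO_0002303"
HABITAT_TERMS = {
    "forest": "http://purl.obolibrary.org/obo/ENVO_01000174",
}

DEFAULT_LICENSE = "https://creativecommons.org/licenses/by/4.0/"


class NanopubError(ValueError):
    pass


Triple = tuple[str, str, str]  # IRIs, or literal marked with leading '"'


@dataclass
class Nanopublication:
    uri: str
    head: list[Triple]
    assertion: list[Triple]
    provenance: list[Triple]
    pubinfo: list[Triple]

    @property
    def graphs(self) -> dict[str, list[Triple]]:
        return {
            f"{self.uri}#head": self.head,
            f"{self.uri}#assertion": self.assertion,
            f"{self.uri}#provenance": self.provenance,
            f"{self.uri}#pubinfo": self.pubinfo,
        }


def build_habitat_nanopub(record: OTURecord, habitat: str = "forest",
                          habitat_iri: Optional[str] = None,
                          creator: str = "", created: str = "",
                          license_iri: str = DEFAULT_LICENSE) -> Nanopublication:
    """Package "taxon inhabits habitat" as one nanopublication.

    ``created`` (an ISO date) is optional so that emission stays
    deterministic unless the caller pins a date.
    """
    if not record.taxon_id:
        raise NanopubError(f"species {record.otu_id!r} has no taxon identifier")
    habitat_iri = habitat_iri or HABITAT_TERMS.get(habitat)
    if habitat_iri is None:
        raise NanopubError(f"no IRI known for habitat {habitat!r}")

    digest = hashlib.sha256(
        f"{record.taxon_id}|{habitat_iri}".encode()).hexdigest()[:12]
    uri = f"{PUB_BASE}{record.otu_id}-{habitat}-{digest}"
    head = [
        (uri, "http://www.w3.org/1999/02/22-rdf-syntax-ns#type",
         NP_NS + "Nanopublication"),
        (uri, NP_NS + "hasAssertion", f"{uri}#assertion"),
        (uri, NP_NS + "hasProvenance", f"{uri}#provenance"),
        (uri, NP_NS + "hasPublicationInfo", f"{uri}#pubinfo"),
    ]
    assertion = [(record.taxon_id, HABITAT_PROPERTY, habitat_iri)]
    provenance = [
        (f"{uri}#assertion", PROV_NS + "wasDerivedFrom", ABOX_NS + record.otu_id),
    ]
    if creator:
        provenance.append(
            (f"{uri}#assertion", PROV_NS + "wasAttributedTo", f'"{creator}'))
    pubinfo = [(uri, DCT_NS + "license", license_iri)]
    if creator:
        pubinfo.append((uri, DCT_NS + "creator", f'"{creator}'))
    if created:
        pubinfo.append((uri, DCT_NS + "created", f'"{created}'))
    return Nanopublication(uri=uri, head=head, assertion=assertion,
                           provenance=provenance, pubinfo=pubinfo)


def _term(t: str) -> str:
    if t.startswith('"'):
        escaped = t[1:].replace("\\", "\\\\").replace('"', '\\"')
        return f'"{escaped}"'
    return f"<{t}>"


def serialize_trig(pubs: Iterable[Nanopublication]) -> str:
    """One TriG document; four named graphs per nanopublication."""
    lines: list[str] = []
    for pub in sorted(pubs, key=lambda p: p.uri):
        for graph_iri, triples in pub.graphs.items():
            lines.append(f"<{graph_iri}> {{")
            for s, p, o in triples:
                lines.append(f"  {_term(s)} {_term(p)} {_term(o)} .")
            lines.append("}")
            lines.append("")
    return "\n".join(lines)


def load_trig(text: str) -> rdflib.Dataset:
    ds = rdflib.Dataset()
    ds.parse(data=text, format="trig")
    return ds


def validate_structure(pub: Nanopublication) -> None:
    """Structural rule: non-empty assertion + provenance + pubinfo, all
    referenced from the head graph."""
    if not pub.assertion:
        raise NanopubError("empty assertion graph")
    head_objects = {o for _, _, o in pub.head}
    for part in ("assertion", "provenance", "pubinfo"):
        iri = f"{pub.uri}#{part}"
        if iri not in head_objects:
            raise NanopubError(f"head does not reference {part} graph")
        if not getattr(pub, part):
            raise NanopubError(f"empty {part} graph")
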