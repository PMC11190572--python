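"""End-to-end pipeline: parse → compile → validate → build TBox → reason →
generate NL → query → package nanopublications.

Runs the six processing stages in order with fail-fast gates: a shape
validation failure halts after stage 2 and an inconsistent ontology halts
after stage 4, leaving earlier artifacts in place.  Re-running an
unchanged configuration reproduces every artifact byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .compiler import compile_document, serialize_abox
from .fixture import build_fixture_ontology
from .nanopub import build_habitat_nanopub, serialize_trig
from .nlgen import annotate_links, generate
from .parser import ProjectConfig, parse_document
from .queries import (CHARACTERISTIC_PRESET, count_by_class, count_by_region,
                      export_sparql_bundle)
from .reasoner import materialize
from .shapes import default_shapes, report_to_dict, serialize_shapes, validate
from .synth import golden_document_source
from .tbox import load_tbox, serialize_tbox


class PipelineError(RuntimeError):
    def __init__(self, step: int, message: str) -> None:
        super().__init__(f"step {step}: {message}")
        self.step = step


@dataclass
class PipelineConfig:
    title: str = "phenoc project"
    authors: list[str] = field(default_factory=list)
    organism_class: str = "uberon-male_organism"
    description_paths: list[str] = field(default_factory=list)
    use_goldens: bool = False
    tbox_paths: list[str] = field(default_factory=list)   # empty -> fixture
    outdir: str = "phenoc_out"
    presets: list[str] = field(default_factory=lambda: ["characteristics",
                                                        "regions"])
    habitat: str = "forest"
    nanopub_created: str = ""     # ISO date; empty keeps output date-free
    seed: int = 0

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        kwargs = {k: v for k, v in data.items()
                  if k in cls.__dataclass_fields__}
        return cls(**kwargs)


@dataclass
class StepResult:
    step: int
    name: str
    status: str                 # "ok" | "failed" | "skipped"
    seconds: float = 0.0
    artifacts: dict[str, str] = field(default_factory=dict)  # path -> sha256
    detail: str = ""


@dataclass
class RunReport:
    steps: list[StepResult] = field(default_factory=list)
    ok: bool = True

    def to_json(self) -> str:
        return json.dumps(
            {"ok": self.ok,
             "steps": [{"step": s.step, "name": s.name, "status": s.status,
                        "seconds": round(s.seconds, 3),
                        "artifacts": s.artifacts, "detail": s.detail}
                       for s in self.steps]},
            indent=2)


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full pipeline; raises :class:`PipelineError` on a gate."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    def finish(step: StepResult, *paths: Path) -> None:
        for p in paths:
            step.artifacts[str(p)] = _sha(p)
        report.steps.append(step)

    def fail(step_no: int, name: str, detail: str) -> PipelineError:
        report.steps.append(StepResult(step_no, name, "failed", detail=detail))
        report.ok = False
        (outdir / "run_report.json").write_text(report.to_json())
        return PipelineError(step_no, detail)

    # TBox (needed from step 1 on; written as the step-3 artifact)
    if config.tbox_paths:
        tbox = load_tbox(config.tbox_paths)
    else:
        tbox = build_fixture_ontology()

    # Step 1 — compile to OWL (ABox)
    t0 = time.perf_counter()
    if config.use_goldens:
        source = golden_document_source()
    else:
        parts = [Path(p).read_text(encoding="utf-8")
                 for p in config.description_paths]
        source = "\n".join(parts)
    project = ProjectConfig(title=config.title, authors=config.authors,
                            organism_class=config.organism_class)
    doc = parse_document(source, project)
    graph = compile_document(doc, tbox)
    abox_path = outdir / "abox.ttl"
    abox_path.write_text(serialize_abox(graph, tbox), encoding="utf-8")
    finish(StepResult(1, "compile", "ok", time.perf_counter() - t0), abox_path)

    # Step 2 — shape validation (gate)
    t0 = time.perf_counter()
    shapes = default_shapes()
    shapes_path = outdir / "shapes.ttl"
    shapes_path.write_text(serialize_shapes(shapes, tbox), encoding="utf-8")
    val = validate(graph, shapes, tbox)
    val_path = outdir / "validation_report.json"
    val_path.write_text(json.dumps(report_to_dict(val), indent=2),
                        encoding="utf-8")
    if not val.conforms:
        raise fail(2, "validate",
                   f"{len(val.violations)} shape violation(s); see {val_path}")
    finish(StepResult(2, "validate", "ok", time.perf_counter() - t0),
           shapes_path, val_path)

    # Step 3 — merged TBox artifact
    t0 = time.perf_counter()
    tbox_path = outdir / "tbox.ttl"
    tbox_path.write_text(serialize_tbox(tbox), encoding="utf-8")
    finish(StepResult(3, "tbox", "ok", time.perf_counter() - t0), tbox_path)

    # Step 4 — reasoning (gate on consistency)
    t0 = time.perf_counter()
    inf = materialize(graph, tbox)
    clash_path = outdir / "clashes.json"
    clash_path.write_text(json.dumps(
        [{"kind": c.kind, "individual": c.individual, "detail": c.detail}
         for c in inf.clashes], indent=2), encoding="utf-8")
    if not inf.consistent:
        raise fail(4, "reason",
                   f"ontology inconsistent: {len(inf.clashes)} clash(es); "
                   f"see {clash_path}")
    inferred_path = outdir / "inferred.ttl"
    from .reasoner import serialize_inferred
    inferred_path.write_text(serialize_inferred(inf), encoding="utf-8")
    finish(StepResult(4, "reason", "ok", time.perf_counter() - t0),
           inferred_path, clash_path)

    # Step 5 — NL descriptions
    t0 = time.perf_counter()
    nl_paths = []
    for otu_id in sorted(graph.otus):
        nl = generate(inf, otu_id)
        md_path = outdir / f"description_{otu_id}.md"
        md_path.write_text(annotate_links(nl, "markdown"), encoding="utf-8")
        txt_path = outdir / f"description_{otu_id}.txt"
        txt_path.write_text(nl.text(), encoding="utf-8")
        nl_paths += [md_path, txt_path]
    finish(StepResult(5, "nl", "ok", time.perf_counter() - t0), *nl_paths)

    # Step 6 — queries and nanopublications
    t0 = time.perf_counter()
    artifacts = []
    if "characteristics" in config.presets:
        qc = count_by_class(inf, CHARACTERISTIC_PRESET)
        p = outdir / "table_characteristics.tsv"
        p.write_text(qc.to_tsv(), encoding="utf-8")
        artifacts.append(p)
    if "regions" in config.presets:
        qr = count_by_region(inf)
        p = outdir / "table_regions.tsv"
        p.write_text(qr.to_tsv(), encoding="utf-8")
        artifacts.append(p)
    bundle = export_sparql_bundle(inf, outdir / "sparql",
                                  presets=tuple(config.presets))
    artifacts.extend(bundle.values())
    pubs = [build_habitat_nanopub(rec, habitat=config.habitat,
                                  creator=", ".join(config.authors),
                                  created=config.nanopub_created)
            for rec in graph.otus.values() if rec.taxon_id]
    trig_path = outdir / "nanopubs.trig"
    trig_path.write_text(serialize_trig(pubs), encoding="utf-8")
    artifacts.append(trig_path)
    finish(StepResult(6, "query+nanopub", "ok", time.perf_counter() - t0),
           *artifacts)

    (outdir / "run_report.json").write_text(report.to_json(), encoding="utf-8")
    return report


def print_version_manifest(config: Optional[PipelineConfig] = None) -> str:
    """Reproducibility manifest: tool version, TBox and config digests."""
    config = config or PipelineConfig()
    if config.tbox_paths:
        tbox = load_tbox(config.tbox_paths)
    else:
        tbox = build_fixture_ontology()
    tbox_hash = hashlib.sha256(serialize_tbox(tbox).encode()).hexdigest()
    cfg_text = json.dumps(config.__dict__, sort_keys=True, default=str)
    cfg_hash = hashlib.sha256(cfg_text.encode()).hexdigest()
    return (f"phenoc {__version__}\n"
            f"tbox sha256: {tbox_hash}\n"
            f"config sha256: {cfg_hash}\n")
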