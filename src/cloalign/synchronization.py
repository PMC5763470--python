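"""Synchronization: rewrite aligned records into the cell-line-cell pattern.

Mapped population-pattern classes are merged into their cell-line-cell
partners (evidence the target lacks is added, the source label and its
" cell" conversion become exact synonyms, and the source class is deprecated
with a replaced-by pointer). Unique immortalized lines are added under the
cell-line-cell root with freshly minted IRIs and the " cell" naming
convention; the flat cross-reference authority carries no hierarchy, so no
deeper subclass placement is assumed. Stem, primary and foreign-namespace
lines are kept where they are.

Merging is state-aware: a pair whose evidence, names and cross-references
are already present on the target (including the source-id xref recorded at
merge time) produces a KEEP, so re-running synchronization on its own output
plans zero new actions.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd
from rdflib import BNode, Graph, Literal, URIRef, RDF, RDFS, OWL, XSD

from .config import PipelineConfig
from .lexical import normalize_label, normalize_xref, normalized_names
from .model import CellLineRecord, MappingDecision, Stage

AxiomPair = tuple[str, str]  # (object property IRI, named filler IRI)


class ActionKind(enum.Enum):
    MERGE = "MERGE"
    ADD = "ADD"
    DEPRECATE = "DEPRECATE"
    KEEP = "KEEP"


@dataclass
class SynchronizationAction:
    kind: ActionKind
    subject_iri: str
    target_iri: Optional[str] = None
    new_label: Optional[str] = None
    merged_axioms: list[AxiomPair] = field(default_factory=list)
    new_synonyms: list[str] = field(default_factory=list)
    new_xrefs: list[str] = field(default_factory=list)
    note: str = ""


def to_clo_name(efo_label: str) -> str:
    """Convert a population-pattern label to the cell-line-cell convention.

    Labels already ending in " cell" pass through unchanged, so the
    conversion is idempotent.
    """
    if not efo_label:
        raise ValueError("cannot convert an empty label")
    if efo_label.casefold().endswith(" cell"):
        return efo_label
    return efo_label + " cell"


def transform_to_clo_pattern(
    record: CellLineRecord,
    config: Optional[PipelineConfig] = None,
) -> list[AxiomPair]:
    """Re-express a population-pattern record's evidence as CLO-style axioms.

    Disease moves from the bearer-of property to is-model-for; cell type,
    anatomy and species carry through on the target pattern's properties.
    Deterministic (sorted) output.
    """
    config = config or PipelineConfig()
    pat = config.clo_pattern
    axioms: list[AxiomPair] = []
    for d in sorted(record.diseases):
        axioms.append((pat.disease_property, d))
    if record.cell_type:
        axioms.append((pat.cell_type_property, record.cell_type))
    if record.anatomical_location:
        axioms.append((pat.anatomy_property, record.anatomical_location))
    if record.species:
        axioms.append((pat.species_property, record.species))
    return axioms


_IRI_SUFFIX_RE = re.compile(r"^(.*?)(\d{7})$")


def assign_new_clo_iri(
    existing_clo_iris: Iterable[str],
    count: int,
    namespace: Optional[str] = None,
) -> list[str]:
    """Mint ``count`` consecutive fresh IRIs after the highest existing one.

    Existing IRIs must end in a zero-padded 7-digit numeric suffix; an empty
    set starts the sequence at 1 in *namespace*.
    """
    best = 0
    ns = namespace
    for iri in existing_clo_iris:
        m = _IRI_SUFFIX_RE.match(iri)
        if not m:
            raise ValueError(f"malformed cell-line-cell IRI: {iri}")
        if int(m.group(2)) > best:
            best = int(m.group(2))
            ns = m.group(1)
    if ns is None:
        ns = PipelineConfig().clo_namespace
    return [f"{ns}{best + i + 1:07d}" for i in range(count)]


def iri_to_xref(iri: str) -> str:
    """Curie-style xref for an ontology class IRI (…/EFO_0002208 → EFO:0002208)."""
    local = iri.rsplit("/", 1)[-1].rsplit("#", 1)[-1]
    if "_" in local:
        prefix, ident = local.split("_", 1)
        return normalize_xref(f"{prefix}:{ident}")
    return local


def _merge_additions(
    efo: CellLineRecord,
    clo: CellLineRecord,
    config: PipelineConfig,
) -> tuple[list[AxiomPair], list[str], list[str]]:
    """What a MERGE would add to the target: axioms, synonyms, xrefs.

    Single-valued elements are only filled in when the target lacks them;
    conflicting values are a review matter, never silently overwritten.
    """
    pat = config.clo_pattern
    axioms: list[AxiomPair] = []
    for d in sorted(efo.diseases - clo.diseases):
        axioms.append((pat.disease_property, d))
    if efo.cell_type and not clo.cell_type:
        axioms.append((pat.cell_type_property, efo.cell_type))
    if efo.anatomical_location and not clo.anatomical_location:
        axioms.append((pat.anatomy_property, efo.anatomical_location))
    if efo.species and not clo.species:
        axioms.append((pat.species_property, efo.species))

    have = normalized_names(clo.names())
    synonyms = sorted(
        {s for s in ({efo.label, to_clo_name(efo.label)} | efo.synonyms)
         if normalize_label(s) not in have}
    )
    xrefs = sorted((efo.xrefs | {iri_to_xref(efo.iri)}) - clo.xrefs)
    return axioms, synonyms, xrefs


def plan_synchronization(
    decisions: Iterable[MappingDecision],
    efo_records: Iterable[CellLineRecord],
    clo_records: Iterable[CellLineRecord],
    config: Optional[PipelineConfig] = None,
) -> list[SynchronizationAction]:
    """Turn per-record decisions into MERGE/ADD/DEPRECATE/KEEP actions.

    Every mapped pair not yet synchronized yields one MERGE plus one paired
    DEPRECATE of the source class; unique immortalized lines yield ADDs with
    fresh IRIs; everything else is KEPT. Decisions naming unknown IRIs are a
    hard error.
    """
    config = config or PipelineConfig()
    efo_by_iri = {r.iri: r for r in efo_records}
    clo_list = list(clo_records)
    clo_by_iri = {r.iri: r for r in clo_list}
    known_xrefs: set[str] = set()
    for r in clo_list:
        known_xrefs.update(r.xrefs)

    actions: list[SynchronizationAction] = []
    fresh_needed: list[tuple[CellLineRecord, MappingDecision]] = []

    for dec in sorted(decisions, key=lambda d: d.efo_iri):
        rec = efo_by_iri.get(dec.efo_iri)
        if rec is None:
            raise ValueError(f"decision for unknown record {dec.efo_iri}")
        if dec.is_mapped:
            clo_rec = clo_by_iri.get(dec.clo_iri)
            if clo_rec is None:
                raise ValueError(f"decision targets unknown class {dec.clo_iri}")
            axioms, synonyms, xrefs = _merge_additions(rec, clo_rec, config)
            if axioms or synonyms or xrefs:
                actions.append(SynchronizationAction(
                    kind=ActionKind.MERGE, subject_iri=rec.iri,
                    target_iri=clo_rec.iri, merged_axioms=axioms,
                    new_synonyms=synonyms, new_xrefs=xrefs,
                ))
                actions.append(SynchronizationAction(
                    kind=ActionKind.DEPRECATE, subject_iri=rec.iri,
                    target_iri=clo_rec.iri, new_label=rec.label,
                ))
            else:
                actions.append(SynchronizationAction(
                    kind=ActionKind.KEEP, subject_iri=rec.iri,
                    target_iri=clo_rec.iri, note="already synchronized",
                ))
        elif dec.stage is Stage.UNIQUE_IMMORTALIZED:
            identity = {iri_to_xref(rec.iri)} | rec.xrefs
            if identity & known_xrefs:
                actions.append(SynchronizationAction(
                    kind=ActionKind.KEEP, subject_iri=rec.iri,
                    note="already added",
                ))
            else:
                fresh_needed.append((rec, dec))
        else:
            actions.append(SynchronizationAction(
                kind=ActionKind.KEEP, subject_iri=rec.iri,
                note=dec.stage.value.lower(),
            ))

    per_add = 2 if config.population_companion else 1
    fresh = assign_new_clo_iri(
        list(clo_by_iri), len(fresh_needed) * per_add, config.clo_namespace
    )
    for i, (rec, dec) in enumerate(fresh_needed):
        new_iri = fresh[i * per_add]
        companion = fresh[i * per_add + 1] if config.population_companion else None
        actions.append(SynchronizationAction(
            kind=ActionKind.ADD, subject_iri=rec.iri, target_iri=new_iri,
            new_label=to_clo_name(rec.label),
            merged_axioms=transform_to_clo_pattern(rec, config),
            new_synonyms=sorted({rec.label} | rec.synonyms),
            new_xrefs=sorted(rec.xrefs | {iri_to_xref(rec.iri)}),
            note=f"companion:{companion}" if companion else "",
        ))
    return actions


class _BNodeCounter:
    def __init__(self) -> None:
        self.n = 0

    def __call__(self) -> BNode:
        self.n += 1
        return BNode(f"sync{self.n:06d}")


def _add_restriction(g: Graph, cls: URIRef, prop: str, filler: str,
                     bnode: _BNodeCounter) -> None:
    r = bnode()
    g.add((cls, RDFS.subClassOf, r))
    g.add((r, RDF.type, OWL.Restriction))
    g.add((r, OWL.onProperty, URIRef(prop)))
    g.add((r, OWL.someValuesFrom, URIRef(filler)))


def emit_updated_clo(
    actions: Iterable[SynchronizationAction],
    clo_graph: Graph,
    config: Optional[PipelineConfig] = None,
) -> tuple[bytes, pd.DataFrame]:
    """Apply actions to the ontology and serialize RDF/XML plus a report.

    Deprecations become tombstones: label, owl:deprecated=true and a
    term-replaced-by pointer at the replacement class. Output is byte-stable
    for fixed inputs (deterministic action order and blank-node naming).
    """
    config = config or PipelineConfig()
    ann = config.annotations
    out = Graph()
    for prefix, ns in clo_graph.namespaces():
        out.bind(prefix, ns)
    for triple in sorted(clo_graph):
        out.add(triple)
    bnode = _BNodeCounter()
    syn_prop = URIRef(ann.synonyms[0])
    rows: list[dict] = []

    ordered = sorted(actions, key=lambda a: (a.kind.value, a.subject_iri))
    for act in ordered:
        if act.kind is ActionKind.MERGE:
            target = URIRef(act.target_iri)
            for prop, filler in act.merged_axioms:
                _add_restriction(out, target, prop, filler, bnode)
            for s in act.new_synonyms:
                out.add((target, syn_prop, Literal(s)))
            for x in act.new_xrefs:
                out.add((target, URIRef(ann.db_xref), Literal(x)))
        elif act.kind is ActionKind.ADD:
            cls = URIRef(act.target_iri)
            out.add((cls, RDF.type, OWL.Class))
            out.add((cls, RDFS.subClassOf, URIRef(config.clo_pattern.root_class)))
            out.add((cls, URIRef(ann.label), Literal(act.new_label)))
            for s in act.new_synonyms:
                out.add((cls, syn_prop, Literal(s)))
            for x in act.new_xrefs:
                out.add((cls, URIRef(ann.db_xref), Literal(x)))
            for prop, filler in act.merged_axioms:
                _add_restriction(out, cls, prop, filler, bnode)
            if act.note.startswith("companion:"):
                comp = URIRef(act.note.split(":", 1)[1])
                out.add((comp, RDF.type, OWL.Class))
                out.add((comp, RDFS.subClassOf, URIRef(config.population_root)))
                base = act.new_label[:-5] if act.new_label.endswith(" cell") else act.new_label
                out.add((comp, URIRef(ann.label), Literal(base + " cell line")))
                _add_restriction(out, comp, config.has_grain_property,
                                 act.target_iri, bnode)
        elif act.kind is ActionKind.DEPRECATE:
            cls = URIRef(act.subject_iri)
            out.add((cls, RDF.type, OWL.Class))
            if act.new_label:
                out.add((cls, URIRef(ann.label), Literal(act.new_label)))
            out.add((cls, URIRef(ann.deprecated),
                     Literal(True, datatype=XSD.boolean)))
            out.add((cls, URIRef(ann.replaced_by), URIRef(act.target_iri)))
        rows.append({
            "action": act.kind.value,
            "subject": act.subject_iri,
            "target": act.target_iri or "",
            "label": act.new_label or "",
            "axioms_added": len(act.merged_axioms),
            "synonyms_added": len(act.new_synonyms),
            "xrefs_added": len(act.new_xrefs),
            "note": act.note,
        })

    data = out.serialize(format="pretty-xml", encoding="utf-8")
    return data, pd.DataFrame(rows, columns=[
        "action", "subject", "target", "label",
        "axioms_added", "synonyms_added", "xrefs_added", "note",
    ])
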