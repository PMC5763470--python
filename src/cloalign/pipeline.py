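"""End-to-end orchestration of the four-step alignment workflow.

Extraction, three-way triangulation, direct C-score mapping, residual
classification, synchronization planning and ontology emission run in
sequence; every intermediate product is kept on the result object so the
command-line subcommands (and tests) can report on any stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd
from rdflib import Graph

from .classification import classify_unmapped
from .config import PipelineConfig
from .matching import candidates_to_rows, direct_map
from .model import (
    Category,
    CellLineRecord,
    CellosaurusEntry,
    MappingDecision,
    Pattern,
    Stage,
    TermGraph,
    decisions_by_iri,
)
from .sources_io import (
    build_term_graph,
    evidence_terms_of,
    extract_cell_line_records,
    parse_cellosaurus,
    partition_by_namespace,
)
from .synchronization import (
    SynchronizationAction,
    emit_updated_clo,
    plan_synchronization,
)
from .threeway import three_way_map

log = logging.getLogger(__name__)

SUMMARY_ROWS = ("mapped", "unique_immortalized", "imported", "stem", "primary")


@dataclass
class PipelineResult:
    native_records: list[CellLineRecord]
    foreign_records: list[CellLineRecord]
    clo_records: list[CellLineRecord]
    entries: list[CellosaurusEntry]
    term_graph: TermGraph
    decisions: list[MappingDecision]
    actions: list[SynchronizationAction]
    updated_clo: bytes
    change_report: pd.DataFrame
    candidate_rows: list[dict] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        counts = summarize_decisions(self.decisions)
        return pd.DataFrame(
            [{"outcome": k, "n": counts[k]} for k in SUMMARY_ROWS]
        )


def summarize_decisions(decisions: list[MappingDecision]) -> dict[str, int]:
    """Five-way outcome partition: every input class lands in exactly one row."""
    counts = dict.fromkeys(SUMMARY_ROWS, 0)
    for d in decisions:
        if d.stage in (Stage.XREF3WAY, Stage.DIRECT) and d.is_mapped:
            counts["mapped"] += 1
        elif d.stage is Stage.UNIQUE_IMMORTALIZED:
            counts["unique_immortalized"] += 1
        elif d.stage is Stage.FOREIGN:
            counts["imported"] += 1
        elif d.stage is Stage.STEM:
            counts["stem"] += 1
        elif d.stage is Stage.PRIMARY:
            counts["primary"] += 1
        else:  # a direct UNMAPPED decision that skipped classification
            counts["primary"] += 1
    return counts


def run_pipeline(
    efo_graph: Graph,
    clo_graph: Graph,
    cellosaurus_text: str,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run extract → triangulate → direct map → classify → synchronize."""
    config = config or PipelineConfig()

    entries = parse_cellosaurus(cellosaurus_text)
    log.info("parsed %d Cellosaurus entries", len(entries))

    efo_records = extract_cell_line_records(efo_graph, Pattern.EFO_STYLE, config)
    native, foreign = partition_by_namespace(efo_records, config)
    clo_records = extract_cell_line_records(clo_graph, Pattern.CLO_STYLE, config)
    log.info("extracted %d native + %d foreign population-pattern records, "
             "%d cell-line-cell records", len(native), len(foreign), len(clo_records))

    evidence = evidence_terms_of(native) | evidence_terms_of(clo_records)
    term_graph = build_term_graph([efo_graph, clo_graph], evidence)

    threeway_decisions, deferred = three_way_map(
        native, clo_records, entries, term_graph, config)
    log.info("three-way mapping: %d decided, %d deferred",
             len(threeway_decisions), len(deferred))

    candidate_rows: list[dict] = []
    if deferred and clo_records:
        direct_decisions = direct_map(deferred, clo_records, term_graph, config)
    else:
        direct_decisions = [
            MappingDecision(efo_iri=r.iri, stage=Stage.DIRECT,
                            category=Category.UNMAPPED)
            for r in deferred
        ]
    for d in direct_decisions:
        candidate_rows.extend(candidates_to_rows(d.efo_iri, d.candidates, d.category))
    direct_mapped = [d for d in direct_decisions if d.category is not Category.UNMAPPED]
    residual_iris = {d.efo_iri for d in direct_decisions
                     if d.category is Category.UNMAPPED}
    residual = [r for r in deferred if r.iri in residual_iris]
    log.info("direct mapping: %d mapped, %d residual",
             len(direct_mapped), len(residual))

    classified = classify_unmapped(residual, entries)
    foreign_decisions = [
        MappingDecision(efo_iri=r.iri, stage=Stage.FOREIGN, note="foreign namespace")
        for r in foreign
    ]
    decisions = threeway_decisions + direct_mapped + classified + foreign_decisions
    decisions_by_iri(decisions)  # guard: exactly one decision per class
    log.info("outcomes: %s", summarize_decisions(decisions))

    actions = plan_synchronization(decisions, efo_records, clo_records, config)
    updated_clo, change_report = emit_updated_clo(actions, clo_graph, config)
    log.info("synchronization: %s",
             change_report["action"].value_counts().to_dict() if len(change_report) else {})

    return PipelineResult(
        native_records=native,
        foreign_records=foreign,
        clo_records=clo_records,
        entries=entries,
        term_graph=term_graph,
        decisions=decisions,
        actions=actions,
        updated_clo=updated_clo,
        change_report=change_report,
        candidate_rows=candidate_rows,
    )


def decisions_to_rows(decisions: list[MappingDecision]) -> list[dict]:
    return [
        {
            "efo_iri": d.efo_iri,
            "stage": d.stage.value,
            "category": d.category.value if d.category else "",
            "clo_iri": d.clo_iri or "",
            "needs_manual": int(d.needs_manual),
            "recovery_flag": int(d.recovery_used),
            "c_score": d.evidence.c_score if d.evidence else "",
            "sld": d.evidence.sld_value if d.evidence else "",
            "note": d.note,
        }
        for d in decisions
    ]


def records_to_rows(records: list[CellLineRecord]) -> list[dict]:
    return [
        {
            "iri": r.iri,
            "source": r.source.value,
            "label": r.label,
            "synonyms": "|".join(sorted(r.synonyms)),
            "xrefs": "|".join(sorted(r.xrefs)),
            "diseases": "|".join(sorted(r.diseases)),
            "cell_type": r.cell_type or "",
            "anatomical_location": r.anatomical_location or "",
            "species": r.species or "",
        }
        for r in records
    ]
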