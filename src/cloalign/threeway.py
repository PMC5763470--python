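"""EFO-Cellosaurus-CLO triangulated mapping over unique cross-references.

The first mapping step aligns only cell lines whose link to the curated
cross-reference authority is unambiguous: an accession counts as *unique*
for a source ontology when exactly one record carries it and that record
carries exactly one Cellosaurus xref. For each accession unique on both
sides, name agreement and the common evidence elements (disease, species of
origin) are validated against the Cellosaurus entry; a disease conflict is
recovered when both the EFO-Cellosaurus and CLO-Cellosaurus disease pairs
stand in a direct subclass-superclass relation. Records that cannot be
triangulated are deferred to direct C-score mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .config import PipelineConfig
from .lexical import normalize_label, normalized_names
from .matching import element_match
from .model import (
    Category,
    CellLineRecord,
    CellosaurusEntry,
    MappingDecision,
    Stage,
    TermGraph,
)

CVCL_PREFIX = "CELLOSAURUS:"


def cellosaurus_accessions(record: CellLineRecord) -> set[str]:
    """The Cellosaurus accessions among a record's normalized xrefs."""
    return {x[len(CVCL_PREFIX):] for x in record.xrefs if x.startswith(CVCL_PREFIX)}


@dataclass
class XrefIndex:
    """Accession -> record-IRI index for one source ontology."""

    by_accession: dict[str, set[str]] = field(default_factory=dict)
    xref_counts: dict[str, int] = field(default_factory=dict)  # iri -> #CVCL xrefs

    def is_unique(self, accession: str) -> bool:
        iris = self.by_accession.get(accession, set())
        if len(iris) != 1:
            return False
        (iri,) = iris
        return self.xref_counts.get(iri, 0) == 1

    def unique_record(self, accession: str) -> Optional[str]:
        return next(iter(self.by_accession[accession])) if self.is_unique(accession) else None


def build_xref_index(records: Iterable[CellLineRecord]) -> XrefIndex:
    index = XrefIndex()
    for r in records:
        accs = cellosaurus_accessions(r)
        index.xref_counts[r.iri] = len(accs)
        for acc in accs:
            index.by_accession.setdefault(acc, set()).add(r.iri)
    return index


def resolve_entry_diseases(
    entry: CellosaurusEntry,
    graph: TermGraph,
    config: PipelineConfig,
) -> set[str]:
    """Resolve a flat-file entry's disease annotations to ontology term IRIs.

    Explicit terminology-id mappings from config win; otherwise the disease
    label is looked up (normalized) among the term graph's labels.
    """
    iris: set[str] = set()
    for term_id, label in entry.diseases:
        if term_id in config.disease_xref_map:
            iris.add(config.disease_xref_map[term_id])
        else:
            iris.update(graph.find_by_label(normalize_label(label), normalize_label))
    return iris


def _disease_check(
    side: set[str],
    entry_iris: set[str],
    graph: TermGraph,
    config: PipelineConfig,
) -> tuple[bool, bool]:
    """(passes, used_recovery) for one ontology-vs-Cellosaurus disease pair."""
    plain = element_match(side, entry_iris, graph, "disease", hierarchy_recovery=False)
    if plain != -1:
        return True, False
    if config.semantic_recovery:
        recovered = element_match(side, entry_iris, graph, "disease",
                                  hierarchy_recovery=True)
        if recovered == 1:
            return True, True
    return False, False


def three_way_map(
    efo_records: list[CellLineRecord],
    clo_records: list[CellLineRecord],
    cellosaurus_entries: list[CellosaurusEntry],
    graph: TermGraph,
    config: Optional[PipelineConfig] = None,
) -> tuple[list[MappingDecision], list[CellLineRecord]]:
    """Triangulate uniquely cross-referenced cell lines through Cellosaurus.

    Returns decisions (stage XREF3WAY) for triangulated records and the
    deferred records to be handed to direct mapping. The two outputs
    partition the EFO input.
    """
    config = config or PipelineConfig()
    efo_index = build_xref_index(efo_records)
    clo_index = build_xref_index(clo_records)
    entries = {e.accession: e for e in cellosaurus_entries}
    clo_by_iri = {r.iri: r for r in clo_records}

    decisions: list[MappingDecision] = []
    deferred: list[CellLineRecord] = []

    for rec in efo_records:
        accs = cellosaurus_accessions(rec)
        acc = next(iter(accs)) if len(accs) == 1 else None
        if (
            acc is None
            or not efo_index.is_unique(acc)
            or acc not in entries
            or clo_index.unique_record(acc) is None
        ):
            deferred.append(rec)
            continue

        entry = entries[acc]
        clo_rec = clo_by_iri[clo_index.unique_record(acc)]
        problems: list[str] = []
        recovery_used = False

        entry_names = normalized_names(entry.names())
        if not (normalized_names(rec.names()) & entry_names):
            problems.append("efo-name")
        if not (normalized_names(clo_rec.names()) & entry_names):
            problems.append("clo-name")

        entry_disease_iris = resolve_entry_diseases(entry, graph, config)
        if entry_disease_iris:
            for side_name, side in (("efo", rec.diseases), ("clo", clo_rec.diseases)):
                ok, used = _disease_check(side, entry_disease_iris, graph, config)
                recovery_used |= used
                if not ok:
                    problems.append(f"{side_name}-disease")
        elif element_match(rec.diseases, clo_rec.diseases, graph, "disease",
                           hierarchy_recovery=config.semantic_recovery) == -1:
            problems.append("disease")

        efo_tax = config.resolve_taxid(rec.species)
        clo_tax = config.resolve_taxid(clo_rec.species)
        if entry.species_taxids:
            for side_name, tax in (("efo", efo_tax), ("clo", clo_tax)):
                if tax is not None and tax not in entry.species_taxids:
                    problems.append(f"{side_name}-species")
        elif efo_tax is not None and clo_tax is not None and efo_tax != clo_tax:
            problems.append("species")

        decisions.append(MappingDecision(
            efo_iri=rec.iri,
            stage=Stage.XREF3WAY,
            category=Category.EXACT_VALID if not problems else Category.EXACT_NEEDS_REVIEW,
            clo_iri=clo_rec.iri,
            needs_manual=bool(problems),
            recovery_used=recovery_used,
            note=";".join(problems),
        ))

    return decisions, deferred


def threeway_to_rows(decisions: Iterable[MappingDecision],
                     efo_index: XrefIndex) -> list[dict]:
    """Flatten three-way decisions for TSV export."""
    rows = []
    for d in decisions:
        rows.append({
            "efo_iri": d.efo_iri,
            "clo_iri": d.clo_iri or "",
            "stage": d.stage.value,
            "category": d.category.value if d.category else "",
            "recovery_flag": int(d.recovery_used),
            "conflicts": d.note,
        })
    return rows
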