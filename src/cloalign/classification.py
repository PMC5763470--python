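"""Classification of cell lines left unmapped after direct mapping.

A residual cell line with a traceable Cellosaurus record is assumed to be an
immortalized permanent cell line — primary cell lines are not curated in
Cellosaurus — unless the entry's category places it among stem cells, which
the target ontology does not yet model. Residual lines without a resolvable
cross-reference are flagged as (presumed) primary cell lines for manual
verification. This assumption is a curation heuristic, preserved as such
and surfaced through the ``note`` field of each decision.
"""

from __future__ import annotations

import logging
from typing import Iterable

from .model import CellLineRecord, CellosaurusEntry, MappingDecision, Stage
from .threeway import cellosaurus_accessions

log = logging.getLogger(__name__)

STEM_MARKER = "stem cell"


def classify_unmapped(
    records: Iterable[CellLineRecord],
    cellosaurus_entries: Iterable[CellosaurusEntry],
) -> list[MappingDecision]:
    """Split residual cell lines into unique-immortalized, stem, and primary.

    Records resolving to a non-stem Cellosaurus entry become
    UNIQUE_IMMORTALIZED (to be added to the cell-line-cell ontology); stem
    entries stay behind as STEM; records without any resolvable accession
    become PRIMARY with a manual-review flag. When a record's accessions
    disagree (one stem, one not), STEM wins — a possible stem line is never
    auto-added.
    """
    entries = {e.accession: e for e in cellosaurus_entries}
    decisions: list[MappingDecision] = []
    for rec in records:
        resolved: list[CellosaurusEntry] = []
        for acc in sorted(cellosaurus_accessions(rec)):
            entry = entries.get(acc)
            if entry is None:
                log.warning("record %s: accession %s absent from Cellosaurus file",
                            rec.iri, acc)
            else:
                resolved.append(entry)
        if not resolved:
            decisions.append(MappingDecision(
                efo_iri=rec.iri, stage=Stage.PRIMARY, needs_manual=True,
                note="no Cellosaurus record; presumed primary, verify manually",
            ))
        elif any(STEM_MARKER in e.category.casefold() for e in resolved):
            decisions.append(MappingDecision(
                efo_iri=rec.iri, stage=Stage.STEM,
                note="stem-cell category in Cellosaurus; kept in source namespace",
            ))
        else:
            decisions.append(MappingDecision(
                efo_iri=rec.iri, stage=Stage.UNIQUE_IMMORTALIZED,
                note="traceable Cellosaurus record; assumed immortalized permanent",
            ))
    return decisions
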