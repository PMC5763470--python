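"""Direct cell-line mapping: element matching, C-score, ranking, categories.

The confidence score of a candidate pair is

    C = sum_i M_i - SLD

where M_i is +1 / -1 / 0 for a matched / unmatched / missing evidence
element i over K = {disease, cell type, anatomical location, species of
origin}, and SLD is the shortest Levenshtein distance over the two name
sets. An exact annotation match (shared normalized name, or shared
cross-reference) forces SLD to zero. Disease conflicts may additionally be
matched when the two terms stand in a direct subclass-superclass relation
(one-hop semantic recovery).
"""

from __future__ import annotations

from typing import Iterable, Optional, Union

from .config import PipelineConfig
from .lexical import normalized_names, sld
from .model import (
    Category,
    CellLineRecord,
    EVIDENCE_ELEMENTS,
    MappingDecision,
    MatchEvidence,
    RankedCandidate,
    Stage,
    TermGraph,
)

TermSide = Union[None, str, int, set]


def _as_set(value: TermSide) -> set:
    if value is None:
        return set()
    if isinstance(value, (set, frozenset)):
        return set(value)
    return {value}


def element_match(
    term_a: TermSide,
    term_b: TermSide,
    graph: TermGraph,
    element: str,
    *,
    hierarchy_recovery: bool = True,
    cell_type_recovery: bool = False,
) -> int:
    """Match one evidence element: +1 matched, -1 unmatched, 0 missing.

    Missing means either side lacks the element — one-sided absence cannot
    evidence a mismatch. Equality matches any element; a direct asserted
    subclass-superclass relation additionally matches diseases (and, when
    enabled, cell types). Species are compared by resolved TaxID, so either
    side may be an integer TaxID or a term IRI already resolved to one.
    """
    a, b = _as_set(term_a), _as_set(term_b)
    if not a or not b:
        return 0
    if a & b:
        return 1
    use_hierarchy = (element == "disease" and hierarchy_recovery) or (
        element == "cell_type" and cell_type_recovery
    )
    if use_hierarchy:
        for x in a:
            for y in b:
                if isinstance(x, str) and isinstance(y, str) and graph.one_hop_related(x, y):
                    return 1
    return -1


def exact_annotation_match(a: CellLineRecord, b: CellLineRecord) -> bool:
    """Exact label/synonym match or exact cross-reference match."""
    if normalized_names(a.names()) & normalized_names(b.names()):
        return True
    return bool(a.xrefs & b.xrefs)


def c_score(
    record_efo: CellLineRecord,
    record_clo: CellLineRecord,
    graph: TermGraph,
    config: Optional[PipelineConfig] = None,
) -> MatchEvidence:
    """Score one candidate pair: C = sum(M) - SLD."""
    config = config or PipelineConfig()
    m_values: dict[str, int] = {}
    for element in EVIDENCE_ELEMENTS:
        if element == "disease":
            a: TermSide = record_efo.diseases
            b: TermSide = record_clo.diseases
        elif element == "cell_type":
            a, b = record_efo.cell_type, record_clo.cell_type
        elif element == "anatomical_location":
            a, b = record_efo.anatomical_location, record_clo.anatomical_location
        else:  # species: compare by resolved TaxID where possible
            ta = config.resolve_taxid(record_efo.species)
            tb = config.resolve_taxid(record_clo.species)
            a = ta if ta is not None else record_efo.species
            b = tb if tb is not None else record_clo.species
        m_values[element] = element_match(
            a, b, graph, element,
            hierarchy_recovery=config.semantic_recovery,
            cell_type_recovery=config.cell_type_recovery,
        )

    if exact_annotation_match(record_efo, record_clo):
        sld_value = 0
    else:
        sld_value = sld(normalized_names(record_efo.names()),
                        normalized_names(record_clo.names()))
    return MatchEvidence(
        m_values=m_values,
        sld_value=sld_value,
        c_score=sum(m_values.values()) - sld_value,
    )


def rank_candidates(
    record_efo: CellLineRecord,
    clo_records: list[CellLineRecord],
    graph: TermGraph,
    config: Optional[PipelineConfig] = None,
    top_k: Optional[int] = None,
) -> list[RankedCandidate]:
    """Score one record against all candidates, keep the top-k best C-scores.

    Ordering is deterministic: C-score descending, then SLD ascending, then
    IRI lexicographic. Only the top three candidates are kept by default —
    inspecting thousands of candidate pairs per cell line is not practical.
    """
    if not clo_records:
        raise ValueError("rank_candidates requires a non-empty candidate list")
    config = config or PipelineConfig()
    if top_k is None:
        top_k = config.top_k
    scored = [(c_score(record_efo, r, graph, config), r.iri) for r in clo_records]
    scored.sort(key=lambda t: (-t[0].c_score, t[0].sld_value, t[1]))
    return [
        RankedCandidate(clo_iri=iri, evidence=ev, rank=i + 1)
        for i, (ev, iri) in enumerate(scored[:top_k])
    ]


def categorize_direct_match(
    record_efo: CellLineRecord,
    ranked: list[RankedCandidate],
    clo_by_iri: dict[str, CellLineRecord],
    config: Optional[PipelineConfig] = None,
) -> MappingDecision:
    """Assign the direct-mapping outcome category from the ranked candidates.

    EXACT_VALID: the best candidate matches exactly on annotations and no
    evidence element disagrees. EXACT_NEEDS_REVIEW: exact annotation match
    but some element disagrees (manual validation). INEXACT_TOP3: no exact
    match, but the best C-score clears the acceptance threshold (manual
    selection among the top candidates). Otherwise UNMAPPED.
    """
    config = config or PipelineConfig()
    if not ranked:
        return MappingDecision(efo_iri=record_efo.iri, stage=Stage.DIRECT,
                               category=Category.UNMAPPED)
    best = ranked[0]
    exact = exact_annotation_match(record_efo, clo_by_iri[best.clo_iri])
    conflict = any(v == -1 for v in best.evidence.m_values.values())
    if exact and not conflict:
        category, needs_manual = Category.EXACT_VALID, False
    elif exact:
        category, needs_manual = Category.EXACT_NEEDS_REVIEW, True
    elif best.evidence.c_score >= config.inexact_threshold:
        category, needs_manual = Category.INEXACT_TOP3, True
    else:
        return MappingDecision(efo_iri=record_efo.iri, stage=Stage.DIRECT,
                               category=Category.UNMAPPED, candidates=ranked)
    return MappingDecision(
        efo_iri=record_efo.iri,
        stage=Stage.DIRECT,
        category=category,
        clo_iri=best.clo_iri,
        needs_manual=needs_manual,
        evidence=best.evidence,
        candidates=ranked,
    )


def direct_map(
    efo_records: Iterable[CellLineRecord],
    clo_records: list[CellLineRecord],
    graph: TermGraph,
    config: Optional[PipelineConfig] = None,
) -> list[MappingDecision]:
    """Run direct C-score mapping of each record against all candidates."""
    config = config or PipelineConfig()
    clo_by_iri = {r.iri: r for r in clo_records}
    decisions = []
    for rec in efo_records:
        ranked = rank_candidates(rec, clo_records, graph, config)
        decisions.append(categorize_direct_match(rec, ranked, clo_by_iri, config))
    return decisions


def candidates_to_rows(efo_iri: str, ranked: list[RankedCandidate],
                       category: Optional[Category]) -> list[dict]:
    """Flatten a ranked candidate list for TSV export."""
    rows = []
    for c in ranked:
        row = {
            "efo_iri": efo_iri,
            "clo_iri": c.clo_iri,
            "rank": c.rank,
            "c_score": c.evidence.c_score,
            "sld": c.evidence.sld_value,
            "category": category.value if category else "",
        }
        for element in EVIDENCE_ELEMENTS:
            row[f"m_{element}"] = c.evidence.m_values.get(element, 0)
        rows.append(row)
    return rows
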