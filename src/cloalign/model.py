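"""Domain types shared across the alignment pipeline.

The central objects are :class:`CellLineRecord` (one cell-line class pulled
out of an ontology, with its lexical annotations and up to four biological
evidence elements), :class:`CellosaurusEntry` (one flat-file record of the
cross-reference authority), :class:`TermGraph` (asserted subclass edges among
evidence terms, supporting one-hop semantic recovery), and
:class:`MappingDecision` (the unique pipeline outcome per input class).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

#: the four biological evidence elements checked during mapping
EVIDENCE_ELEMENTS = ("disease", "cell_type", "anatomical_location", "species")


class Source(enum.Enum):
    EFO = "EFO"
    CLO = "CLO"
    FOREIGN = "FOREIGN"


class Pattern(enum.Enum):
    """Which design pattern an ontology models cell lines with."""

    EFO_STYLE = "EFO_STYLE"   # population-level "cell line" bearer-of disease
    CLO_STYLE = "CLO_STYLE"   # individual "cell line cell", is-model-for disease


class Stage(enum.Enum):
    """Which pipeline step produced a decision."""

    XREF3WAY = "XREF3WAY"                   # EFO-Cellosaurus-CLO triangulation
    DIRECT = "DIRECT"                       # direct C-score mapping
    UNIQUE_IMMORTALIZED = "UNIQUE_IMMORTALIZED"
    STEM = "STEM"
    PRIMARY = "PRIMARY"
    FOREIGN = "FOREIGN"


class Category(enum.Enum):
    """Outcome category of a mapping attempt."""

    EXACT_VALID = "EXACT_VALID"
    EXACT_NEEDS_REVIEW = "EXACT_NEEDS_REVIEW"
    INEXACT_TOP3 = "INEXACT_TOP3"
    UNMAPPED = "UNMAPPED"


@dataclass
class CellLineRecord:
    """One cell-line class: lexical annotations plus biological evidence."""

    iri: str
    source: Source
    label: str
    synonyms: set[str] = field(default_factory=set)
    xrefs: set[str] = field(default_factory=set)
    diseases: set[str] = field(default_factory=set)
    cell_type: Optional[str] = None
    anatomical_location: Optional[str] = None
    species: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError(f"record {self.iri} has an empty label")
        self.synonyms.discard(self.label)

    def names(self) -> set[str]:
        """Label plus synonyms — the name set lexical comparison runs over."""
        return {self.label} | self.synonyms


@dataclass
class CellosaurusEntry:
    """One record of the Cellosaurus-dialect flat file."""

    accession: str
    name: str
    synonyms: set[str] = field(default_factory=set)
    xrefs: set[tuple[str, str]] = field(default_factory=set)
    diseases: set[tuple[str, str]] = field(default_factory=set)  # (terminology:id, label)
    species_taxids: set[int] = field(default_factory=set)
    category: str = "Undefined"

    def names(self) -> set[str]:
        return {self.name} | self.synonyms


@dataclass
class TermGraph:
    """Asserted direct subclass edges among referenced terms.

    Edges are (child, parent) pairs; only asserted direct relations are
    stored, never the transitive closure, so one-hop recovery stays one hop.
    """

    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str]] = field(default_factory=set)
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, parent in self.edges:
            self.nodes.add(child)
            self.nodes.add(parent)

    def is_direct_parent(self, parent: str, child: str) -> bool:
        return (child, parent) in self.edges

    def one_hop_related(self, a: str, b: str) -> bool:
        """True iff a and b stand in a direct subclass relation (either way)."""
        return (a, b) in self.edges or (b, a) in self.edges

    def find_by_label(self, normalized_label: str,
                      normalizer) -> set[str]:
        """Term IRIs whose label normalizes to ``normalized_label``."""
        return {iri for iri, lab in self.labels.items()
                if normalizer(lab) == normalized_label}


@dataclass
class MatchEvidence:
    """Per-element match values, lexical distance, and the confidence score.

    The confidence score is the sum of the element-match values minus the
    shortest Levenshtein distance between the two records' name sets.
    """

    m_values: dict[str, int]
    sld_value: int
    c_score: int

    def __post_init__(self) -> None:
        assert set(self.m_values) <= set(EVIDENCE_ELEMENTS)
        assert self.c_score == sum(self.m_values.values()) - self.sld_value


@dataclass
class RankedCandidate:
    clo_iri: str
    evidence: MatchEvidence
    rank: int


@dataclass
class MappingDecision:
    """The unique pipeline outcome assigned to one input cell-line class."""

    efo_iri: str
    stage: Stage
    category: Optional[Category] = None
    clo_iri: Optional[str] = None
    needs_manual: bool = False
    recovery_used: bool = False
    evidence: Optional[MatchEvidence] = None
    candidates: list[RankedCandidate] = field(default_factory=list)
    note: str = ""

    @property
    def is_mapped(self) -> bool:
        """True when the class has an accepted CLO partner."""
        return self.clo_iri is not None and self.category is not Category.UNMAPPED


def decisions_by_iri(decisions: Iterable[MappingDecision]) -> dict[str, MappingDecision]:
    out: dict[str, MappingDecision] = {}
    for d in decisions:
        if d.efo_iri in out:
            raise ValueError(f"duplicate decision for {d.efo_iri}")
        out[d.efo_iri] = d
    return out
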