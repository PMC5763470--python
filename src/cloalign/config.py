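"""Pipeline configuration.

All ontology-specific IRIs (root classes, design-pattern object properties,
annotation properties, namespaces) are configurable so the pipeline can be
pointed at real EFO/CLO releases or at synthetic fixture corpora. The
defaults match the IRIs the bundled fixture generator emits; the canonical
RO properties (bearer of, derives from, in taxon) carry their real OBO ids.
"""

from __future__ import annotations

import re
from typing import Optional

import yaml
from pydantic import BaseModel, Field

# -- annotation properties (OBO / EFO conventions) ---------------------------
RDFS_LABEL = "http://www.w3.org/2000/01/rdf-schema#label"
EXACT_SYNONYM = "http://www.geneontology.org/formats/oboInOwl#hasExactSynonym"
ALTERNATIVE_TERM = "http://www.ebi.ac.uk/efo/alternative_term"
DB_XREF = "http://www.geneontology.org/formats/oboInOwl#hasDbXref"
OWL_DEPRECATED = "http://www.w3.org/2002/07/owl#deprecated"
TERM_REPLACED_BY = "http://purl.obolibrary.org/obo/IAO_0100001"

# -- design-pattern object properties ----------------------------------------
BEARER_OF = "http://purl.obolibrary.org/obo/RO_0000053"
IS_MODEL_FOR = "http://purl.obolibrary.org/obo/RO_0003301"
DERIVES_FROM = "http://purl.obolibrary.org/obo/RO_0001000"
IN_TAXON = "http://purl.obolibrary.org/obo/RO_0002162"
LOCATED_IN = "http://purl.obolibrary.org/obo/RO_0001025"
HAS_GRAIN = "http://purl.obolibrary.org/obo/clo#has_grain"

_NCBITAXON_RE = re.compile(r"NCBITaxon[_:](\d+)$")


class PatternConfig(BaseModel):
    """One ontology design pattern: root class plus evidence-linking properties."""

    root_class: str
    disease_property: str
    cell_type_property: str = DERIVES_FROM
    anatomy_property: str = LOCATED_IN
    species_property: str = IN_TAXON


class AnnotationConfig(BaseModel):
    label: str = RDFS_LABEL
    synonyms: tuple[str, ...] = (EXACT_SYNONYM, ALTERNATIVE_TERM)
    db_xref: str = DB_XREF
    deprecated: str = OWL_DEPRECATED
    replaced_by: str = TERM_REPLACED_BY


class PipelineConfig(BaseModel):
    """Everything the four-step alignment workflow needs besides the inputs."""

    efo_namespace: str = "http://www.ebi.ac.uk/efo/"
    clo_namespace: str = "http://purl.obolibrary.org/obo/CLO_"

    efo_pattern: PatternConfig = Field(
        default_factory=lambda: PatternConfig(
            root_class="http://www.ebi.ac.uk/efo/EFO_0000322",
            disease_property=BEARER_OF,
        )
    )
    clo_pattern: PatternConfig = Field(
        default_factory=lambda: PatternConfig(
            root_class="http://purl.obolibrary.org/obo/CLO_0000001",
            disease_property=IS_MODEL_FOR,
        )
    )
    annotations: AnnotationConfig = Field(default_factory=AnnotationConfig)

    # matching behaviour
    top_k: int = 3
    inexact_threshold: int = 0          # minimum C-score to accept an inexact match
    semantic_recovery: bool = True      # one-hop disease subclass recovery
    cell_type_recovery: bool = False    # one-hop cell-type recovery (off by default)

    # synchronization behaviour
    population_companion: bool = True   # emit a has-grain population class per ADD
    population_root: str = "http://purl.obolibrary.org/obo/CLO_0000000"
    has_grain_property: str = HAS_GRAIN

    # species resolution: term IRI -> NCBI TaxID (NCBITaxon IRIs parse automatically)
    taxon_iri_map: dict[str, int] = Field(default_factory=dict)
    # Cellosaurus disease terminology id (e.g. "NCIt:C3512") -> ontology term IRI;
    # terms not listed here are resolved by normalized-label lookup in the TermGraph.
    disease_xref_map: dict[str, str] = Field(default_factory=dict)

    def resolve_taxid(self, term_iri: Optional[str]) -> Optional[int]:
        """Map a taxon term IRI to an integer NCBI TaxID, or None."""
        if term_iri is None:
            return None
        if term_iri in self.taxon_iri_map:
            return self.taxon_iri_map[term_iri]
        m = _NCBITAXON_RE.search(term_iri)
        return int(m.group(1)) if m else None

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.model_validate(data)
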