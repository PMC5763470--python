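"""Shared fixtures: hand-built motif ontologies and naive oracles."""

from __future__ import annotations

import pytest
from rdflib import BNode, Graph, Literal, URIRef, RDF, RDFS, OWL

from cloalign.config import PipelineConfig
from cloalign.model import CellLineRecord, Source, TermGraph

EFO_NS = "http://www.ebi.ac.uk/efo/"
OBO = "http://purl.obolibrary.org/obo/"


def naive_levenshtein(a: str, b: str) -> int:
    """Textbook O(nm) dynamic-programming edit distance (unit costs)."""
    n, m = len(a), len(b)
    d = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        d[i][0] = i
    for j in range(m + 1):
        d[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            d[i][j] = min(
                d[i - 1][j] + 1,
                d[i][j - 1] + 1,
                d[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
    return d[n][m]


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


def add_restriction(g: Graph, cls: str, prop: str, filler: str, tag: str) -> None:
    b = BNode(tag)
    g.add((URIRef(cls), RDFS.subClassOf, b))
    g.add((b, RDF.type, OWL.Restriction))
    g.add((b, OWL.onProperty, URIRef(prop)))
    g.add((b, OWL.someValuesFrom, URIRef(filler)))


def add_class(g: Graph, iri: str, label: str, parent: str | None = None) -> None:
    g.add((URIRef(iri), RDF.type, OWL.Class))
    g.add((URIRef(iri), RDFS.label, Literal(label)))
    if parent:
        g.add((URIRef(iri), RDFS.subClassOf, URIRef(parent)))


# -- disease motif: a specific term below two different general terms --------

LUNG_CARCINOMA = f"{EFO_NS}EFO_0001071"          # recorded on the EFO side
LUNG_ADENOCARCINOMA = f"{OBO}MONDO_0005061"      # assigned by Cellosaurus
ADENOCARCINOMA = f"{OBO}MONDO_0004970"           # recorded on the CLO side


@pytest.fixture
def motif_graph() -> TermGraph:
    """NCI-H2087-style disease triangle: one specific child of two generals."""
    return TermGraph(
        edges={
            (LUNG_ADENOCARCINOMA, LUNG_CARCINOMA),
            (LUNG_ADENOCARCINOMA, ADENOCARCINOMA),
        },
        labels={
            LUNG_CARCINOMA: "lung carcinoma",
            LUNG_ADENOCARCINOMA: "lung adenocarcinoma",
            ADENOCARCINOMA: "adenocarcinoma",
        },
    )


HUMAN = f"{OBO}NCBITaxon_9606"


def make_record(iri: str, label: str, source=Source.EFO, **kw) -> CellLineRecord:
    return CellLineRecord(iri=iri, source=source, label=label, **kw)


@pytest.fixture
def h2087_records() -> tuple[CellLineRecord, CellLineRecord]:
    efo = make_record(
        f"{EFO_NS}EFO_0900001", "NCI-H2087",
        xrefs={"CELLOSAURUS:CVCL_1524"}, diseases={LUNG_CARCINOMA}, species=HUMAN,
    )
    clo = make_record(
        f"{OBO}CLO_0900001", "NCI-H2087 cell", source=Source.CLO,
        synonyms={"NCI-H2087"}, xrefs={"CELLOSAURUS:CVCL_1524"},
        diseases={ADENOCARCINOMA}, species=HUMAN,
    )
    return efo, clo


H2087_CELLOSAURUS = """\
synthetic header line
--------------------
ID   NCI-H2087
AC   CVCL_1524
SY   NCIH2087; H2087
DR   ATCC; CRL-5922
DI   NCIt; C0152013; lung adenocarcinoma
OX   NCBI_TaxID=9606; ! Homo sapiens
CA   Cancer cell line
//
"""


@pytest.fixture
def h2087_cellosaurus_text() -> str:
    return H2087_CELLOSAURUS
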