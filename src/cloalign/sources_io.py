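"""Input parsing: Cellosaurus flat file and OWL cell-line extraction.

Two readers live here. ``parse_cellosaurus`` handles the line-oriented
Cellosaurus text dialect (two-letter line codes, ``//`` record terminator);
``extract_cell_line_records`` walks an RDF graph and pulls one
:class:`~cloalign.model.CellLineRecord` per subclass of the configured root
class, reading the biological evidence from the existential restrictions of
the configured design pattern. ``build_term_graph`` collects the asserted
subclass edges among evidence terms that one-hop semantic recovery needs.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, TextIO, Union

import networkx as nx
from rdflib import Graph, URIRef, RDF, RDFS, OWL, Literal

from .config import PatternConfig, AnnotationConfig, PipelineConfig
from .lexical import normalize_xref
from .model import CellLineRecord, CellosaurusEntry, Pattern, Source, TermGraph

log = logging.getLogger(__name__)


class CellosaurusParseError(Exception):
    pass


# ---------------------------------------------------------------------------
# Cellosaurus dialect
# ---------------------------------------------------------------------------

_KNOWN_CODES = {"ID", "AC", "SY", "DR", "DI", "OX", "CA"}


def parse_cellosaurus(
    stream: Union[str, TextIO],
    errors: Optional[list[str]] = None,
) -> list[CellosaurusEntry]:
    """Parse a Cellosaurus-dialect flat file into entries.

    Record-level problems (a ``//``-terminated block missing its ID or AC
    line) are collected into *errors* and parsing continues; a duplicate
    accession is a hard error. Header lines before the first ID are ignored,
    and unknown line codes inside a block are preserved-ignored.
    """
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        text = stream
    if errors is None:
        errors = []

    entries: list[CellosaurusEntry] = []
    seen: dict[str, int] = {}
    block: list[tuple[str, str]] = []
    in_body = False

    def flush(lines: list[tuple[str, str]]) -> None:
        fields: dict[str, list[str]] = {}
        for code, value in lines:
            fields.setdefault(code, []).append(value)
        if "ID" not in fields or "AC" not in fields:
            errors.append(
                "record missing %s: %r"
                % (" and ".join(c for c in ("ID", "AC") if c not in fields),
                   lines[:2])
            )
            return
        accession = fields["AC"][0]
        if accession in seen:
            raise CellosaurusParseError(f"duplicate accession {accession}")
        seen[accession] = 1

        synonyms: set[str] = set()
        for sy in fields.get("SY", []):
            synonyms.update(s for s in sy.split("; ") if s)
        xrefs: set[tuple[str, str]] = set()
        for dr in fields.get("DR", []):
            parts = [p.strip() for p in dr.split(";", 1)]
            if len(parts) == 2:
                xrefs.add((parts[0], parts[1]))
        diseases: set[tuple[str, str]] = set()
        for di in fields.get("DI", []):
            parts = [p.strip() for p in di.split(";", 2)]
            if len(parts) == 3:
                diseases.add((f"{parts[0]}:{parts[1]}", parts[2]))
        taxids: set[int] = set()
        for ox in fields.get("OX", []):
            for tok in ox.replace(";", " ").split():
                if tok.startswith("NCBI_TaxID="):
                    try:
                        taxids.add(int(tok.split("=", 1)[1]))
                    except ValueError:
                        pass
        category = fields.get("CA", ["Undefined"])[0].strip() or "Undefined"
        entries.append(CellosaurusEntry(
            accession=accession,
            name=fields["ID"][0],
            synonyms=synonyms,
            xrefs=xrefs,
            diseases=diseases,
            species_taxids=taxids,
            category=category,
        ))

    for raw_line in text.splitlines():
        line = raw_line.rstrip("\n")
        if line.strip() == "//":
            if block:
                flush(block)
            block = []
            in_body = True
            continue
        code, value = line[:2], line[2:].strip()
        if not in_body:
            # the header ends at the first recognizable record line
            if code in _KNOWN_CODES and (len(line) <= 2 or line[2] == " "):
                in_body = True
            else:
                continue
        if line.strip():
            block.append((code, value))
    if block:
        flush(block)
    return entries


def serialize_cellosaurus(entries: Iterable[CellosaurusEntry]) -> str:
    """Write entries back to the Cellosaurus dialect (deterministic order)."""
    out: list[str] = []
    for e in entries:
        out.append(f"ID   {e.name}")
        out.append(f"AC   {e.accession}")
        if e.synonyms:
            out.append("SY   " + "; ".join(sorted(e.synonyms)))
        for res, ident in sorted(e.xrefs):
            out.append(f"DR   {res}; {ident}")
        for term, label in sorted(e.diseases):
            terminology, ident = term.split(":", 1)
            out.append(f"DI   {terminology}; {ident}; {label}")
        for taxid in sorted(e.species_taxids):
            out.append(f"OX   NCBI_TaxID={taxid}; ! synthetic")
        out.append(f"CA   {e.category}")
        out.append("//")
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# OWL extraction
# ---------------------------------------------------------------------------

def _subclasses_transitive(graph: Graph, root: URIRef) -> list[URIRef]:
    """Named direct-or-transitive subclasses of root, over asserted axioms."""
    seen: set[URIRef] = set()
    frontier = [root]
    while frontier:
        parent = frontier.pop()
        for child in graph.subjects(RDFS.subClassOf, parent):
            if isinstance(child, URIRef) and child not in seen:
                seen.add(child)
                frontier.append(child)
    return sorted(seen)


def _restriction_fillers(graph: Graph, cls: URIRef, prop: URIRef) -> set[str]:
    """Named fillers of ``cls subClassOf (prop some Filler)`` axioms."""
    fillers: set[str] = set()
    for sup in graph.objects(cls, RDFS.subClassOf):
        if isinstance(sup, URIRef):
            continue
        if (sup, OWL.onProperty, prop) not in graph:
            continue
        for filler in graph.objects(sup, OWL.someValuesFrom):
            if isinstance(filler, URIRef):
                fillers.add(str(filler))
    return fillers


def _is_deprecated(graph: Graph, cls: URIRef, ann: AnnotationConfig) -> bool:
    for v in graph.objects(cls, URIRef(ann.deprecated)):
        if isinstance(v, Literal) and v.toPython() in (True, "true"):
            return True
    return False


def record_source(iri: str, config: PipelineConfig) -> Source:
    if iri.startswith(config.efo_namespace):
        return Source.EFO
    if iri.startswith(config.clo_namespace):
        return Source.CLO
    return Source.FOREIGN


def extract_cell_line_records(
    graph: Graph,
    pattern: Pattern,
    config: PipelineConfig,
) -> list[CellLineRecord]:
    """Extract one record per (transitive) subclass of the pattern's root.

    Diseases come from existential restrictions on the pattern's disease
    property (``bearer of`` for the population pattern, ``is model for`` for
    the cell-line-cell pattern); cell type, anatomy and species likewise.
    Labels and synonyms come from the configured annotation properties,
    cross-references from the db-xref annotation, normalized. A missing root
    class is a hard error; a subclass without a label is skipped with a
    warning; deprecated classes are skipped.
    """
    pat: PatternConfig = (
        config.efo_pattern if pattern is Pattern.EFO_STYLE else config.clo_pattern
    )
    ann = config.annotations
    root = URIRef(pat.root_class)
    if (root, None, None) not in graph and (None, None, root) not in graph:
        raise ValueError(f"root class {pat.root_class} absent from ontology")

    records: list[CellLineRecord] = []
    for cls in _subclasses_transitive(graph, root):
        if _is_deprecated(graph, cls, ann):
            continue
        label = graph.value(cls, URIRef(ann.label))
        if label is None or not str(label).strip():
            log.warning("skipping %s: no label", cls)
            continue
        synonyms: set[str] = set()
        for syn_prop in ann.synonyms:
            synonyms.update(str(v) for v in graph.objects(cls, URIRef(syn_prop)))
        xrefs = {normalize_xref(str(v))
                 for v in graph.objects(cls, URIRef(ann.db_xref))}
        diseases = _restriction_fillers(graph, cls, URIRef(pat.disease_property))
        cell_types = _restriction_fillers(graph, cls, URIRef(pat.cell_type_property))
        anatomy = _restriction_fillers(graph, cls, URIRef(pat.anatomy_property))
        species = _restriction_fillers(graph, cls, URIRef(pat.species_property))
        records.append(CellLineRecord(
            iri=str(cls),
            source=record_source(str(cls), config),
            label=str(label),
            synonyms=synonyms,
            xrefs={x for x in xrefs if x},
            diseases=diseases,
            cell_type=min(cell_types) if cell_types else None,
            anatomical_location=min(anatomy) if anatomy else None,
            species=min(species) if species else None,
        ))
    return records


def partition_by_namespace(
    records: Iterable[CellLineRecord],
    config: PipelineConfig,
) -> tuple[list[CellLineRecord], list[CellLineRecord]]:
    """Split records from the population-pattern input into native vs foreign.

    Cell lines drawn into EFO from external namespaces (CLO, BTO, ...) are
    excluded from mapping and kept as imports.
    """
    native = [r for r in records if r.iri.startswith(config.efo_namespace)]
    foreign = [r for r in records if not r.iri.startswith(config.efo_namespace)]
    return native, foreign


def build_term_graph(
    graphs: Iterable[Graph],
    evidence_terms: Optional[set[str]] = None,
) -> TermGraph:
    """Union of asserted named-class subclass edges over the input graphs.

    When *evidence_terms* is given the graph is restricted to those terms,
    their asserted (transitive) parents, and their direct children — the
    children are what one-hop recovery through a third-party term needs
    (the shared specific term sits *below* both recorded diseases). Only
    direct asserted edges are stored. A cycle among asserted subclass
    axioms is a hard error.
    """
    dg = nx.DiGraph()
    labels: dict[str, str] = {}
    for g in graphs:
        for child, parent in g.subject_objects(RDFS.subClassOf):
            if isinstance(child, URIRef) and isinstance(parent, URIRef):
                dg.add_edge(str(child), str(parent))
        for s, o in g.subject_objects(RDFS.label):
            if isinstance(s, URIRef):
                labels.setdefault(str(s), str(o))

    try:
        cycle = nx.find_cycle(dg)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        path = " -> ".join(edge[0] for edge in cycle)
        raise ValueError(f"cycle among asserted subclass axioms: {path}")

    if evidence_terms is not None:
        keep: set[str] = set(evidence_terms)
        frontier = [t for t in evidence_terms if t in dg]
        for t in list(frontier):
            keep.update(dg.predecessors(t))  # direct children
        while frontier:
            node = frontier.pop()
            if node not in dg:
                continue
            for parent in dg.successors(node):
                if parent not in keep:
                    keep.add(parent)
                    frontier.append(parent)
        dg = dg.subgraph([n for n in dg if n in keep]).copy()
        nodes = set(keep)
    else:
        nodes = set(dg.nodes)

    return TermGraph(
        nodes=nodes,
        edges={(c, p) for c, p in dg.edges},
        labels={iri: lab for iri, lab in sorted(labels.items()) if iri in nodes},
    )


def evidence_terms_of(records: Iterable[CellLineRecord]) -> set[str]:
    """All term IRIs referenced by the records' evidence fields."""
    terms: set[str] = set()
    for r in records:
        terms.update(r.diseases)
        for t in (r.cell_type, r.anatomical_location, r.species):
            if t:
                terms.add(t)
    return terms
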