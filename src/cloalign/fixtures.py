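"""Deterministic synthetic corpora for exercising the whole pipeline.

The generator emits a paired population-pattern ontology, a cell-line-cell
pattern ontology, a Cellosaurus-dialect flat file and a ground-truth
manifest, composed the way the real inputs are: planted true pairs sharing a
unique Cellosaurus accession (with controlled label corruption on the
cell-line-cell side), pairs whose disease annotations disagree but are
recoverable through a one-hop subclass motif, pairs matchable only by direct
mapping (non-unique cross-references), unique immortalized lines with no
partner, stem-cell lines, xref-less primary lines, foreign-namespace
imports, and lexically distant decoys.

Default composition scales the real corpus proportions down to desk scale;
see docs/methods.md. All randomness flows from the seed; outputs are
byte-identical for a fixed spec.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from typing import Optional

from pydantic import BaseModel, Field, model_validator
from rdflib import BNode, Graph, Literal, URIRef, RDF, RDFS, OWL

from .config import PipelineConfig
from .lexical import levenshtein, normalize_label, normalized_names
from .model import (
    Category,
    CellLineRecord,
    MappingDecision,
    Stage,
    decisions_by_iri,
)

TERM_NS = "http://example.org/synthetic/"
FOREIGN_NS = "http://purl.obolibrary.org/obo/BTO_"


class CorpusSpec(BaseModel):
    """Composition of one synthetic corpus (all counts of cell-line classes)."""

    seed: int = 17
    n_true_pairs: int = 88
    n_semantic_recovery_pairs: int = 19
    n_nonunique_xref_pairs: int = 6
    n_unique_immortalized: int = 49
    n_stem: int = 9
    n_primary: int = 5
    n_foreign: int = 64
    label_corruption_distance: int = 1
    decoy_count: int = 30
    element_missing_rate: float = 0.1

    @model_validator(mode="after")
    def _check(self) -> "CorpusSpec":
        for name in ("n_true_pairs", "n_semantic_recovery_pairs",
                     "n_nonunique_xref_pairs", "n_unique_immortalized",
                     "n_stem", "n_primary", "n_foreign",
                     "label_corruption_distance", "decoy_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.element_missing_rate <= 1.0:
            raise ValueError("element_missing_rate must be in [0, 1]")
        return self


@dataclass
class GroundTruth:
    """Expected pipeline outcome for every generated class."""

    pairs: dict[str, tuple[Stage, Optional[str]]] = field(default_factory=dict)
    recovery_flags: set[str] = field(default_factory=set)

    def expected_counts(self) -> dict[str, int]:
        counts = {"mapped": 0, "unique_immortalized": 0, "imported": 0,
                  "stem": 0, "primary": 0}
        for stage, _ in self.pairs.values():
            if stage in (Stage.XREF3WAY, Stage.DIRECT):
                counts["mapped"] += 1
            elif stage is Stage.UNIQUE_IMMORTALIZED:
                counts["unique_immortalized"] += 1
            elif stage is Stage.FOREIGN:
                counts["imported"] += 1
            elif stage is Stage.STEM:
                counts["stem"] += 1
            elif stage is Stage.PRIMARY:
                counts["primary"] += 1
        return counts

    def to_manifest_rows(self) -> list[dict]:
        return [
            {"efo_iri": iri, "expected_stage": stage.value,
             "expected_clo_iri": clo or "",
             "needs_recovery": int(iri in self.recovery_flags)}
            for iri, (stage, clo) in sorted(self.pairs.items())
        ]


# ---------------------------------------------------------------------------
# name machinery
# ---------------------------------------------------------------------------

def _fresh_name(rng: random.Random, taken: list[str], min_sep: int = 6) -> str:
    """A base name at Levenshtein distance >= min_sep from all taken names."""
    while True:
        stem = "".join(rng.choice(string.ascii_lowercase) for _ in range(8))
        cand = f"{stem}-{rng.randrange(10, 99)}"
        if all(levenshtein(cand, t) >= min_sep for t in taken):
            taken.append(cand)
            return cand


def corrupt_label(name: str, distance: int, rng: random.Random,
                  require_change: bool = False) -> str:
    """Apply ``distance`` seeded edit operations to a label.

    Operations are drawn from {insert hyphen, delete character, substitute
    character, case flip}; with *require_change* the case-flip operation is
    excluded and the result is guaranteed lexically distinct after
    normalization.
    """
    ops = ["insert", "delete", "substitute"] + ([] if require_change else ["flip"])
    for _ in range(50):
        chars = list(name)
        for _ in range(distance):
            op = rng.choice(ops)
            pos = rng.randrange(len(chars)) if chars else 0
            if op == "insert":
                chars.insert(pos, "-")
            elif op == "delete" and chars:
                del chars[pos]
            elif op == "substitute" and chars:
                chars[pos] = rng.choice(string.ascii_lowercase)
            elif op == "flip" and chars:
                chars[pos] = chars[pos].swapcase()
        out = "".join(chars)
        if not require_change or normalize_label(out) != normalize_label(name):
            return out
    return name + "-x"  # pathological inputs only


# ---------------------------------------------------------------------------
# graph assembly
# ---------------------------------------------------------------------------

class _GraphBuilder:
    """Accumulates triples with deterministic blank-node naming."""

    def __init__(self) -> None:
        self.graph = Graph()
        self._n = 0

    def cls(self, iri: str, label: str, parent: Optional[str] = None) -> URIRef:
        c = URIRef(iri)
        self.graph.add((c, RDF.type, OWL.Class))
        self.graph.add((c, RDFS.label, Literal(label)))
        if parent:
            self.graph.add((c, RDFS.subClassOf, URIRef(parent)))
        return c

    def annotate(self, iri: str, prop: str, value: str) -> None:
        self.graph.add((URIRef(iri), URIRef(prop), Literal(value)))

    def restriction(self, iri: str, prop: str, filler: str) -> None:
        self._n += 1
        b = BNode(f"gen{self._n:06d}")
        self.graph.add((URIRef(iri), RDFS.subClassOf, b))
        self.graph.add((b, RDF.type, OWL.Restriction))
        self.graph.add((b, OWL.onProperty, URIRef(prop)))
        self.graph.add((b, OWL.someValuesFrom, URIRef(filler)))


def generate_corpus(
    spec: CorpusSpec,
    config: Optional[PipelineConfig] = None,
) -> tuple[Graph, Graph, str, GroundTruth]:
    """Generate (efo_graph, clo_graph, cellosaurus_text, ground_truth)."""
    config = config or PipelineConfig()
    rng = random.Random(spec.seed)
    efo = _GraphBuilder()
    clo = _GraphBuilder()
    truth = GroundTruth()
    cvs_blocks: list[str] = []
    taken_names: list[str] = []

    efo_pat, clo_pat, ann = config.efo_pattern, config.clo_pattern, config.annotations
    efo.cls(efo_pat.root_class, "cell line")
    clo.cls(clo_pat.root_class, "cell line cell")
    clo.cls(config.population_root, "cell line")

    # shared synthetic vocabularies ----------------------------------------
    disease_root = f"{TERM_NS}SYND_0000000"
    for b in (efo, clo):
        b.cls(disease_root, "disease")
    diseases = []
    for i in range(12):
        iri = f"{TERM_NS}SYND_{i + 1:07d}"
        for b in (efo, clo):
            b.cls(iri, f"synthetic disease {i + 1}", disease_root)
        diseases.append(iri)
    cell_types = []
    for i in range(6):
        iri = f"{TERM_NS}SYNC_{i + 1:07d}"
        for b in (efo, clo):
            b.cls(iri, f"synthetic cell type {i + 1}")
        cell_types.append(iri)
    anatomies = []
    for i in range(6):
        iri = f"{TERM_NS}SYNA_{i + 1:07d}"
        for b in (efo, clo):
            b.cls(iri, f"synthetic organism part {i + 1}")
        anatomies.append(iri)
    taxa = ["http://purl.obolibrary.org/obo/NCBITaxon_9606"] * 5 + [
        "http://purl.obolibrary.org/obo/NCBITaxon_10090"]
    for b in (efo, clo):
        b.cls(taxa[0], "Homo sapiens")
        b.cls(taxa[-1], "Mus musculus")

    term_labels = {iri: f"synthetic disease {i + 1}"
                   for i, iri in enumerate(diseases)}

    acc_counter = 0

    def next_accession() -> str:
        nonlocal acc_counter
        acc_counter += 1
        return f"CVCL_{acc_counter:04d}"

    def cvs_block(name: str, accession: str, synonyms: list[str],
                  disease: Optional[tuple[str, str]], taxid: int,
                  category: str) -> None:
        lines = [f"ID   {name}", f"AC   {accession}"]
        if synonyms:
            lines.append("SY   " + "; ".join(synonyms))
        lines.append(f"DR   ATCC; SYN-{accession[-4:]}")
        if disease:
            term_iri, label = disease
            local = term_iri.rsplit("/", 1)[-1]
            prefix, ident = local.split("_", 1)
            lines.append(f"DI   {prefix}; {ident}; {label}")
        lines.append(f"OX   NCBI_TaxID={taxid}; ! synthetic species")
        lines.append(f"CA   {category}")
        lines.append("//")
        cvs_blocks.append("\n".join(lines))

    efo_counter = 0

    def next_efo_iri() -> str:
        nonlocal efo_counter
        efo_counter += 1
        return f"{config.efo_namespace}EFO_{1000000 + efo_counter:07d}"

    clo_counter = 0

    def next_clo_iri() -> str:
        nonlocal clo_counter
        clo_counter += 1
        return f"{config.clo_namespace}{1000 + clo_counter:07d}"

    def maybe(value, exempt: bool = False):
        if exempt or value is None:
            return value
        return None if rng.random() < spec.element_missing_rate else value

    def emit_efo_record(iri: str, label: str, xrefs: list[str],
                        disease: Optional[str], ct: Optional[str],
                        anat: Optional[str], taxon: Optional[str]) -> None:
        efo.cls(iri, label, efo_pat.root_class)
        for x in xrefs:
            efo.annotate(iri, ann.db_xref, x)
        if disease:
            efo.restriction(iri, efo_pat.disease_property, disease)
        if ct:
            efo.restriction(iri, efo_pat.cell_type_property, ct)
        if anat:
            efo.restriction(iri, efo_pat.anatomy_property, anat)
        if taxon:
            efo.restriction(iri, efo_pat.species_property, taxon)

    def emit_clo_record(iri: str, base_label: str, xrefs: list[str],
                        disease: Optional[str], ct: Optional[str],
                        anat: Optional[str], taxon: Optional[str]) -> None:
        clo.cls(iri, base_label + " cell", clo_pat.root_class)
        clo.annotate(iri, ann.synonyms[0], base_label)
        for x in xrefs:
            clo.annotate(iri, ann.db_xref, x)
        if disease:
            clo.restriction(iri, clo_pat.disease_property, disease)
        if ct:
            clo.restriction(iri, clo_pat.cell_type_property, ct)
        if anat:
            clo.restriction(iri, clo_pat.anatomy_property, anat)
        if taxon:
            clo.restriction(iri, clo_pat.species_property, taxon)

    def pick_elements() -> tuple[str, str, str, int]:
        taxon = rng.choice(taxa)
        return (rng.choice(cell_types), rng.choice(anatomies), taxon,
                int(taxon.rsplit("_", 1)[-1]))

    # true pairs triangulated through a unique accession --------------------
    for _ in range(spec.n_true_pairs):
        name = _fresh_name(rng, taken_names)
        acc = next_accession()
        disease = rng.choice(diseases)
        ct, anat, taxon, taxid = pick_elements()
        corrupted = corrupt_label(name, spec.label_corruption_distance, rng)
        e_iri, c_iri = next_efo_iri(), next_clo_iri()
        emit_efo_record(e_iri, name, [f"Cellosaurus:{acc}"],
                        maybe(disease), maybe(ct), maybe(anat), maybe(taxon))
        emit_clo_record(c_iri, corrupted, [acc],
                        maybe(disease), maybe(ct), maybe(anat), maybe(taxon))
        sy = [corrupted] if normalize_label(corrupted) != normalize_label(name) else []
        cvs_block(name, acc, sy, (disease, term_labels[disease]), taxid,
                  "Cancer cell line")
        truth.pairs[e_iri] = (Stage.XREF3WAY, c_iri)

    # pairs recoverable only through the one-hop disease motif --------------
    for j in range(spec.n_semantic_recovery_pairs):
        name = _fresh_name(rng, taken_names)
        acc = next_accession()
        specific = f"{TERM_NS}SYND_{2000 + j:07d}"
        general_a = f"{TERM_NS}SYND_{3000 + j:07d}"
        general_b = f"{TERM_NS}SYND_{4000 + j:07d}"
        lab_s = f"specific disease {j + 1}"
        for b in (efo, clo):
            b.cls(general_a, f"general disease A{j + 1}", disease_root)
            b.cls(general_b, f"general disease B{j + 1}", disease_root)
        efo.cls(specific, lab_s, general_a)   # asserted in one source...
        clo.cls(specific, lab_s, general_b)   # ...and in the other
        ct, anat, taxon, taxid = pick_elements()
        corrupted = corrupt_label(
            name, max(1, spec.label_corruption_distance), rng, require_change=True)
        e_iri, c_iri = next_efo_iri(), next_clo_iri()
        emit_efo_record(e_iri, name, [f"Cellosaurus:{acc}"],
                        general_a, maybe(ct), maybe(anat), maybe(taxon))
        emit_clo_record(c_iri, corrupted, [acc],
                        general_b, maybe(ct), maybe(anat), maybe(taxon))
        cvs_block(name, acc, [corrupted], (specific, lab_s), taxid,
                  "Cancer cell line")
        truth.pairs[e_iri] = (Stage.XREF3WAY, c_iri)
        truth.recovery_flags.add(e_iri)

    # pairs deferred to direct mapping (non-unique cross-references) --------
    for _ in range(spec.n_nonunique_xref_pairs):
        name = _fresh_name(rng, taken_names)
        acc, acc2 = next_accession(), next_accession()
        disease = rng.choice(diseases)
        ct, anat, taxon, taxid = pick_elements()
        corrupted = corrupt_label(name, spec.label_corruption_distance, rng)
        e_iri, c_iri = next_efo_iri(), next_clo_iri()
        emit_efo_record(e_iri, name, [f"Cellosaurus:{acc}", f"Cellosaurus:{acc2}"],
                        maybe(disease), maybe(ct), maybe(anat), maybe(taxon))
        emit_clo_record(c_iri, corrupted, [acc],
                        maybe(disease), maybe(ct), maybe(anat), maybe(taxon))
        sy = [corrupted] if normalize_label(corrupted) != normalize_label(name) else []
        cvs_block(name, acc, sy, (disease, term_labels[disease]), taxid,
                  "Cancer cell line")
        cvs_block(name + " duplicate", acc2, [], None, taxid, "Cancer cell line")
        truth.pairs[e_iri] = (Stage.DIRECT, c_iri)

    # unique immortalized lines: traceable in Cellosaurus, no partner -------
    for _ in range(spec.n_unique_immortalized):
        name = _fresh_name(rng, taken_names)
        acc = next_accession()
        disease = rng.choice(diseases)
        ct, anat, taxon, taxid = pick_elements()
        e_iri = next_efo_iri()
        emit_efo_record(e_iri, name, [f"Cellosaurus:{acc}"],
                        maybe(disease), maybe(ct), maybe(anat), maybe(taxon))
        cvs_block(name, acc, [], (disease, term_labels[disease]), taxid,
                  "Cancer cell line")
        truth.pairs[e_iri] = (Stage.UNIQUE_IMMORTALIZED, None)

    # stem-cell lines: stay in the source namespace -------------------------
    for _ in range(spec.n_stem):
        name = _fresh_name(rng, taken_names)
        acc = next_accession()
        e_iri = next_efo_iri()
        emit_efo_record(e_iri, name, [f"Cellosaurus:{acc}"],
                        None, maybe(rng.choice(cell_types)), None, taxa[0])
        cvs_block(name, acc, [], None, 9606, "Embryonic stem cell")
        truth.pairs[e_iri] = (Stage.STEM, None)

    # primary lines: no cross-reference at all ------------------------------
    for _ in range(spec.n_primary):
        name = _fresh_name(rng, taken_names)
        e_iri = next_efo_iri()
        emit_efo_record(e_iri, name, [], maybe(rng.choice(diseases)),
                        maybe(rng.choice(cell_types)), None, taxa[0])
        truth.pairs[e_iri] = (Stage.PRIMARY, None)

    # foreign-namespace imports ---------------------------------------------
    for k in range(spec.n_foreign):
        name = _fresh_name(rng, taken_names)
        iri = f"{FOREIGN_NS}{k + 1:07d}"
        efo.cls(iri, name, efo_pat.root_class)
        truth.pairs[iri] = (Stage.FOREIGN, None)

    # decoys on the cell-line-cell side --------------------------------------
    for _ in range(spec.decoy_count):
        name = _fresh_name(rng, taken_names)
        c_iri = next_clo_iri()
        emit_clo_record(
            c_iri, name, [],
            maybe(rng.choice(diseases)), maybe(rng.choice(cell_types)),
            maybe(rng.choice(anatomies)), maybe(rng.choice(taxa)),
        )

    header = "synthetic Cellosaurus-dialect corpus\n" + "-" * 40 + "\n"
    return efo.graph, clo.graph, header + "\n".join(cvs_blocks) + ("\n" if cvs_blocks else ""), truth


def write_corpus(spec: CorpusSpec, outdir: str,
                 config: Optional[PipelineConfig] = None) -> GroundTruth:
    """Serialize a corpus to ``efo.owl``, ``clo.owl``, ``cellosaurus.txt``,
    ``truth.tsv`` under *outdir*."""
    import os

    import pandas as pd

    efo_g, clo_g, cvs_text, truth = generate_corpus(spec, config)
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "efo.owl"), "wb") as fh:
        fh.write(efo_g.serialize(format="pretty-xml", encoding="utf-8"))
    with open(os.path.join(outdir, "clo.owl"), "wb") as fh:
        fh.write(clo_g.serialize(format="pretty-xml", encoding="utf-8"))
    with open(os.path.join(outdir, "cellosaurus.txt"), "w") as fh:
        fh.write(cvs_text)
    pd.DataFrame(truth.to_manifest_rows()).to_csv(
        os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    return truth


# ---------------------------------------------------------------------------
# evaluation against the manifest
# ---------------------------------------------------------------------------

def score_recovery(
    decisions: list[MappingDecision],
    truth: GroundTruth,
    efo_records: Optional[list[CellLineRecord]] = None,
    clo_records: Optional[list[CellLineRecord]] = None,
) -> dict:
    """Per-stage precision/recall plus the annotation-only comparison arm.

    The annotation-only arm maps a pair iff the two records' normalized name
    sets intersect — the lexical baseline the full pipeline (biological
    evidence plus semantic recovery) is compared against. Requires a
    decision for every manifest key.
    """
    by_iri = decisions_by_iri(decisions)
    missing = set(truth.pairs) - set(by_iri)
    if missing:
        raise ValueError(f"decisions missing for {len(missing)} manifest keys")

    stages = [s for s in Stage]
    summary: dict = {"stages": {}}
    for stage in stages:
        expected = {i for i, (s, _) in truth.pairs.items() if s is stage}
        decided = {i for i in truth.pairs if by_iri[i].stage is stage}
        tp = len(expected & decided)
        summary["stages"][stage.value] = {
            "expected": len(expected),
            "decided": len(decided),
            "true_positive": tp,
            "precision": tp / len(decided) if decided else 1.0,
            "recall": tp / len(expected) if expected else 1.0,
        }

    expected_pairs = {i: clo for i, (s, clo) in truth.pairs.items()
                      if s in (Stage.XREF3WAY, Stage.DIRECT)}
    n_pairs = len(expected_pairs)
    full_ok = sum(
        1 for i, clo in expected_pairs.items()
        if by_iri[i].clo_iri == clo
        and by_iri[i].category in (Category.EXACT_VALID, Category.INEXACT_TOP3)
    )
    summary["full_pipeline_mapped_fraction"] = full_ok / n_pairs if n_pairs else 1.0

    if efo_records is not None and clo_records is not None and n_pairs:
        efo_by = {r.iri: r for r in efo_records}
        clo_by = {r.iri: r for r in clo_records}
        lex_ok = sum(
            1 for i, clo_iri in expected_pairs.items()
            if i in efo_by and clo_iri in clo_by
            and normalized_names(efo_by[i].names())
            & normalized_names(clo_by[clo_iri].names())
        )
        summary["annotation_only_mapped_fraction"] = lex_ok / n_pairs
    return summary
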