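# Methods

## The alignment model

`cloalign` treats cell-line alignment as a three-evidence problem: lexical
identity (labels and synonyms), catalog identity (Cellosaurus accessions),
and biological identity (disease, cell type, anatomical location, species
of origin, encoded as existential restrictions in each ontology's design
pattern). No single channel is trusted alone — near-identical labels can
denote different lines, catalogs can be cross-referenced ambiguously, and
biological annotations are sparse — so the pipeline stages them from the
most to the least reliable signal:

1. unique-accession triangulation through Cellosaurus, with name and
   evidence validation;
2. direct confidence scoring, C = ΣM − SLD, over all candidates;
3. category-based classification of whatever remains.

Every class receives exactly one decision, and decisions that required
judgment in the original curation workflow (annotation conflicts, inexact
matches) are never dropped — they are flagged `needs_manual` so the human
step is preserved as metadata rather than silently automated away.

### Element matching

An element match M is +1 when both sides record equal terms, −1 when both
record conflicting terms, and 0 when either side lacks the element:
one-sided absence cannot evidence a mismatch. Disease terms additionally
match when they stand in a *direct* asserted subclass–superclass relation
(one hop, never the transitive closure — the term graph stores asserted
edges only, so recovery cannot chain). Species comparison resolves taxon
IRIs to NCBI TaxIDs (NCBITaxon IRIs parse directly; other schemes go
through the configurable `taxon_iri_map`). Cell-type hierarchy recovery
(e.g. fibroblast under connective-tissue cell, the SW684 situation) is
implemented but off by default (`cell_type_recovery`), since disease is
the only element for which triangulated recovery is validated by the
three-way step.

### Lexical comparison

Normalization is deliberately conservative: Unicode compatibility
folding, case folding, typographic-dash unification, whitespace
collapsing. Punctuation is never removed, because removing it conflates
genuinely distinct lines (17/14 vs 171-4). SLD is the minimum Levenshtein
distance (unit costs, computed with edlib) over the cross product of the
two normalized name sets; it is zero exactly when the sets intersect, and
is forced to zero when the records share a normalized cross-reference.
Normalization runs *before* distance computation, so case differences are
free and "NIH3T3" vs "NIH-3T3" costs exactly the inserted hyphen.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `top_k` | 3 | candidates retained per line in direct mapping |
| `inexact_threshold` | 0 | minimum C-score for accepting an inexact match; replaces the manual selection step, with `needs_manual` preserving review semantics. 0 demands net-positive evidence |
| `semantic_recovery` | on | one-hop disease subclass recovery |
| `cell_type_recovery` | off | one-hop cell-type recovery |
| `population_companion` | on | emit a population-level companion class linked by `has grain` for each ADDed cell-line-cell class |

All root-class, property and annotation IRIs are configuration
(`PipelineConfig`, YAML-loadable). The canonical RO properties carry their
real OBO ids (`RO_0000053` bearer of, `RO_0001000` derives from,
`RO_0002162` in taxon); the anatomy link and `has grain` have no single
canonical IRI in the wild, so the defaults (`RO_0001025` located in,
`obo/clo#has_grain`) are explicit config meant to be overridden to match
the deployed ontologies.

## Synchronization semantics

Merging is additive and conflict-averse: evidence the target class lacks
is carried over; a single-valued element already present on the target is
never overwritten (a conflict there has already been surfaced as
`EXACT_NEEDS_REVIEW`). The source label and its " cell" conversion become
exact synonyms, source xrefs plus a curie for the source IRI are recorded
on the target, and the source class is deprecated to a tombstone (label,
`owl:deprecated`, `IAO_0100001` replaced-by). Keeping the source-IRI
curie on the target is what makes the whole operation idempotent: a
re-run recognizes already-synchronized pairs and already-added classes
and plans only KEEPs. Added classes are placed as direct children of the
cell-line-cell root — the flat catalog provides no hierarchy to inherit —
and fresh IRIs are minted consecutively after the highest existing
7-digit suffix. Deprecated classes are kept as tombstones rather than
retaining their old axioms; retaining axioms on obsolete terms invites
reasoning over retracted content.

## The synthetic corpus generator

Real EFO/CLO/Cellosaurus releases are too large and too mutable to pin
tests to, so `fixtures.generate_corpus` builds corpora with the same
*structure*: true pairs sharing a unique accession with seeded label
corruption on the cell-line-cell side (the corrupted variant is also
listed as a Cellosaurus synonym, as the curated catalog does in
practice); recovery-only pairs whose diseases form the
specific-under-two-generals motif and whose labels are forced lexically
inexact; pairs with non-unique cross-references that only direct mapping
can resolve; unique immortalized, stem-category, xref-less primary and
foreign-namespace lines; and decoys kept at Levenshtein distance ≥ 6 from
every true base name so that a wrong pairing can never reach a
non-negative C-score (ΣM ≤ 4 < 6 − corruption).

Default composition scales the five-way outcome proportions of a
realistic curation round to desk scale: 88 plain + 19 recovery + 6
non-unique pairs, 49 unique immortalized, 64 foreign, 9 stem, 5 primary,
30 decoys, corruption distance 1, element-missing rate 0.1. The large
structural check in the test suite uses a 1,000-class corpus; problem
sizes were chosen so the whole suite exercises every path at full depth
while staying fast enough to run on every commit.

What the generator does **not** emulate: real label distributions (names
are random, uniformly separated), synonym breadth, multi-disease records,
catalog curation errors, and scale (real EFO/CLO have tens of thousands
of classes). Passing tests therefore demonstrate correctness of the
mechanics — partitioning, scoring, recovery, bookkeeping, round-tripping —
not the empirical mapped fraction one would obtain on production
releases, which depends on the releases themselves.

## Numerical and procedural choices

- Candidate ordering is fully deterministic: C-score descending, SLD
  ascending, IRI lexicographic. The IRI tie-break is arbitrary but fixed.
- Blank nodes in emitted RDF/XML are named from a counter, and triples
  are inserted in sorted order, so serialization is byte-stable.
- Accession uniqueness follows the strict reading: unique means exactly
  one record carries the accession *and* that record carries exactly one
  accession; anything else defers to direct mapping.
- Cellosaurus disease annotations are resolved to ontology terms by
  normalized-label lookup in the term graph (overridable per terminology
  id via `disease_xref_map`).
- Three-way name agreement means exact normalized-name intersection with
  the Cellosaurus entry's names; cross-references are excluded from this
  particular check because the triangulating accession would satisfy it
  vacuously. Failures are flagged for review, not discarded.
- A record with multiple accessions whose categories disagree (stem vs
  not) classifies as stem: a possible stem line is never auto-added.
- Degenerate inputs: empty name sets are a hard error for SLD; an empty
  candidate list is a hard error for ranking; a cycle among asserted
  subclass axioms is a hard error naming the cycle; a duplicate accession
  in one flat file is a hard error; a block missing ID/AC or an
  unresolvable accession degrades gracefully with a logged warning.

## Known limitations

- Alignment is one-to-one; many-to-many cell-line relationships (sublines,
  clones) are out of scope.
- Only asserted subclass edges feed recovery; classes whose relationship
  exists only under OWL reasoning will not recover.
- The inexact-acceptance threshold is a blunt stand-in for human
  inspection of the top-3 list; `needs_manual` rows should still be
  reviewed.
- The Cellosaurus dialect parser covers the line codes the method uses
  (ID, AC, SY, DR, DI, OX, CA); other codes are preserved-ignored.
- Stem detection is a substring test on the category field.
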