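# cloalign

Aligning cell-line terms across biomedical ontologies is harder than it
looks: the Experimental Factor Ontology (EFO) models a cell line as a
population of cells, the Cell Line Ontology (CLO) models the individual
"cell line cell", the two communities name the same line differently
("NIH3T3" vs "NIH-3T3"), and near-identical labels can denote different
lines entirely (cell line 17/14 is not cell line 171-4). `cloalign`
implements a complete, deterministic pipeline for comparing, mapping and
synchronizing cell-line classes between an EFO-style ontology and a
CLO-style ontology, using the Cellosaurus knowledgebase as a third-party
cross-reference authority. It is intended for ontology engineers and
biocurators maintaining cell-line vocabularies, and for anyone who needs a
reproducible, auditable account of how two cell-line term sets were merged.

## Method

The workflow runs in four steps:

1. **Extraction.** Cell-line classes and their annotations (label,
   synonyms, database cross-references) are pulled from each ontology,
   together with four elements of biological evidence encoded as
   existential restrictions in each design pattern: disease (`bearer of`
   in the population pattern, `is model for` in the cell-line-cell
   pattern), cell type (`derives from`), anatomical location, and species
   of origin. EFO classes drawn from foreign namespaces (CLO, BTO, ...)
   are set aside as imports.

2. **Three-way triangulation.** Cell lines carrying a *unique* Cellosaurus
   accession on both sides are aligned through the Cellosaurus entry.
   Names and the shared evidence elements (disease, species) are
   validated; a disease conflict is *semantically recovered* when the two
   recorded terms each stand in a direct subclass–superclass relation to
   the Cellosaurus-assigned term — e.g. NCI-H2087 is annotated with
   "lung carcinoma" (EFO), "lung adenocarcinoma" (Cellosaurus) and
   "adenocarcinoma" (CLO), which only cohere through the hierarchy.

3. **Direct confidence-scored mapping.** Remaining lines are scored
   against every candidate with

   $$C = \sum_{i=1}^{K} M_i - SLD$$

   where $M_i \in \{+1, -1, 0\}$ marks each evidence element as matched,
   unmatched or missing over $K$ = {disease, cell type, anatomical
   location, species}, and $SLD$ is the shortest Levenshtein distance over
   all pairs of normalized labels and synonyms (forced to 0 on an exact
   name or cross-reference match). For NIH3T3 vs NIH-3T3 with matched
   disease, anatomy and species and no cell-type evidence: $SLD = 1$,
   $\sum M = +3$, $C = +2$. Only the top three candidates per line are
   retained, and each mapped line is categorized as exact-and-valid,
   exact-needing-review, or inexact (flagged for manual selection).

4. **Classification and synchronization.** Unmapped lines with a traceable
   non-stem Cellosaurus record are treated as immortalized permanent cell
   lines and added to CLO under fresh consecutive IRIs and the " cell"
   naming convention; stem and primary lines stay in EFO. Mapped EFO
   classes are merged into their CLO partners (evidence CLO lacks is
   carried over, EFO names become exact synonyms) and deprecated with a
   replaced-by pointer. The emitted RDF/XML is byte-stable and re-running
   the pipeline on its own output plans zero further changes.

## Worked example

Generate a small synthetic corpus (8 plain pairs, 3 pairs mappable only
through disease-hierarchy recovery, plus unique/stem/primary/foreign lines
and decoys) and run the full workflow:

```bash
cloalign generate --out corpus --seed 17 --true-pairs 8 --recovery-pairs 3
cloalign run --efo corpus/efo.owl --clo corpus/clo.owl \
             --cellosaurus corpus/cellosaurus.txt --out out
```

which logs each stage and prints the five-way outcome summary:

```
INFO cloalign.pipeline: parsed 81 Cellosaurus entries
INFO cloalign.pipeline: extracted 80 native + 64 foreign population-pattern records, 47 cell-line-cell records
INFO cloalign.pipeline: three-way mapping: 11 decided, 69 deferred
INFO cloalign.pipeline: direct mapping: 6 mapped, 63 residual
            outcome  n
             mapped 17
unique_immortalized 49
           imported 64
               stem  9
            primary  5
```

Here 17 lines found a CLO partner (8 + 3 planted pairs through
triangulation, 6 via direct scoring), 49 traceable-but-unpartnered lines
are queued for addition to CLO, 64 foreign-namespace imports and the
stem/primary lines stay in EFO. `out/` contains `decisions.tsv` (one row
per input class with stage, category, C-score, SLD and review flags),
`candidates.tsv` (top-3 ranked candidates for directly mapped lines),
`changes.tsv` (the MERGE/ADD/DEPRECATE/KEEP plan) and `clo_updated.owl`
(the synchronized ontology). `--no-semantic-recovery` demotes exactly the
3 recovery pairs from valid to needs-review; `cloalign report` re-prints
the summary from a saved decision table.

## Layout

- `src/cloalign/lexical.py` — name/xref normalization, SLD
- `src/cloalign/sources_io.py` — Cellosaurus dialect + OWL extraction
- `src/cloalign/threeway.py` — unique-xref triangulation with recovery
- `src/cloalign/matching.py` — C-score, ranking, outcome categories
- `src/cloalign/classification.py` — immortalized / stem / primary split
- `src/cloalign/synchronization.py` — merge, add, deprecate, emit
- `src/cloalign/fixtures.py` — synthetic corpus generator + evaluation
- `src/cloalign/pipeline.py`, `src/cloalign/cli.py` — orchestration, CLI

See `docs/methods.md` for modeling assumptions, parameter defaults and
known limitations.
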