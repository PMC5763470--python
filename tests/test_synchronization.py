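"""Naming convention, pattern transformation, IRI minting, planning, emission."""

import pytest
from rdflib import Graph

from cloalign.config import PipelineConfig
from cloalign.model import Category, MappingDecision, Pattern, Source, Stage
from cloalign.sources_io import extract_cell_line_records
from cloalign.synchronization import (
    ActionKind,
    assign_new_clo_iri,
    emit_updated_clo,
    plan_synchronization,
    to_clo_name,
    transform_to_clo_pattern,
)
from conftest import EFO_NS, OBO, add_class, add_restriction, make_record


class TestToCloName:
    @pytest.mark.parametrize("label, expected", [
        ("MCF 10A", "MCF 10A cell"),
        ("HEK-293 cell", "HEK-293 cell"),   # idempotent
        ("NIH3T3", "NIH3T3 cell"),
    ])
    def test_convention(self, label, expected):
        assert to_clo_name(label) == expected

    def test_empty_label_hard_error(self):
        with pytest.raises(ValueError):
            to_clo_name("")


class TestTransformPattern:
    def test_disease_moves_to_is_model_for(self, config):
        rec = make_record(f"{EFO_NS}EFO_1", "x", diseases={"http://x/D"})
        assert transform_to_clo_pattern(rec, config) == [
            (config.clo_pattern.disease_property, "http://x/D")]

    def test_all_elements_carry_through(self, config):
        rec = make_record(f"{EFO_NS}EFO_1", "x", diseases={"http://x/D"},
                          cell_type="http://x/C", anatomical_location="http://x/A",
                          species="http://x/S")
        pairs = transform_to_clo_pattern(rec, config)
        assert len(pairs) == 4
        assert (config.clo_pattern.anatomy_property, "http://x/A") in pairs

    def test_no_evidence_empty_axioms(self, config):
        assert transform_to_clo_pattern(make_record(f"{EFO_NS}EFO_1", "x"),
                                        config) == []


class TestAssignIris:
    def test_consecutive_after_max(self):
        got = assign_new_clo_iri([f"{OBO}CLO_0007599", f"{OBO}CLO_0000100"], 2)
        assert got == [f"{OBO}CLO_0007600", f"{OBO}CLO_0007601"]

    def test_empty_existing_starts_at_one(self):
        assert assign_new_clo_iri([], 1, f"{OBO}CLO_") == [f"{OBO}CLO_0000001"]

    def test_zero_count(self):
        assert assign_new_clo_iri([f"{OBO}CLO_0007599"], 0) == []

    def test_malformed_existing_hard_error(self):
        with pytest.raises(ValueError, match="malformed"):
            assign_new_clo_iri(["http://x/not-numeric"], 1)


def _mapped_world(config):
    efo = make_record(f"{EFO_NS}EFO_0001200", "MCF 10A",
                      diseases=set(), anatomical_location="http://x/mammary",
                      xrefs={"CELLOSAURUS:CVCL_0598"})
    clo = make_record(f"{OBO}CLO_0007599", "MCF 10A cell", source=Source.CLO,
                      synonyms={"MCF 10A"}, xrefs={"CELLOSAURUS:CVCL_0598"},
                      cell_type="http://x/epithelial")
    dec = MappingDecision(efo_iri=efo.iri, stage=Stage.XREF3WAY,
                          category=Category.EXACT_VALID, clo_iri=clo.iri)
    return efo, clo, dec


class TestPlan:
    def test_mapped_pair_yields_merge_plus_deprecate(self, config):
        efo, clo, dec = _mapped_world(config)
        actions = plan_synchronization([dec], [efo], [clo], config)
        kinds = [a.kind for a in actions]
        assert kinds.count(ActionKind.MERGE) == 1
        assert kinds.count(ActionKind.DEPRECATE) == 1
        merge = next(a for a in actions if a.kind is ActionKind.MERGE)
        # the anatomy the target lacks is drawn from the source record
        assert (config.clo_pattern.anatomy_property, "http://x/mammary") \
            in merge.merged_axioms
        # target's own cell type is never overwritten
        assert not any(p == config.clo_pattern.cell_type_property
                       for p, _ in merge.merged_axioms)

    def test_unique_immortalized_yields_add_with_cell_suffix(self, config):
        rec = make_record(f"{EFO_NS}EFO_2", "KTC-1",
                          xrefs={"CELLOSAURUS:CVCL_0101"}, diseases={"http://x/D"})
        dec = MappingDecision(efo_iri=rec.iri, stage=Stage.UNIQUE_IMMORTALIZED)
        clo = make_record(f"{OBO}CLO_0007599", "other cell", source=Source.CLO)
        (action,) = plan_synchronization([dec], [rec], [clo], config)
        assert action.kind is ActionKind.ADD
        assert action.new_label == "KTC-1 cell"
        assert action.target_iri == f"{OBO}CLO_0007600"

    def test_stem_and_foreign_kept(self, config):
        stem = make_record(f"{EFO_NS}EFO_3", "H9")
        foreign = make_record(f"{OBO}BTO_0000001", "bto line")
        decs = [MappingDecision(efo_iri=stem.iri, stage=Stage.STEM),
                MappingDecision(efo_iri=foreign.iri, stage=Stage.FOREIGN)]
        actions = plan_synchronization(decs, [stem, foreign], [], config)
        assert all(a.kind is ActionKind.KEEP for a in actions)

    def test_unknown_iri_hard_error(self, config):
        dec = MappingDecision(efo_iri="http://x/ghost", stage=Stage.STEM)
        with pytest.raises(ValueError, match="unknown"):
            plan_synchronization([dec], [], [], config)

    def test_conservation_counts(self, config):
        efo, clo, dec = _mapped_world(config)
        add = make_record(f"{EFO_NS}EFO_2", "KTC-1", xrefs={"CELLOSAURUS:CVCL_0101"})
        stem = make_record(f"{EFO_NS}EFO_3", "H9")
        decs = [dec,
                MappingDecision(efo_iri=add.iri, stage=Stage.UNIQUE_IMMORTALIZED),
                MappingDecision(efo_iri=stem.iri, stage=Stage.STEM)]
        actions = plan_synchronization(decs, [efo, add, stem], [clo], config)
        n = {k: sum(1 for a in actions if a.kind is k) for k in ActionKind}
        assert n[ActionKind.MERGE] + n[ActionKind.ADD] + n[ActionKind.KEEP] == 3
        assert n[ActionKind.MERGE] == n[ActionKind.DEPRECATE]


def _clo_base_graph(config):
    """Graph form of _mapped_world's cell-line-cell record."""
    from rdflib import Literal, URIRef

    g = Graph()
    add_class(g, config.clo_pattern.root_class, "cell line cell")
    iri = f"{OBO}CLO_0007599"
    add_class(g, iri, "MCF 10A cell", config.clo_pattern.root_class)
    g.add((URIRef(iri), URIRef(config.annotations.synonyms[0]),
           Literal("MCF 10A")))
    g.add((URIRef(iri), URIRef(config.annotations.db_xref),
           Literal("Cellosaurus:CVCL_0598")))
    add_restriction(g, iri, config.clo_pattern.cell_type_property,
                    "http://x/epithelial", "base1")
    return g


class TestEmit:
    def test_merge_adds_exactly_the_restriction(self, config):
        efo, clo, dec = _mapped_world(config)
        g = _clo_base_graph(config)
        actions = plan_synchronization([dec], [efo], [clo], config)
        data, report = emit_updated_clo(actions, g, config)
        out = Graph()
        out.parse(data=data, format="xml")
        (rec,) = [r for r in extract_cell_line_records(out, Pattern.CLO_STYLE, config)
                  if r.iri == clo.iri]
        assert rec.anatomical_location == "http://x/mammary"
        assert "EFO:0001200" in rec.xrefs

    def test_deprecation_tombstone_serialized(self, config):
        from rdflib import URIRef, Literal, XSD

        efo, clo, dec = _mapped_world(config)
        actions = plan_synchronization([dec], [efo], [clo], config)
        data, _ = emit_updated_clo(actions, _clo_base_graph(config), config)
        out = Graph()
        out.parse(data=data, format="xml")
        cls = URIRef(efo.iri)
        assert (cls, URIRef(config.annotations.deprecated),
                Literal(True, datatype=XSD.boolean)) in out
        assert (cls, URIRef(config.annotations.replaced_by),
                URIRef(clo.iri)) in out

    def test_add_grows_class_count_and_companion(self, config):
        recs = [make_record(f"{EFO_NS}EFO_{i}", f"line{i}",
                            xrefs={f"CELLOSAURUS:CVCL_010{i}"}) for i in range(3)]
        decs = [MappingDecision(efo_iri=r.iri, stage=Stage.UNIQUE_IMMORTALIZED)
                for r in recs]
        g = _clo_base_graph(config)
        before = len(extract_cell_line_records(g, Pattern.CLO_STYLE, config))
        actions = plan_synchronization(decs, recs, [
            make_record(f"{OBO}CLO_0007599", "MCF 10A cell", source=Source.CLO)],
            config)
        data, _ = emit_updated_clo(actions, g, config)
        out = Graph()
        out.parse(data=data, format="xml")
        after = extract_cell_line_records(out, Pattern.CLO_STYLE, config)
        assert len(after) == before + 3
        # has-grain companion classes sit under the population root
        from rdflib import URIRef, RDFS
        companions = list(out.subjects(RDFS.subClassOf,
                                       URIRef(config.population_root)))
        assert len(companions) == 3

    def test_no_companion_when_disabled(self):
        config = PipelineConfig(population_companion=False)
        rec = make_record(f"{EFO_NS}EFO_1", "solo",
                          xrefs={"CELLOSAURUS:CVCL_0101"})
        dec = MappingDecision(efo_iri=rec.iri, stage=Stage.UNIQUE_IMMORTALIZED)
        actions = plan_synchronization([dec], [rec], [
            make_record(f"{OBO}CLO_0007599", "MCF 10A cell", source=Source.CLO)],
            config)
        data, _ = emit_updated_clo(actions, _clo_base_graph(config), config)
        out = Graph()
        out.parse(data=data, format="xml")
        from rdflib import URIRef, RDFS
        assert not list(out.subjects(RDFS.subClassOf,
                                     URIRef(config.population_root)))

    def test_byte_stable_across_calls(self, config):
        efo, clo, dec = _mapped_world(config)
        actions = plan_synchronization([dec], [efo], [clo], config)
        d1, _ = emit_updated_clo(actions, _clo_base_graph(config), config)
        d2, _ = emit_updated_clo(actions, _clo_base_graph(config), config)
        assert d1 == d2

    def test_replan_after_merge_is_all_keep(self, config):
        """Re-running synchronization on its own output plans no new actions."""
        efo, clo, dec = _mapped_world(config)
        actions = plan_synchronization([dec], [efo], [clo], config)
        data, _ = emit_updated_clo(actions, _clo_base_graph(config), config)
        out = Graph()
        out.parse(data=data, format="xml")
        clo2 = extract_cell_line_records(out, Pattern.CLO_STYLE, config)
        again = plan_synchronization([dec], [efo], clo2, config)
        assert all(a.kind is ActionKind.KEEP for a in again)

    def test_change_report_row_per_action(self, config):
        efo, clo, dec = _mapped_world(config)
        actions = plan_synchronization([dec], [efo], [clo], config)
        _, report = emit_updated_clo(actions, _clo_base_graph(config), config)
        assert len(report) == len(actions)
        assert set(report["action"]) == {"MERGE", "DEPRECATE"}
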