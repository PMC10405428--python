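"""Fragment classification: original vs revised semantics, oracle equivalence."""

import pytest

import cardphen as cp
from cardphen.classify import (
    classify_original,
    classify_original_ontology,
    classify_revised,
    entails,
    naive_saturation_oracle,
)
from cardphen.eq import DECREASED_AMOUNT, INCREASED_AMOUNT
from cardphen.ontology import ClassTerm, EQDefinition, Ontology, OntologyError
from cardphen.rewrite import cq_id, cxp_id, rewrite_ontology

from conftest import make_random_phenotype_fixture, nonreflexive

DEC_T, DEC_NK = "MP:0005018", "MP:0008040"
ABS_T, ABS_NK = "MP:0008070", "MP:0008041"


@pytest.fixture()
def original_graph(demo):
    return classify_original_ontology(demo)


@pytest.fixture()
def revised_graph(demo, config):
    return classify_revised(rewrite_ontology(demo, config))


class TestOriginalMode:
    def test_decreased_subtype_under_decreased_supertype(self, original_graph):
        assert entails(original_graph, DEC_NK, DEC_T)

    def test_absent_subtype_under_absent_supertype(self, original_graph):
        assert entails(original_graph, ABS_NK, ABS_T)

    def test_identical_quality_unrelated_entities_incomparable(self):
        onto = Ontology()
        for cid in ("CL:0000001", "CL:0000002"):
            onto.add_class(ClassTerm(cid, cid, "entity"))
        onto.add_class(ClassTerm("PATO:0001997", "decreased amount", "quality"))
        for i, ent in enumerate(("CL:0000001", "CL:0000002"), start=1):
            pid = f"MP:000000{i}"
            onto.add_class(ClassTerm(pid, pid, "phenotype"))
            onto.set_eq_definition(EQDefinition(pid, "PATO:0001997", ent))
        g = classify_original_ontology(onto)
        assert not entails(g, "MP:0000001", "MP:0000002")
        assert not entails(g, "MP:0000002", "MP:0000001")

    def test_subclass_strength_definition_gains_no_subclasses(self, demo):
        from dataclasses import replace

        demo.eq_definitions[DEC_T] = replace(
            demo.eq_definitions[DEC_T], strength="subclass"
        )
        g = classify_original_ontology(demo)
        assert not entails(g, DEC_NK, DEC_T)  # T-side is now primitive
        # but the primitive class still gains superclasses: none here to gain

    def test_eqdef_outside_closures_is_an_error(self, demo):
        bad = EQDefinition("MP:0009999", DECREASED_AMOUNT, "CL:7777777")
        with pytest.raises(OntologyError):
            classify_original(
                [bad],
                demo.entity_graph().closure(),
                demo.quality_graph().closure(),
            )


class TestRevisedMode:
    def test_absence_inverts(self, revised_graph):
        assert entails(revised_graph, ABS_T, ABS_NK)
        assert not entails(revised_graph, ABS_NK, ABS_T)

    def test_amount_phenotypes_of_distinct_entities_incomparable(self, revised_graph):
        assert not entails(revised_graph, DEC_NK, DEC_T)
        assert not entails(revised_graph, DEC_T, DEC_NK)

    def test_grouping_placements(self, revised_graph):
        assert entails(revised_graph, DEC_T, cxp_id("CL:0000084"))
        assert entails(revised_graph, ABS_T, cxp_id("CL:0000084"))
        assert entails(revised_graph, DEC_T, cq_id(DECREASED_AMOUNT))
        assert not entails(revised_graph, ABS_T, cq_id(DECREASED_AMOUNT))

    def test_reflexivity(self, revised_graph):
        assert entails(revised_graph, DEC_T, DEC_T)

    def test_unknown_id_is_an_error(self, revised_graph):
        with pytest.raises(OntologyError):
            entails(revised_graph, DEC_T, "MP:7777777")

    def test_every_removed_amount_edge_was_present_in_original(self, config):
        """The problematic inference exists before the rewrite and is removed by it."""
        pheno, cfg = make_random_phenotype_fixture(seed=123)
        g_orig = classify_original_ontology(pheno)
        rw = rewrite_ontology(pheno, cfg)
        g_rev = classify_revised(rw)
        orig_edges = nonreflexive(g_orig)
        rev_edges = nonreflexive(g_rev)
        amount_ids = {
            r.source_phenotype_id for r in rw.rewrites.values() if r.kind == "amount"
        }
        removed = {
            (a, b) for a, b in orig_edges - rev_edges
            if a in amount_ids and b in amount_ids
        }
        entity_closure = pheno.entity_graph().closure()
        for a, b in removed:
            ra, rb = rw.rewrites[a], rw.rewrites[b]
            assert entity_closure.entails(ra.entity_id, rb.entity_id)
            assert ra.entity_id != rb.entity_id


class TestAbsenceDuality:
    @pytest.mark.parametrize("seed", [0, 7, 21])
    def test_absence_order_is_dual_of_entity_order(self, seed):
        # no extra asserted is-a edges: duality concerns the rewrite's own
        # entailments, which must mirror the entity order exactly
        pheno, cfg = make_random_phenotype_fixture(seed, asserted_edges=False)
        rw = rewrite_ontology(pheno, cfg)
        g = classify_revised(rw)
        absences = {
            r.entity_id: r.source_phenotype_id
            for r in rw.rewrites.values() if r.kind == "absence"
        }
        if not absences:
            pytest.skip("fixture drew no absence quality")
        closed = nonreflexive(g)
        entity_closure = pheno.entity_graph().closure()
        absence_edges = {
            (a, b) for a, b in closed
            if a in absences.values() and b in absences.values()
        }
        dual = {
            (absences[y], absences[x])
            for x, y in entity_closure.edges
            if x != y and x in absences and y in absences
        }
        assert absence_edges == dual


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(6))
    def test_original_mode(self, seed):
        pheno, _ = make_random_phenotype_fixture(seed)
        opt = nonreflexive(classify_original_ontology(pheno))
        assert opt == naive_saturation_oracle(pheno, "original")

    @pytest.mark.parametrize("seed", range(6))
    def test_revised_mode(self, seed):
        pheno, cfg = make_random_phenotype_fixture(seed)
        rw = rewrite_ontology(pheno, cfg)
        opt = nonreflexive(classify_revised(rw))
        assert opt == naive_saturation_oracle(rw, "revised")

    def test_empty_input(self):
        assert naive_saturation_oracle(Ontology(), "original") == set()
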