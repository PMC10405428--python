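"""Collection classes, partonomy materialization, phenotype rewrites, groupings."""

import pytest

import cardphen as cp
from cardphen.eq import ABSENT, DECREASED_AMOUNT, QUALITY_ROOT
from cardphen.expressions import (
    And,
    Atom,
    Bottom,
    EquivalentClasses,
    Not,
    OneOf,
    Only,
    Some,
    SubClassOf,
    HAS_MEMBER,
    MEMBER_OF,
    PART_OF,
)
from cardphen.ontology import EQDefinition, OntologyError
from cardphen.rewrite import (
    ROOT_COLLECTION_ID,
    RewrittenOntology,
    make_collection_class,
    make_grouping_classes,
    materialize_partonomy,
    rewrite_ontology,
    rewrite_phenotype,
)

from conftest import make_random_dag


def _rw(onto, config=None):
    return RewrittenOntology(ontology=onto.copy(), config=config or cp.CardinalityConfig())


class TestMakeCollectionClass:
    def test_emits_the_three_axioms_plus_root(self, demo, config):
        rw = _rw(demo, config)
        coll = make_collection_class(rw, "CL:0000084")
        axioms = set(rw.ontology.axioms)
        assert SubClassOf(Atom(coll.id), Only(HAS_MEMBER, Atom("CL:0000084"))) in axioms
        assert SubClassOf(Atom("CL:0000084"), Some(MEMBER_OF, Atom(coll.id))) in axioms
        assert EquivalentClasses(Atom(coll.id), OneOf((coll.nominal_individual_id,))) in axioms
        assert rw.ontology.graph.entails(coll.id, ROOT_COLLECTION_ID)

    def test_idempotent(self, demo, config):
        rw = _rw(demo, config)
        a = make_collection_class(rw, "CL:0000084")
        n_axioms = len(rw.ontology.axioms)
        b = make_collection_class(rw, "CL:0000084")
        assert a == b and len(rw.ontology.axioms) == n_axioms

    def test_distinct_entities_get_distinct_nominals(self, demo, config):
        rw = _rw(demo, config)
        a = make_collection_class(rw, "CL:0000084")
        b = make_collection_class(rw, "CL:0000814")
        assert a.id != b.id
        assert a.nominal_individual_id != b.nominal_individual_id


class TestPartonomy:
    def test_chain_yields_three_part_of_axioms(self, entity_chain, config):
        rw = _rw(entity_chain, config)
        for ent in ["CL:0000542", "CL:0000084", "CL:0000814"]:
            make_collection_class(rw, ent)
        axioms = materialize_partonomy(rw)
        coll = {ent: c.id for ent, c in rw.collections.items()}
        got = {(a.sub.id, a.sup.filler.id) for a in axioms}
        assert got == {
            (coll["CL:0000814"], coll["CL:0000084"]),
            (coll["CL:0000814"], coll["CL:0000542"]),
            (coll["CL:0000084"], coll["CL:0000542"]),
        }
        assert all(isinstance(a.sup, Some) and a.sup.prop == PART_OF for a in axioms)

    def test_single_entity_no_axioms(self, demo, config):
        rw = _rw(demo, config)
        make_collection_class(rw, "CL:0000814")
        # the ancestor T cell is pulled in, giving exactly one non-reflexive pair
        axioms = materialize_partonomy(rw)
        assert len(axioms) == 1 and "CL:0000084" in rw.collections

    def test_truly_isolated_entity_no_axioms(self, config):
        from cardphen.ontology import ClassTerm, Ontology

        onto = Ontology().add_class(ClassTerm("CL:0000084", "T cell", "entity"))
        rw = _rw(onto, config)
        make_collection_class(rw, "CL:0000084")
        assert materialize_partonomy(rw) == []

    @pytest.mark.parametrize("seed", range(3))
    def test_axiom_count_equals_nonreflexive_closure_pairs(self, seed, config):
        onto = make_random_dag(seed, n=15)
        rw = _rw(onto, config)
        for ent in sorted(onto.ids_in_namespace("entity")):
            make_collection_class(rw, ent)
        axioms = materialize_partonomy(rw)
        closure = onto.entity_graph().closure()
        expected = sum(1 for s, t in closure.edges if s != t)
        assert len(axioms) == expected


class TestRewritePhenotype:
    def test_amount_rewrite_points_at_collection(self, demo, config):
        rw = _rw(demo, config)
        coll = make_collection_class(rw, "CL:0000084")
        res = rewrite_phenotype(rw, demo.eq_definitions["MP:0005018"])
        assert res.kind == "amount" and res.collection_id == coll.id
        ax = res.primary_axiom
        assert isinstance(ax, EquivalentClasses)
        inner = ax.b.filler
        assert Atom(DECREASED_AMOUNT) in inner.operands
        assert any(
            isinstance(op, Some) and op.filler == Atom(coll.id) for op in inner.operands
        )
        # the original entity-based definition is replaced, not retained
        assert "MP:0005018" not in rw.ontology.eq_definitions

    def test_absence_rewrite_is_dual(self, demo, config):
        rw = _rw(demo, config)
        coll = make_collection_class(rw, "CL:0000084")
        res = rewrite_phenotype(rw, demo.eq_definitions["MP:0008070"])
        assert res.kind == "absence"
        empty = res.primary_axiom.b.filler
        assert Only(HAS_MEMBER, Bottom()) in _collect_only(empty)
        neg = res.negative_absence_axiom
        assert isinstance(neg.b, Not)
        # both forms define the same class id
        assert neg.a == res.primary_axiom.a == Atom("MP:0008070")
        # the negative form carries the member class, not the collection
        assert Atom("CL:0000084") in _atoms(neg.b)

    def test_missing_collection_is_an_error(self, demo, config):
        rw = _rw(demo, config)
        with pytest.raises(OntologyError, match="collection"):
            rewrite_phenotype(rw, demo.eq_definitions["MP:0005018"])


def _atoms(expr):
    out = []
    stack = [expr]
    while stack:
        e = stack.pop()
        if isinstance(e, Atom):
            out.append(e)
        for attr in ("filler", "operand"):
            if hasattr(e, attr):
                stack.append(getattr(e, attr))
        if hasattr(e, "operands"):
            stack.extend(e.operands)
    return out


def _collect_only(expr):
    out = []
    stack = [expr]
    while stack:
        e = stack.pop()
        if isinstance(e, Only):
            out.append(e)
        for attr in ("filler", "operand"):
            if hasattr(e, attr):
                stack.append(getattr(e, attr))
        if hasattr(e, "operands"):
            stack.extend(e.operands)
    return out


class TestGroupingClasses:
    def test_one_cxp_per_collection_one_cq_per_quality(self, entity_chain, config):
        from cardphen.eq import INCREASED_AMOUNT

        rw = _rw(entity_chain, config)
        for ent in ["CL:0000542", "CL:0000084", "CL:0000814"]:
            make_collection_class(rw, ent)
        made = make_grouping_classes(rw, [INCREASED_AMOUNT, DECREASED_AMOUNT])
        kinds = [g.kind for g in made]
        assert kinds.count("by_collection") == 3 and kinds.count("by_quality") == 2

    def test_no_collections_yields_only_cq(self, demo, config):
        rw = _rw(demo, config)
        made = make_grouping_classes(rw, [DECREASED_AMOUNT])
        assert [g.kind for g in made] == ["by_quality"]
        assert made[0].root_collection_id == ROOT_COLLECTION_ID


class TestRewriteOntology:
    def test_demo_counts(self, demo, config):
        rw = rewrite_ontology(demo, config)
        # 2 entities in a chain, 4 cardinality phenotypes, 1 amount quality used
        assert rw.summary() == {
            "collections": 2,
            "rewritten_phenotypes": 4,
            "grouping_classes": 3,  # 2 CXP + 1 CQ (decreased amount)
            "partonomy_axioms": 1,
        }

    def test_three_entity_three_quality_fixture_counts(self):
        spec = cp.FixtureSpec(depth=2, branching=1, seed=0)  # chain of 3 entities
        pheno = cp.generate_phenotype_ontology(cp.generate_entity_ontology(spec), spec)
        rw = rewrite_ontology(pheno, spec.config())
        assert rw.summary() == {
            "collections": 3,
            "rewritten_phenotypes": 9,
            "grouping_classes": 3 + 2,  # 3 CXP + 2 amount-quality CQ (absence has none)
            "partonomy_axioms": 3,
        }

    def test_no_cardinality_phenotypes_is_a_noop_plus_root(self, entity_chain, config):
        rw = rewrite_ontology(entity_chain, config)
        assert rw.summary()["rewritten_phenotypes"] == 0
        extra = set(rw.ontology.terms) - set(entity_chain.terms)
        assert extra == {ROOT_COLLECTION_ID}

    def test_rerun_on_own_output_is_a_fixpoint(self, demo, config):
        rw = rewrite_ontology(demo, config)
        again = rewrite_ontology(rw.ontology, config)
        assert again.summary()["rewritten_phenotypes"] == 0
        assert set(again.ontology.terms) == set(rw.ontology.terms)

    def test_generated_ids_do_not_collide_with_input(self, demo, config):
        rw = rewrite_ontology(demo, config)
        # rewrites redefine existing phenotype ids in place; every *new*
        # class id must avoid the input id space
        generated = {
            g for g, _, schema in rw.provenance if not schema.startswith("rewrite")
        }
        assert generated.isdisjoint(set(demo.terms))

    def test_provenance_covers_every_generated_class(self, demo, config):
        rw = rewrite_ontology(demo, config)
        new_classes = set(rw.ontology.terms) - set(demo.terms)
        assert new_classes <= {g for g, _, _ in rw.provenance}

    def test_input_ontology_untouched(self, demo, config):
        before = set(demo.terms)
        rewrite_ontology(demo, config)
        assert set(demo.terms) == before and len(demo.eq_definitions) == 4

    def test_deterministic(self, demo, config, tmp_path):
        from cardphen.io import write_owl_functional

        a, b = rewrite_ontology(demo, config), rewrite_ontology(demo, config)
        write_owl_functional(a.ontology, tmp_path / "a.ofn")
        write_owl_functional(b.ontology, tmp_path / "b.ofn")
        assert (tmp_path / "a.ofn").read_bytes() == (tmp_path / "b.ofn").read_bytes()
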