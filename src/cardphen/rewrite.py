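"""Rewriting cardinality phenotypes over maximal-collection classes.

For every entity class X referenced by a cardinality phenotype (plus the
ancestors pulled in by partonomy materialization) a collection class
``X-Collection`` is generated with three axioms:

* ``X-Collection [= has_member only X``   (members are Xs)
* ``X [= member_of some X-Collection``    (every X belongs to the collection)
* ``X-Collection = { x-collection }``     (a fresh nominal: there is exactly
  one such collection per body, approximating the maximal collection)

The subclass order of entities is materialized as a partonomy between their
collections (``X [= Y`` yields ``X-Collection [= part_of some Y-Collection``),
and every collection is a subclass of a single root collection class C.

Cardinality phenotypes are then redefined over the collection instead of the
member class: amount phenotypes keep their quality but point at
``X-Collection``; absence phenotypes receive two definitions of one class —
the empty-collection form (``X-Collection and has_member only Nothing``) and
the negative form (``not (has_part some (quality and characteristic_of some
X))``) — whose right-hand sides thereby become equivalent.  Grouping classes
collect all abnormalities of one collection (CXP) and one quality across all
collections (CQ).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .eq import CardinalityConfig, detect_cardinality_phenotypes, match_eq_expression
from .expressions import (
    And,
    Atom,
    Bottom,
    EquivalentClasses,
    Expr,
    Not,
    OneOf,
    Only,
    Some,
    SubClassOf,
    eq_expression,
    CHARACTERISTIC_OF,
    HAS_MEMBER,
    HAS_PART,
    HAS_MODIFIER,
    MEMBER_OF,
    PART_OF,
)
from .ontology import ClassTerm, EQDefinition, Ontology, OntologyError, SubsumptionGraph

logger = logging.getLogger(__name__)

ROOT_COLLECTION_ID = "COLL:root"
ROOT_COLLECTION_LABEL = "collection of cells"


def _local(class_id: str) -> str:
    return class_id.replace(":", "_")


def collection_id(entity_id: str) -> str:
    return f"COLL:{_local(entity_id)}"


def collection_individual_id(entity_id: str) -> str:
    return f"COLLI:{_local(entity_id)}"


def cxp_id(entity_id: str) -> str:
    return f"CXP:{_local(entity_id)}"


def cq_id(quality_id: str) -> str:
    return f"CQ:{_local(quality_id)}"


@dataclass(frozen=True)
class CollectionClass:
    id: str
    member_class_id: str
    nominal_individual_id: str


@dataclass(frozen=True)
class RewrittenAxioms:
    """The new definition(s) of one cardinality phenotype class.

    ``kind`` is ``amount`` (quality under *amount*, entity replaced by its
    collection) or ``absence`` (dual definitions).  The original entity-based
    definition is replaced, not retained.
    """

    source_phenotype_id: str
    kind: str  # "amount" | "absence"
    quality_id: str
    entity_id: str
    collection_id: str
    has_abnormal_modifier: bool
    strength: str  # "equivalent" | "subclass"
    primary_axiom: object = None
    negative_absence_axiom: object = None


@dataclass(frozen=True)
class GroupingClass:
    id: str
    kind: str  # "by_collection" | "by_quality"
    anchor_id: str
    root_collection_id: Optional[str] = None
    axiom: object = None


@dataclass
class RewrittenOntology:
    """The input ontology plus generated collection machinery.

    ``provenance`` maps every generated id to its source id and the schema
    that produced it, for reproducibility audits.
    """

    ontology: Ontology
    config: CardinalityConfig
    collections: dict[str, CollectionClass] = field(default_factory=dict)  # entity -> coll
    root_collection_id: str = ROOT_COLLECTION_ID
    rewrites: dict[str, RewrittenAxioms] = field(default_factory=dict)  # phenotype ->
    groupings: list[GroupingClass] = field(default_factory=list)
    partonomy: list[SubClassOf] = field(default_factory=list)
    provenance: list[tuple[str, str, str]] = field(default_factory=list)

    def summary(self) -> dict[str, int]:
        return {
            "collections": len(self.collections),
            "rewritten_phenotypes": len(self.rewrites),
            "grouping_classes": len(self.groupings),
            "partonomy_axioms": len(self.partonomy),
        }


def _ensure_root_collection(onto: Ontology, rw: RewrittenOntology) -> None:
    if ROOT_COLLECTION_ID not in onto:
        onto.add_class(
            ClassTerm(ROOT_COLLECTION_ID, ROOT_COLLECTION_LABEL, "collection")
        )
        rw.provenance.append((ROOT_COLLECTION_ID, "-", "root-collection"))


def make_collection_class(
    rw: RewrittenOntology, entity_id: str
) -> CollectionClass:
    """Create (or return) the collection class for ``entity_id``.

    Emits the member-typing, membership and nominal axioms plus
    ``X-Collection [= C``.  Idempotent: a second call returns the existing
    collection without duplicating axioms.
    """
    onto = rw.ontology
    entity_id = onto.canonical(entity_id)
    if entity_id not in onto:
        raise OntologyError(f"unknown entity {entity_id!r}")
    if entity_id in rw.collections:
        return rw.collections[entity_id]
    _ensure_root_collection(onto, rw)
    cid = collection_id(entity_id)
    ind = collection_individual_id(entity_id)
    if cid in onto:
        raise OntologyError(f"generated collection id {cid!r} collides with input")
    if ind in onto.individuals:
        raise OntologyError(f"generated individual id {ind!r} collides with input")
    label = onto.get(entity_id).label or entity_id
    onto.add_class(ClassTerm(cid, f"collection of {label}", "collection"))
    onto.individuals.add(ind)
    onto.axioms.append(SubClassOf(Atom(cid), Only(HAS_MEMBER, Atom(entity_id))))
    onto.axioms.append(SubClassOf(Atom(entity_id), Some(MEMBER_OF, Atom(cid))))
    onto.axioms.append(EquivalentClasses(Atom(cid), OneOf((ind,))))
    onto.add_subclass_of(cid, ROOT_COLLECTION_ID)
    coll = CollectionClass(cid, entity_id, ind)
    rw.collections[entity_id] = coll
    rw.provenance.append((cid, entity_id, "collection"))
    return coll


def materialize_partonomy(
    rw: RewrittenOntology, entity_graph: Optional[SubsumptionGraph] = None
) -> list[SubClassOf]:
    """Assert ``X-Collection [= part_of some Y-Collection`` for every
    non-reflexive ``X [= Y`` in the entity closure restricted to entities
    having collections (missing collections are auto-created)."""
    onto = rw.ontology
    graph = entity_graph if entity_graph is not None else onto.entity_graph()
    closure = graph.closure()
    in_scope = set(rw.collections)
    # ancestors of in-scope entities are pulled into scope
    for ent in sorted(in_scope):
        for anc in sorted(closure.ancestors(ent)):
            if anc not in rw.collections:
                logger.info("auto-creating collection for ancestor entity %s", anc)
                make_collection_class(rw, anc)
    axioms = []
    for sub, sup in sorted(closure.edges):
        if sub == sup or sub not in rw.collections or sup not in rw.collections:
            continue
        ax = SubClassOf(
            Atom(rw.collections[sub].id),
            Some(PART_OF, Atom(rw.collections[sup].id)),
        )
        axioms.append(ax)
    existing = set(rw.partonomy)
    for ax in axioms:
        if ax not in existing:
            rw.partonomy.append(ax)
            onto.axioms.append(ax)
    return axioms


def rewrite_phenotype(
    rw: RewrittenOntology, eqdef: EQDefinition
) -> RewrittenAxioms:
    """Replace one cardinality phenotype's EQ definition with its
    collection-based form; see module docstring for the two kinds."""
    onto = rw.ontology
    config = rw.config
    pid = onto.canonical(eqdef.phenotype_id)
    if pid in rw.rewrites:
        return rw.rewrites[pid]
    entity = onto.canonical(eqdef.entity_id)
    if entity not in rw.collections:
        raise OntologyError(
            f"no collection class for entity {entity!r}; create it first"
        )
    coll = rw.collections[entity]
    kind = "absence" if eqdef.quality_id in config.absence_ids else "amount"
    modifier = config.abnormal_id if eqdef.has_abnormal_modifier else None
    lhs = Atom(pid)
    if kind == "amount":
        rhs = eq_expression(eqdef.quality_id, Atom(coll.id), modifier)
        primary = (
            EquivalentClasses(lhs, rhs)
            if eqdef.strength == "equivalent"
            else SubClassOf(lhs, rhs)
        )
        negative = None
    else:
        empty_coll = And([Atom(coll.id), Only(HAS_MEMBER, Bottom())])
        rhs_empty = eq_expression(config.quality_root_id, empty_coll, modifier)
        rhs_negative = Not(
            Some(
                HAS_PART,
                And([Atom(config.quality_root_id),
                     Some(CHARACTERISTIC_OF, Atom(entity))]),
            )
        )
        primary = EquivalentClasses(lhs, rhs_empty)
        negative = EquivalentClasses(lhs, rhs_negative)
    # replace the original entity-based definition
    onto.eq_definitions.pop(pid, None)
    onto.axioms.append(primary)
    if negative is not None:
        onto.axioms.append(negative)
    result = RewrittenAxioms(
        source_phenotype_id=pid,
        kind=kind,
        quality_id=eqdef.quality_id,
        entity_id=entity,
        collection_id=coll.id,
        has_abnormal_modifier=eqdef.has_abnormal_modifier,
        # the dual absence construction is inherently definitional
        strength="equivalent" if kind == "absence" else eqdef.strength,
        primary_axiom=primary,
        negative_absence_axiom=negative,
    )
    rw.rewrites[pid] = result
    rw.provenance.append((pid, pid, f"rewrite-{kind}"))
    return result


def make_grouping_classes(
    rw: RewrittenOntology, qualities: Optional[Iterable[str]] = None
) -> list[GroupingClass]:
    """One CXP grouping class per collection; one CQ per quality.

    Both are emitted as full (equivalence) definitions so the fragment
    classifier can place rewritten phenotypes under them.  ``qualities``
    defaults to the amount qualities appearing in the rewrites.
    """
    onto = rw.ontology
    config = rw.config
    _ensure_root_collection(onto, rw)
    made: list[GroupingClass] = []
    existing = {g.id for g in rw.groupings}
    for ent in sorted(rw.collections):
        coll = rw.collections[ent]
        gid = cxp_id(ent)
        if gid in existing:
            continue
        if gid in onto:
            raise OntologyError(f"generated grouping id {gid!r} collides with input")
        label = onto.get(ent).label or ent
        onto.add_class(ClassTerm(gid, f"abnormality of collection of {label}", "grouping"))
        ax = EquivalentClasses(
            Atom(gid),
            eq_expression(config.quality_root_id, Atom(coll.id), config.abnormal_id),
        )
        onto.axioms.append(ax)
        g = GroupingClass(gid, "by_collection", coll.id, axiom=ax)
        rw.groupings.append(g)
        made.append(g)
        rw.provenance.append((gid, ent, "grouping-by-collection"))
    if qualities is None:
        qualities = {r.quality_id for r in rw.rewrites.values() if r.kind == "amount"}
    for q in sorted(qualities):
        gid = cq_id(q)
        if gid in existing or any(g.id == gid for g in rw.groupings):
            continue
        if gid in onto:
            raise OntologyError(f"generated grouping id {gid!r} collides with input")
        qlabel = onto.get(q).label if q in onto else q
        onto.add_class(ClassTerm(gid, f"{qlabel or q} cardinality", "grouping"))
        ax = EquivalentClasses(
            Atom(gid),
            eq_expression(q, Atom(ROOT_COLLECTION_ID), config.abnormal_id),
        )
        onto.axioms.append(ax)
        g = GroupingClass(gid, "by_quality", q, root_collection_id=ROOT_COLLECTION_ID, axiom=ax)
        rw.groupings.append(g)
        made.append(g)
        rw.provenance.append((gid, q, "grouping-by-quality"))
    return made


def reconstruct_rewritten(
    ontology: Ontology, config: Optional[CardinalityConfig] = None
) -> RewrittenOntology:
    """Rebuild the structured view of a rewritten ontology from its axioms.

    Used after reading a rewritten ontology back from disk: collections,
    rewrites, groupings and partonomy assertions are recovered structurally
    (namespace annotations distinguish collection and grouping classes).
    """
    config = config or CardinalityConfig()
    rw = RewrittenOntology(ontology=ontology, config=config)
    member_of_coll: dict[str, str] = {}
    nominal_of_coll: dict[str, str] = {}
    for ax in ontology.axioms:
        if isinstance(ax, SubClassOf) and isinstance(ax.sub, Atom) and \
                isinstance(ax.sup, Only) and ax.sup.prop == HAS_MEMBER and \
                isinstance(ax.sup.filler, Atom):
            member_of_coll[ax.sub.id] = ax.sup.filler.id
        if isinstance(ax, EquivalentClasses):
            pair = [(a, b) for a, b in ((ax.a, ax.b), (ax.b, ax.a))
                    if isinstance(a, Atom) and isinstance(b, OneOf)]
            if pair:
                nominal_of_coll[pair[0][0].id] = pair[0][1].individuals[0]
    for cid, ent in member_of_coll.items():
        rw.collections[ent] = CollectionClass(
            cid, ent, nominal_of_coll.get(cid, collection_individual_id(ent))
        )
    coll_ids = {c.id: ent for ent, c in rw.collections.items()}
    roots = [
        t.id for t in ontology
        if t.namespace == "collection" and t.id not in coll_ids
    ]
    if roots:
        rw.root_collection_id = roots[0]

    def _match_eq_rhs(rhs):
        return match_eq_expression(rhs)

    for ax in ontology.axioms:
        if isinstance(ax, SubClassOf) and isinstance(ax.sub, Atom) and \
                isinstance(ax.sup, Some) and ax.sup.prop == PART_OF and \
                isinstance(ax.sup.filler, Atom) and ax.sub.id in coll_ids:
            rw.partonomy.append(ax)
            continue
        if not isinstance(ax, (SubClassOf, EquivalentClasses)):
            continue
        if isinstance(ax, SubClassOf):
            lhs, rhs, strength = ax.sub, ax.sup, "subclass"
        else:
            lhs, rhs, strength = ax.a, ax.b, "equivalent"
            if not isinstance(lhs, Atom) and isinstance(rhs, Atom):
                lhs, rhs = rhs, lhs
        if not isinstance(lhs, Atom) or lhs.id not in ontology:
            continue
        ns = ontology.get(lhs.id).namespace
        if ns == "grouping":
            m = _match_eq_rhs(rhs)
            if m is None:
                continue
            quality, target, _mod = m
            if target == rw.root_collection_id:
                rw.groupings.append(
                    GroupingClass(lhs.id, "by_quality", quality,
                                  root_collection_id=rw.root_collection_id, axiom=ax)
                )
            elif target in coll_ids:
                rw.groupings.append(
                    GroupingClass(lhs.id, "by_collection", target, axiom=ax)
                )
            continue
        if ns == "phenotype":
            # amount rewrite: EQ over a collection atom
            m = _match_eq_rhs(rhs)
            if m is not None and m[1] in coll_ids and lhs.id not in rw.rewrites:
                quality, cid, mod = m
                rw.rewrites[lhs.id] = RewrittenAxioms(
                    lhs.id, "amount", quality, coll_ids[cid], cid, mod, strength,
                    primary_axiom=ax,
                )
                continue
            # absence rewrite: negative form names the member entity directly
            if isinstance(rhs, Not) and isinstance(rhs.operand, Some) and \
                    rhs.operand.prop == HAS_PART and isinstance(rhs.operand.filler, And):
                entity = None
                for op in rhs.operand.filler.operands:
                    if isinstance(op, Some) and op.prop == CHARACTERISTIC_OF and \
                            isinstance(op.filler, Atom):
                        entity = op.filler.id
                if entity is not None and entity in rw.collections:
                    coll = rw.collections[entity]
                    rw.rewrites[lhs.id] = RewrittenAxioms(
                        lhs.id, "absence", config.quality_root_id, entity, coll.id,
                        True, "equivalent", negative_absence_axiom=ax,
                    )
    return rw


def rewrite_ontology(
    ontology: Ontology, config: Optional[CardinalityConfig] = None
) -> RewrittenOntology:
    """Full pipeline: detect -> collections -> partonomy -> rewrites -> groupings.

    Returns a :class:`RewrittenOntology` over a *copy* of the input; the input
    ontology is never modified, so failures cannot leave partial output.
    Deterministic for identical input.
    """
    config = config or CardinalityConfig()
    detections = detect_cardinality_phenotypes(ontology, config)
    rw = RewrittenOntology(ontology=ontology.copy(), config=config)
    _ensure_root_collection(rw.ontology, rw)
    for eqdef in detections:
        make_collection_class(rw, eqdef.entity_id)
    materialize_partonomy(rw)
    for eqdef in detections:
        rewrite_phenotype(rw, eqdef)
    make_grouping_classes(rw)
    logger.info("rewrite summary: %s", rw.summary())
    return rw
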