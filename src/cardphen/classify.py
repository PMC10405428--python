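"""Entailed subsumption hierarchies for the EQ and collection fragments.

A full OWL 2 DL reasoner is not required for the axiom schemata this package
emits; a fixed rule set per mode is sound and complete for them:

original mode (plain EQ definitions)
    P1 [= P2  iff  quality(P1) [= quality(P2), entity(P1) [= entity(P2),
    P2 is fully defined (equivalence strength), and P2's abnormal-modifier
    conjunct (if any) is present in P1.  This is existential-restriction
    monotonicity over the shared ``has_part`` pattern.

revised mode (collection rewrite output)
    R1  amount:     CP(Q1, X-Coll) [= CP(Q2, Y-Coll) iff Q1 [= Q2 and X = Y
                    (collections of distinct entities are nominal singletons,
                    hence incomparable).
    R2  absence:    absent_X [= absent_Y iff Y [= X in the entity order (the
                    negative form inverts the direction).
    R3  grouping:   every rewritten class over X-Coll [= CXP(X).
    R4  quality:    CP(Q1, X-Coll) [= CQ(Q2) iff Q1 [= Q2 (every X-Coll [= C).
    R5  asserted is-a edges, plus transitivity over everything above.
    Untouched (non-cardinality) EQ definitions still classify among
    themselves by the original-mode rule.

Both classifiers are checked against :func:`naive_saturation_oracle`, an
independent exhaustive fixpoint computation with no shared closure machinery.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .ontology import EQDefinition, Ontology, OntologyError, SubsumptionGraph
from .rewrite import RewrittenAxioms, RewrittenOntology


def _check_eqdefs(
    eqdefs: Sequence[EQDefinition],
    entity_closure: SubsumptionGraph,
    quality_closure: SubsumptionGraph,
) -> None:
    for d in eqdefs:
        if d.entity_id not in entity_closure:
            raise OntologyError(f"entity {d.entity_id!r} missing from entity closure")
        if d.quality_id not in quality_closure:
            raise OntologyError(f"quality {d.quality_id!r} missing from quality closure")


def _eq_rule_edges(
    eqdefs: Sequence[EQDefinition],
    entity_closure: SubsumptionGraph,
    quality_closure: SubsumptionGraph,
) -> set[tuple[str, str]]:
    edges = set()
    for d1 in eqdefs:
        for d2 in eqdefs:
            if d1.phenotype_id == d2.phenotype_id:
                continue
            if d2.strength != "equivalent":
                continue  # primitive classes gain no subclasses from the pattern
            if d2.has_abnormal_modifier and not d1.has_abnormal_modifier:
                continue
            if quality_closure.entails(d1.quality_id, d2.quality_id) and \
                    entity_closure.entails(d1.entity_id, d2.entity_id):
                edges.add((d1.phenotype_id, d2.phenotype_id))
    return edges


def classify_original(
    eqdefs: Sequence[EQDefinition],
    entity_closure: SubsumptionGraph,
    quality_closure: SubsumptionGraph,
    asserted: Iterable[tuple[str, str]] = (),
) -> SubsumptionGraph:
    """Entailed phenotype hierarchy under the plain EQ semantics."""
    _check_eqdefs(eqdefs, entity_closure, quality_closure)
    nodes = {d.phenotype_id for d in eqdefs}
    asserted = list(asserted)
    for s, t in asserted:
        nodes.update((s, t))
    g = SubsumptionGraph(nodes, asserted, allow_cycles=True)
    provenance = {e: "asserted" for e in asserted}
    for e in _eq_rule_edges(eqdefs, entity_closure, quality_closure):
        g.add_edge(*e)
        provenance.setdefault(e, "eq-monotonicity")
    g.provenance = provenance
    g.closure()  # warm the cache; inferred equivalences show as mutual edges
    return g


def classify_original_ontology(ontology: Ontology) -> SubsumptionGraph:
    """Convenience wrapper taking closures and asserted edges from an ontology."""
    return classify_original(
        list(ontology.eq_definitions.values()),
        ontology.entity_graph().closure(),
        ontology.quality_graph().closure(),
        ontology.phenotype_graph().edges,
    )


def classify_revised(rewritten: RewrittenOntology) -> SubsumptionGraph:
    """Entailed hierarchy over the rewritten ontology (rules R1--R5)."""
    onto = rewritten.ontology
    entity_closure = onto.entity_graph().closure()
    quality_closure = onto.quality_graph().closure()
    rewrites = rewritten.rewrites
    groupings = {g.id: g for g in rewritten.groupings}
    cxp_by_collection = {
        g.anchor_id: g.id for g in rewritten.groupings if g.kind == "by_collection"
    }
    cq_by_quality = {
        g.anchor_id: g.id for g in rewritten.groupings if g.kind == "by_quality"
    }

    untouched = list(onto.eq_definitions.values())
    _check_eqdefs(untouched, entity_closure, quality_closure)
    for r in rewrites.values():
        if r.entity_id not in entity_closure:
            raise OntologyError(f"entity {r.entity_id!r} missing from entity closure")
        if r.kind == "amount" and r.quality_id not in quality_closure:
            raise OntologyError(f"quality {r.quality_id!r} missing from quality closure")

    nodes = set(rewrites) | set(groupings) | {d.phenotype_id for d in untouched}
    asserted = [
        (s, t) for s, t in onto.phenotype_graph().edges
    ]
    for s, t in asserted:
        nodes.update((s, t))
    g = SubsumptionGraph(nodes, asserted, allow_cycles=True)
    provenance = {e: "asserted" for e in asserted}

    amounts = [r for r in rewrites.values() if r.kind == "amount"]
    absences = [r for r in rewrites.values() if r.kind == "absence"]
    # R1: same collection, quality monotone; modifier must weaken
    for r1 in amounts:
        for r2 in amounts:
            if r1 is r2 or r2.strength != "equivalent":
                continue
            if r1.entity_id != r2.entity_id:
                continue
            if r2.has_abnormal_modifier and not r1.has_abnormal_modifier:
                continue
            if quality_closure.entails(r1.quality_id, r2.quality_id):
                g.add_edge(r1.source_phenotype_id, r2.source_phenotype_id)
                provenance.setdefault((r1.source_phenotype_id, r2.source_phenotype_id), "R1-amount")
    # R2: absence inverts the entity order
    for r1 in absences:
        for r2 in absences:
            if r1 is r2:
                continue
            if entity_closure.entails(r2.entity_id, r1.entity_id):
                g.add_edge(r1.source_phenotype_id, r2.source_phenotype_id)
                provenance.setdefault((r1.source_phenotype_id, r2.source_phenotype_id), "R2-absence-inversion")
    # R3: everything over X-Coll sits under CXP(X)
    for r in amounts + absences:
        gid = cxp_by_collection.get(r.collection_id)
        if gid is not None:
            g.add_edge(r.source_phenotype_id, gid)
            provenance.setdefault((r.source_phenotype_id, gid), "R3-collection-grouping")
    # R4: amount classes sit under matching quality groupings
    for r in amounts:
        for q, gid in cq_by_quality.items():
            if q in quality_closure and r.quality_id in quality_closure and \
                    quality_closure.entails(r.quality_id, q):
                g.add_edge(r.source_phenotype_id, gid)
                provenance.setdefault((r.source_phenotype_id, gid), "R4-quality-grouping")
    # untouched EQ definitions classify among themselves as before
    for e in _eq_rule_edges(untouched, entity_closure, quality_closure):
        g.add_edge(*e)
        provenance.setdefault(e, "eq-monotonicity")
    g.provenance = provenance
    g.closure()
    return g


def entails(graph: SubsumptionGraph, sub_id: str, super_id: str) -> bool:
    """Membership test on the closed classification graph."""
    return graph.entails(sub_id, super_id)


# ---------------------------------------------------------------------------
# Naive saturation oracle: deliberately unoptimized and self-contained.
# ---------------------------------------------------------------------------


def _naive_reachable(edges: set[tuple[str, str]], a: str, b: str) -> bool:
    """Reflexive-transitive reachability by plain depth-first search."""
    if a == b:
        return True
    stack, seen = [a], {a}
    while stack:
        x = stack.pop()
        for s, t in edges:
            if s == x and t not in seen:
                if t == b:
                    return True
                seen.add(t)
                stack.append(t)
    return False


def naive_saturation_oracle(
    payload,
    mode: str,
) -> set[tuple[str, str]]:
    """Reference entailment set by exhaustive fixpoint iteration.

    ``payload`` is an :class:`Ontology` for ``mode='original'`` or a
    :class:`RewrittenOntology` for ``mode='revised'``.  Returns the
    *non-reflexive* entailed edge set.  Intended for small inputs only.
    """
    if mode == "original":
        onto = payload
        rewrites: dict[str, RewrittenAxioms] = {}
        groupings = []
    elif mode == "revised":
        onto = payload.ontology
        rewrites = payload.rewrites
        groupings = payload.groupings
    else:
        raise ValueError(f"unknown mode {mode!r}")

    ent_edges = onto.entity_graph().edges
    qual_edges = onto.quality_graph().edges
    eqdefs = {d.phenotype_id: d for d in onto.eq_definitions.values()}
    cxp_of = {g.anchor_id: g.id for g in groupings if g.kind == "by_collection"}
    cq_of = {g.anchor_id: g.id for g in groupings if g.kind == "by_quality"}

    nodes = set(eqdefs) | set(rewrites) | {g.id for g in groupings}
    edges: set[tuple[str, str]] = set()
    for s, t in onto.phenotype_graph().edges:
        nodes.update((s, t))
        edges.add((s, t))

    def licensed(p1: str, p2: str) -> bool:
        d1, d2 = eqdefs.get(p1), eqdefs.get(p2)
        if d1 is not None and d2 is not None:
            if d2.strength != "equivalent":
                return False
            if d2.has_abnormal_modifier and not d1.has_abnormal_modifier:
                return False
            return _naive_reachable(qual_edges, d1.quality_id, d2.quality_id) and \
                _naive_reachable(ent_edges, d1.entity_id, d2.entity_id)
        r1, r2 = rewrites.get(p1), rewrites.get(p2)
        if r1 is not None and r2 is not None:
            if r1.kind == "amount" and r2.kind == "amount":
                if r2.strength != "equivalent":
                    return False
                if r2.has_abnormal_modifier and not r1.has_abnormal_modifier:
                    return False
                return r1.entity_id == r2.entity_id and \
                    _naive_reachable(qual_edges, r1.quality_id, r2.quality_id)
            if r1.kind == "absence" and r2.kind == "absence":
                return _naive_reachable(ent_edges, r2.entity_id, r1.entity_id)
            return False
        if r1 is not None:
            if p2 == cxp_of.get(r1.collection_id):
                return True
            if r1.kind == "amount":
                for q, gid in cq_of.items():
                    if gid == p2 and _naive_reachable(qual_edges, r1.quality_id, q):
                        return True
        return False

    changed = True
    while changed:
        changed = False
        for p1 in nodes:
            for p2 in nodes:
                if p1 == p2 or (p1, p2) in edges:
                    continue
                if licensed(p1, p2):
                    edges.add((p1, p2))
                    changed = True
        # transitivity, applied exhaustively
        for a, b in list(edges):
            for c in nodes:
                if c != a and (b, c) in edges and (a, c) not in edges:
                    edges.add((a, c))
                    changed = True
    return edges
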