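"""EQ-pattern matching and cardinality-phenotype detection.

A cardinality phenotype is a phenotype class whose EQ definition uses a
quality under *amount* (increased/decreased amount, absence, duplication) and
whose affected entity is an eligible entity class (by default any class in
the entity namespace; a CURIE-prefix filter can restrict this to, e.g.,
cell-type classes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .expressions import (
    And,
    Atom,
    Axiom,
    EquivalentClasses,
    Expr,
    Some,
    SubClassOf,
    CHARACTERISTIC_OF,
    HAS_MODIFIER,
    HAS_PART,
)
from .ontology import EQDefinition, Ontology, OntologyError, SubsumptionGraph

logger = logging.getLogger(__name__)

# PATO identifiers for the amount branch and the abnormal modifier
QUALITY_ROOT = "PATO:0000001"
AMOUNT = "PATO:0000070"
INCREASED_AMOUNT = "PATO:0000470"
DECREASED_AMOUNT = "PATO:0001997"
ABSENT = "PATO:0000462"
DUPLICATED = "PATO:0001473"
ABNORMAL = "PATO:0000460"


@dataclass(frozen=True)
class CardinalityConfig:
    """What counts as a cardinality phenotype.

    ``absence_ids`` lists the qualities read as absence (empty collection);
    they are normally descendants of ``amount_root_id`` but may be explicitly
    whitelisted.  ``entity_prefixes`` restricts eligible entities by CURIE
    prefix (``None`` admits every class in the entity namespace).
    """

    amount_root_id: str = AMOUNT
    absence_ids: frozenset[str] = frozenset({ABSENT})
    entity_prefixes: Optional[frozenset[str]] = None
    quality_root_id: str = QUALITY_ROOT
    abnormal_id: str = ABNORMAL


def _match_inner_conjunction(expr: Expr) -> Optional[tuple[str, str, bool]]:
    """Match ``Q and characteristic_of some E [and has_modifier some abnormal]``."""
    if not isinstance(expr, And):
        return None
    quality = entity = None
    modifier = False
    for op in expr.operands:
        if isinstance(op, Atom):
            if quality is not None:
                return None
            quality = op.id
        elif isinstance(op, Some) and op.prop == CHARACTERISTIC_OF and isinstance(op.filler, Atom):
            if entity is not None:
                return None
            entity = op.filler.id
        elif isinstance(op, Some) and op.prop == HAS_MODIFIER:
            modifier = True
        else:
            return None
    if quality is None or entity is None:
        return None
    return quality, entity, modifier


def match_eq_expression(expr: Expr) -> Optional[tuple[str, str, bool]]:
    """Match the EQ right-hand side; returns (quality, entity, has_modifier).

    Accepts the modifier conjunct either inside the inner conjunction or as an
    outer conjunct next to the ``has_part`` restriction.
    """
    outer_modifier = False
    if isinstance(expr, And):
        rest = [op for op in expr.operands
                if not (isinstance(op, Some) and op.prop == HAS_MODIFIER)]
        if len(rest) == len(expr.operands) or len(rest) != 1:
            return None
        outer_modifier = True
        expr = rest[0]
    if not (isinstance(expr, Some) and expr.prop == HAS_PART):
        return None
    m = _match_inner_conjunction(expr.filler)
    if m is None:
        return None
    quality, entity, inner_modifier = m
    return quality, entity, inner_modifier or outer_modifier


def parse_eq_definition(axiom: Axiom, ontology: Optional[Ontology] = None) -> Optional[EQDefinition]:
    """Extract an :class:`EQDefinition` from a (sub)class or equivalence axiom.

    Returns ``None`` for axioms that do not match the pattern; such axioms are
    left untouched by every downstream step.  If an ``ontology`` is given, the
    quality and entity ids must be declared classes.
    """
    if isinstance(axiom, SubClassOf):
        lhs, rhs, strength = axiom.sub, axiom.sup, "subclass"
    elif isinstance(axiom, EquivalentClasses):
        lhs, rhs, strength = axiom.a, axiom.b, "equivalent"
    else:
        return None
    if not isinstance(lhs, Atom):
        # the defined class must be named; allow the named side on the right
        if isinstance(axiom, EquivalentClasses) and isinstance(rhs, Atom):
            lhs, rhs = rhs, lhs
        else:
            return None
    m = match_eq_expression(rhs)
    if m is None:
        return None
    quality, entity, modifier = m
    if ontology is not None:
        for cid in (quality, entity):
            if cid not in ontology:
                raise OntologyError(
                    f"EQ definition of {lhs.id} references undeclared class {cid!r}"
                )
    return EQDefinition(
        phenotype_id=lhs.id,
        quality_id=quality,
        entity_id=entity,
        has_abnormal_modifier=modifier,
        strength=strength,
    )


def is_cardinality_phenotype(
    eqdef: EQDefinition,
    quality_graph: SubsumptionGraph,
    config: CardinalityConfig,
    entity_namespace_ids: Optional[set[str]] = None,
) -> bool:
    """True iff the quality is under *amount* (or whitelisted as absence) and
    the entity passes the namespace/prefix filter."""
    q = eqdef.quality_id
    if q in config.absence_ids:
        quality_ok = True
    else:
        if q not in quality_graph:
            raise OntologyError(f"quality {q!r} absent from the quality hierarchy")
        quality_ok = quality_graph.entails(q, config.amount_root_id) \
            if config.amount_root_id in quality_graph else False
    if not quality_ok:
        return False
    e = eqdef.entity_id
    if entity_namespace_ids is not None and e not in entity_namespace_ids:
        return False
    if config.entity_prefixes is not None:
        prefix = e.split(":", 1)[0]
        if prefix not in config.entity_prefixes:
            return False
    return True


def detect_cardinality_phenotypes(
    ontology: Ontology, config: CardinalityConfig
) -> list[EQDefinition]:
    """All EQ definitions in the ontology that are cardinality phenotypes,
    sorted by phenotype id."""
    quality_graph = ontology.quality_graph()
    entity_ids = ontology.ids_in_namespace("entity")
    out = [
        eqdef
        for pid, eqdef in sorted(ontology.eq_definitions.items())
        if is_cardinality_phenotype(eqdef, quality_graph, config, entity_ids)
    ]
    logger.info("detected %d cardinality phenotype classes", len(out))
    return out
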