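"""Class-expression trees for the OWL fragment this package emits.

The fragment covers exactly the constructors needed by EQ phenotype
definitions and the collection rewrite: named classes, existential and
universal restrictions, intersection, complement, nominal enumeration and the
bottom class.  Expressions are immutable and hashable so axiom sets can be
deduplicated and compared structurally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

# object properties used by the emitted axiom schemata
HAS_PART = "has_part"
PART_OF = "part_of"
CHARACTERISTIC_OF = "characteristic_of"
HAS_MODIFIER = "has_modifier"
HAS_MEMBER = "has_member"
MEMBER_OF = "member_of"

OBJECT_PROPERTIES = (
    HAS_PART,
    PART_OF,
    CHARACTERISTIC_OF,
    HAS_MODIFIER,
    HAS_MEMBER,
    MEMBER_OF,
)


@dataclass(frozen=True)
class Atom:
    """A named class."""

    id: str


@dataclass(frozen=True)
class Bottom:
    """owl:Nothing."""


@dataclass(frozen=True)
class Some:
    """ObjectSomeValuesFrom(prop filler)."""

    prop: str
    filler: "Expr"


@dataclass(frozen=True)
class Only:
    """ObjectAllValuesFrom(prop filler)."""

    prop: str
    filler: "Expr"


@dataclass(frozen=True)
class And:
    """ObjectIntersectionOf; operands stored sorted for structural equality."""

    operands: tuple["Expr", ...]

    def __init__(self, operands):
        object.__setattr__(
            self, "operands", tuple(sorted(operands, key=_expr_sort_key))
        )


@dataclass(frozen=True)
class Not:
    """ObjectComplementOf."""

    operand: "Expr"


@dataclass(frozen=True)
class OneOf:
    """ObjectOneOf over named individuals."""

    individuals: tuple[str, ...]

    def __init__(self, individuals):
        object.__setattr__(self, "individuals", tuple(sorted(individuals)))


Expr = Union[Atom, Bottom, Some, Only, And, Not, OneOf]


def _expr_sort_key(e: "Expr") -> str:
    return render(e)


@dataclass(frozen=True)
class SubClassOf:
    sub: Expr
    sup: Expr


@dataclass(frozen=True)
class EquivalentClasses:
    a: Expr
    b: Expr


Axiom = Union[SubClassOf, EquivalentClasses]


def render(e: Expr) -> str:
    """Deterministic functional-syntax-style rendering (used for sorting/diffs)."""
    if isinstance(e, Atom):
        return e.id
    if isinstance(e, Bottom):
        return "owl:Nothing"
    if isinstance(e, Some):
        return f"ObjectSomeValuesFrom(:{e.prop} {render(e.filler)})"
    if isinstance(e, Only):
        return f"ObjectAllValuesFrom(:{e.prop} {render(e.filler)})"
    if isinstance(e, And):
        return "ObjectIntersectionOf(" + " ".join(render(o) for o in e.operands) + ")"
    if isinstance(e, Not):
        return f"ObjectComplementOf({render(e.operand)})"
    if isinstance(e, OneOf):
        return "ObjectOneOf(" + " ".join(f":{i.replace(':', '_')}" for i in e.individuals) + ")"
    raise TypeError(f"not an expression: {e!r}")


def render_axiom(ax: Axiom) -> str:
    if isinstance(ax, SubClassOf):
        return f"SubClassOf({render(ax.sub)} {render(ax.sup)})"
    if isinstance(ax, EquivalentClasses):
        return f"EquivalentClasses({render(ax.a)} {render(ax.b)})"
    raise TypeError(f"not an axiom: {ax!r}")


def eq_expression(
    quality_id: str,
    entity_expr: Expr,
    abnormal_modifier_id: str | None,
    modifier_inside: bool = True,
) -> Expr:
    """Build ``has_part some (Q and characteristic_of some E [...])``.

    The abnormal-modifier conjunct may sit inside the inner conjunction or
    outside the ``has_part`` restriction; both nestings occur in published
    phenotype ontologies and both are accepted by the EQ matcher.
    """
    inner = [Atom(quality_id), Some(CHARACTERISTIC_OF, entity_expr)]
    if abnormal_modifier_id and modifier_inside:
        inner.append(Some(HAS_MODIFIER, Atom(abnormal_modifier_id)))
    core = Some(HAS_PART, And(inner))
    if abnormal_modifier_id and not modifier_inside:
        return And([core, Some(HAS_MODIFIER, Atom(abnormal_modifier_id))])
    return core
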