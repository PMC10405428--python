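"""OWL 2 Functional-Style Syntax subset writer and reader.

Covers exactly the constructors the collection rewrite emits: class and
individual declarations, ``SubClassOf``, ``EquivalentClasses``,
``ObjectSomeValuesFrom``, ``ObjectAllValuesFrom``, ``ObjectIntersectionOf``,
``ObjectComplementOf``, ``ObjectOneOf`` and ``owl:Nothing``.  Labels and term
namespaces travel as annotation assertions so a write -> read round trip
reconstructs the full in-memory ontology.  Output is deterministic (sorted
declarations and axioms).
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterator, Optional

from ..eq import parse_eq_definition
from ..expressions import (
    And,
    Atom,
    Bottom,
    EquivalentClasses,
    Expr,
    Not,
    OBJECT_PROPERTIES,
    OneOf,
    Only,
    Some,
    SubClassOf,
    render,
    render_axiom,
)
from ..ontology import ClassTerm, Ontology, OntologyError

logger = logging.getLogger(__name__)

_BASE = "https://cardphen.example"
_FIXED_PREFIXES = {
    "": f"{_BASE}/vocab#",
    "owl": "http://www.w3.org/2002/07/owl#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
}
_NS_ANNOTATION = ":term_namespace"


def _curie_prefixes(ontology: Ontology) -> list[str]:
    prefixes = set()
    for term in ontology:
        prefixes.add(term.id.split(":", 1)[0])
    for ind in ontology.individuals:
        prefixes.add(ind.split(":", 1)[0])
    for alias in set().union(*[ontology.synonyms_of(t.id) for t in ontology] or [set()]):
        prefixes.add(alias.split(":", 1)[0])
    return sorted(prefixes)


def write_owl_functional(ontology: Ontology, path) -> None:
    path = Path(path)
    out: list[str] = []
    for p, iri in _FIXED_PREFIXES.items():
        out.append(f"Prefix({p}:=<{iri}>)")
    for p in _curie_prefixes(ontology):
        out.append(f"Prefix({p}:=<{_BASE}/id/{p}_>)")
    out.append(f"Ontology(<{_BASE}/ontology>")

    decls: list[str] = []
    axioms: list[str] = []
    for prop in OBJECT_PROPERTIES:
        decls.append(f"Declaration(ObjectProperty(:{prop}))")
    for term in ontology:
        decls.append(f"Declaration(Class({term.id}))")
        if term.label:
            axioms.append(
                f'AnnotationAssertion(rdfs:label {term.id} "{_escape(term.label)}")'
            )
        axioms.append(
            f'AnnotationAssertion({_NS_ANNOTATION} {term.id} "{term.namespace}")'
        )
        for alias in sorted(ontology.synonyms_of(term.id) - {term.id}):
            axioms.append(
                f'AnnotationAssertion(:synonym_id {term.id} "{alias}")'
            )
    for ind in sorted(ontology.individuals):
        decls.append(f"Declaration(NamedIndividual(:{ind.replace(':', '_')}))")
    for sub, sup in ontology.graph.edges:
        axioms.append(f"SubClassOf({sub} {sup})")
    for eqdef in ontology.eq_definitions.values():
        from ..eq import ABNORMAL
        from ..expressions import eq_expression

        rhs = eq_expression(
            eqdef.quality_id,
            Atom(eqdef.entity_id),
            ABNORMAL if eqdef.has_abnormal_modifier else None,
        )
        if eqdef.strength == "equivalent":
            axioms.append(f"EquivalentClasses({eqdef.phenotype_id} {render(rhs)})")
        else:
            axioms.append(f"SubClassOf({eqdef.phenotype_id} {render(rhs)})")
    for ax in ontology.axioms:
        axioms.append(_render_axiom_owl(ax))
    out.extend(sorted(set(decls)))
    out.extend(sorted(set(axioms)))
    out.append(")")
    path.write_text("\n".join(out) + "\n")


def _escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"')


def _render_axiom_owl(ax) -> str:
    # the shared renderer already uses functional-syntax constructors; map
    # individual CURIEs in nominals onto the default prefix
    text = render_axiom(ax)
    return text


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<lparen>\() | (?P<rparen>\)) |
    (?P<string>"(?:[^"\\]|\\.)*") |
    (?P<iri><[^>]*>) |
    (?P<name>[^\s()<>"]+)
    """,
    re.VERBOSE,
)


class OWLSyntaxError(OntologyError):
    def __init__(self, path, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


def _tokenize(path, text: str) -> Iterator[tuple[str, str, int]]:
    for lineno, line in enumerate(text.splitlines(), start=1):
        pos = 0
        stripped = line.strip()
        if stripped.startswith("#"):
            continue
        while pos < len(line):
            if line[pos].isspace():
                pos += 1
                continue
            m = _TOKEN_RE.match(line, pos)
            if m is None:
                raise OWLSyntaxError(path, lineno, f"unexpected character {line[pos]!r}")
            yield m.lastgroup, m.group(), lineno
            pos = m.end()


class _Parser:
    def __init__(self, path, text: str):
        self.path = path
        self.tokens = list(_tokenize(path, text))
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None, -1)

    def next(self):
        tok = self.peek()
        if tok[0] is None:
            raise OWLSyntaxError(self.path, -1, "unexpected end of file")
        self.i += 1
        return tok

    def expect(self, kind: str, value: Optional[str] = None):
        k, v, lineno = self.next()
        if k != kind or (value is not None and v != value):
            raise OWLSyntaxError(
                self.path, lineno, f"expected {value or kind}, found {v!r}"
            )
        return v

    def parse_expr(self) -> Expr:
        kind, value, lineno = self.next()
        if kind == "name" and self.peek()[0] != "lparen":
            if value == "owl:Nothing":
                return Bottom()
            return Atom(value)
        if kind != "name":
            raise OWLSyntaxError(self.path, lineno, f"expected class expression, found {value!r}")
        self.expect("lparen")
        if value in ("ObjectSomeValuesFrom", "ObjectAllValuesFrom"):
            prop = self.expect("name").lstrip(":")
            filler = self.parse_expr()
            self.expect("rparen")
            cls = Some if value == "ObjectSomeValuesFrom" else Only
            return cls(prop, filler)
        if value == "ObjectIntersectionOf":
            ops = []
            while self.peek()[0] != "rparen":
                ops.append(self.parse_expr())
            self.expect("rparen")
            return And(ops)
        if value == "ObjectComplementOf":
            inner = self.parse_expr()
            self.expect("rparen")
            return Not(inner)
        if value == "ObjectOneOf":
            inds = []
            while self.peek()[0] != "rparen":
                name = self.expect("name")
                inds.append(_individual_from_token(name))
            self.expect("rparen")
            return OneOf(tuple(inds))
        raise OWLSyntaxError(self.path, lineno, f"unsupported constructor {value!r}")


def _individual_from_token(tok: str) -> str:
    local = tok.lstrip(":")
    # individuals were written with ':' flattened to '_' under the default prefix
    if "_" in local and ":" not in local:
        prefix, rest = local.split("_", 1)
        return f"{prefix}:{rest}"
    return local


def read_owl_functional(path, strict: bool = True) -> Ontology:
    """Parse the functional-syntax subset back into an :class:`Ontology`."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        logger.warning("%s: empty file, returning empty ontology", path)
        return Ontology()
    p = _Parser(path, text)

    classes: dict[str, dict] = {}
    individuals: set[str] = set()
    raw_axioms: list = []
    synonym_pairs: list[tuple[str, str]] = []

    def class_info(cid: str) -> dict:
        return classes.setdefault(cid, {"label": "", "namespace": None})

    while p.peek()[0] is not None:
        kind, value, lineno = p.next()
        if kind == "rparen":  # closing the Ontology(...) block
            continue
        if kind != "name":
            raise OWLSyntaxError(path, lineno, f"expected directive, found {value!r}")
        if value == "Prefix":
            p.expect("lparen")
            while p.peek()[0] != "rparen":
                p.next()
            p.expect("rparen")
            continue
        if value == "Ontology":
            p.expect("lparen")
            if p.peek()[0] == "iri":
                p.next()
            continue
        if value == "Declaration":
            p.expect("lparen")
            dkind = p.expect("name")
            p.expect("lparen")
            name = p.expect("name")
            p.expect("rparen")
            p.expect("rparen")
            if dkind == "Class":
                class_info(name)
            elif dkind == "NamedIndividual":
                individuals.add(_individual_from_token(name))
            elif dkind == "ObjectProperty":
                pass
            elif strict:
                raise OWLSyntaxError(path, lineno, f"unsupported declaration {dkind!r}")
            continue
        if value == "AnnotationAssertion":
            p.expect("lparen")
            prop = p.expect("name")
            subject = p.expect("name")
            k, v, _ = p.next()
            p.expect("rparen")
            literal = v[1:-1].replace('\\"', '"').replace("\\\\", "\\") if k == "string" else v
            if prop == "rdfs:label":
                class_info(subject)["label"] = literal
            elif prop == _NS_ANNOTATION:
                class_info(subject)["namespace"] = literal
            elif prop == ":synonym_id":
                synonym_pairs.append((subject, literal))
            continue
        if value in ("SubClassOf", "EquivalentClasses"):
            p.expect("lparen")
            a = p.parse_expr()
            b = p.parse_expr()
            p.expect("rparen")
            raw_axioms.append(SubClassOf(a, b) if value == "SubClassOf" else EquivalentClasses(a, b))
            continue
        if strict:
            raise OWLSyntaxError(path, lineno, f"unsupported construct {value!r}")
        logger.warning("%s:%d: skipping unsupported construct %r", path, lineno, value)
        _skip_balanced(p)

    onto = Ontology()
    for cid in sorted(classes):
        info = classes[cid]
        ns = info["namespace"] or "phenotype"
        onto.add_class(ClassTerm(cid, info["label"], ns))
    onto.individuals = individuals
    for ax in raw_axioms:
        # plain named is-a
        if isinstance(ax, SubClassOf) and isinstance(ax.sub, Atom) and isinstance(ax.sup, Atom):
            onto.add_subclass_of(ax.sub.id, ax.sup.id)
            continue
        eqdef = parse_eq_definition(ax)
        if eqdef is not None and eqdef.entity_id in onto and \
                onto.get(eqdef.entity_id).namespace == "entity" and \
                eqdef.phenotype_id not in onto.eq_definitions:
            onto.set_eq_definition(eqdef)
            continue
        onto.axioms.append(ax)
    for canon, alias in synonym_pairs:
        onto._synonyms[alias] = canon
    return onto


def _skip_balanced(p: _Parser) -> None:
    depth = 0
    while True:
        kind, _, _ = p.next()
        if kind == "lparen":
            depth += 1
        elif kind == "rparen":
            depth -= 1
            if depth <= 0:
                return
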