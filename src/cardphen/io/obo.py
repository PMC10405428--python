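"""OBO 1.4 subset reader/writer.

The subset covers ``[Term]`` stanzas with ``id``, ``name``, ``namespace``,
``is_a``, ``equivalent_to`` and EQ logical definitions encoded, as compiled
phenotype ontologies do, as genus/differentia ``intersection_of`` lines::

    intersection_of: PATO:0001997            ! the quality (genus)
    intersection_of: characteristic_of CL:0000084
    intersection_of: has_modifier PATO:0000460

The ``has_part`` wrapper of the EQ pattern is implicit in this encoding.
Reading is backed by :mod:`obonet`; a light pre-validation pass reports
syntax errors with their line number first.  Constructs the dialect cannot
encode (subclass-strength EQ definitions, nominals, negation, universal
restrictions of generated axioms) are dropped on write with a logged
manifest; full fidelity needs the OWL functional dialect.
"""

from __future__ import annotations

import io as _io
import logging
import re
from pathlib import Path
from typing import Optional

import obonet

from ..eq import ABNORMAL
from ..expressions import CHARACTERISTIC_OF, HAS_MODIFIER
from ..ontology import ClassTerm, EQDefinition, Ontology, OntologyError

logger = logging.getLogger(__name__)

_TAG_RE = re.compile(r"^[A-Za-z_-]+:\s?.*$")
_PREFIX_NAMESPACE_GUESS = {
    "CL": "entity",
    "UBERON": "entity",
    "ENT": "entity",
    "PATO": "quality",
    "COLL": "collection",
    "CXP": "grouping",
    "CQ": "grouping",
}


class OBOSyntaxError(OntologyError):
    def __init__(self, path, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


def _prevalidate(path, text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("!"):
            continue
        if stripped.startswith("["):
            if not re.fullmatch(r"\[[A-Za-z]+\]", stripped):
                raise OBOSyntaxError(path, lineno, f"malformed stanza header {stripped!r}")
            continue
        if not _TAG_RE.match(stripped):
            raise OBOSyntaxError(path, lineno, f"not a 'tag: value' line: {stripped!r}")


def _infer_namespace(class_id: str, declared: Optional[str], strict: bool) -> str:
    if declared in ("phenotype", "entity", "quality", "collection", "grouping"):
        return declared
    if declared is not None and strict:
        raise OntologyError(
            f"term {class_id}: unknown namespace {declared!r} "
            "(expected phenotype/entity/quality/collection/grouping)"
        )
    guess = _PREFIX_NAMESPACE_GUESS.get(class_id.split(":", 1)[0], "phenotype")
    if declared is not None:
        logger.warning("term %s: namespace %r mapped to %r", class_id, declared, guess)
    return guess


def _parse_intersection_of(class_id: str, values: list[str]) -> EQDefinition:
    quality = entity = None
    modifier = False
    for raw in values:
        parts = raw.split()
        if len(parts) == 1:
            if quality is not None:
                raise OntologyError(f"term {class_id}: two genus lines in intersection_of")
            quality = parts[0]
        elif len(parts) == 2 and parts[0] == CHARACTERISTIC_OF:
            entity = parts[1]
        elif len(parts) == 2 and parts[0] == HAS_MODIFIER:
            modifier = True
        else:
            raise OntologyError(
                f"term {class_id}: unsupported intersection_of line {raw!r}"
            )
    if quality is None or entity is None:
        raise OntologyError(
            f"term {class_id}: intersection_of lacks a quality genus or a "
            f"{CHARACTERISTIC_OF} differentia"
        )
    return EQDefinition(class_id, quality, entity, modifier, "equivalent")


def read_obo(path, strict: bool = True) -> Ontology:
    """Read an ontology from the OBO subset; see module docstring."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        logger.warning("%s: empty file, returning empty ontology", path)
        return Ontology()
    _prevalidate(path, text)
    try:
        graph = obonet.read_obo(_io.StringIO(text))
    except Exception as exc:  # pragma: no cover - obonet failure modes vary
        raise OntologyError(f"{path}: OBO parse failure: {exc}") from exc

    declared = set(
        re.findall(r"^id:\s*(\S+)", text, flags=re.MULTILINE)
    )
    onto = Ontology()
    # obonet materializes edge targets as data-less nodes; only declared
    # stanzas become classes, so dangling references are caught below
    nodes = sorted(
        (n, d) for n, d in graph.nodes(data=True) if n in declared
    )
    for node_id, data in nodes:
        ns = _infer_namespace(node_id, data.get("namespace"), strict)
        onto.add_class(ClassTerm(node_id, data.get("name", ""), ns))
    pending_eq: list[EQDefinition] = []
    equiv_pairs: list[tuple[str, str]] = []
    for node_id, data in nodes:
        for sup in data.get("is_a", []):
            if sup not in onto:
                raise OntologyError(f"{path}: term {node_id} is_a unknown class {sup!r}")
            onto.add_subclass_of(node_id, sup)
        for other in data.get("equivalent_to", []):
            equiv_pairs.append((node_id, other))
        if "intersection_of" in data:
            pending_eq.append(_parse_intersection_of(node_id, data["intersection_of"]))
    for eqdef in pending_eq:
        for cid in (eqdef.quality_id, eqdef.entity_id):
            if cid not in onto:
                raise OntologyError(
                    f"{path}: EQ definition of {eqdef.phenotype_id} references "
                    f"undeclared class {cid!r}"
                )
        onto.set_eq_definition(eqdef)
    if equiv_pairs:
        onto.merge_equivalents(equiv_pairs, strict=strict)
    onto.merge_mutual_subclass_cycles()
    return onto


def write_obo(ontology: Ontology, path, name: str = "cardphen") -> None:
    """Deterministic OBO subset output; unencodable axioms are dropped with a
    logged manifest."""
    path = Path(path)
    lines = ["format-version: 1.4", f"ontology: {name}"]
    direct_edges: dict[str, list[str]] = {}
    for sub, sup in sorted(ontology.graph.edges):
        direct_edges.setdefault(sub, []).append(sup)
    for term in sorted(ontology, key=lambda t: t.id):
        lines += ["", "[Term]", f"id: {term.id}"]
        if term.label:
            lines.append(f"name: {term.label}")
        lines.append(f"namespace: {term.namespace}")
        for syn in sorted(ontology.synonyms_of(term.id) - {term.id}):
            lines.append(f"alt_id: {syn}")
        for sup in sorted(direct_edges.get(term.id, [])):
            lines.append(f"is_a: {sup}")
        eqdef = ontology.eq_definitions.get(term.id)
        if eqdef is not None and eqdef.strength == "equivalent":
            lines.append(f"intersection_of: {eqdef.quality_id}")
            lines.append(f"intersection_of: {CHARACTERISTIC_OF} {eqdef.entity_id}")
            if eqdef.has_abnormal_modifier:
                lines.append(f"intersection_of: {HAS_MODIFIER} {ABNORMAL}")
        elif eqdef is not None:
            logger.warning(
                "OBO dialect cannot encode subclass-strength EQ definition of %s; dropped",
                term.id,
            )
    if ontology.axioms:
        logger.warning(
            "OBO dialect dropped %d general axioms (nominals/negation/universal "
            "restrictions need the OWL functional dialect)",
            len(ontology.axioms),
        )
    path.write_text("\n".join(lines) + "\n")
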