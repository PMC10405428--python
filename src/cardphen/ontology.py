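"""In-memory ontology substrate: classes, is-a edges, and their deductive closure.

Only the subsumption (is-a) fragment is modeled, plus the specific axiom
patterns used for entity--quality (EQ) phenotype definitions and collection
classes.  Identifiers are opaque CURIE-style strings (``PREFIX:LOCAL``); no
IRI resolution is performed.  Classes declared equivalent (via mapping files
or mutual subclass assertions) are merged into one canonical node that keeps
every merged id as a synonym.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import networkx as nx

logger = logging.getLogger(__name__)

#: Allowed term namespaces.
NAMESPACES = ("phenotype", "entity", "quality", "collection", "grouping")


class OntologyError(ValueError):
    """Malformed ontology input (duplicate ids, dangling references, ...)."""


class CycleError(OntologyError):
    """A subsumption cycle that is not a declared equivalence."""

    def __init__(self, members: Iterable[str]):
        self.members = sorted(members)
        super().__init__(
            "subsumption cycle that is not a declared equivalence: "
            + " -> ".join(self.members)
        )


@dataclass(frozen=True)
class ClassTerm:
    """A named ontology class.

    ``namespace`` records the role the class plays (affected entity, PATO-style
    quality, phenotype, generated collection or grouping class) and is fixed at
    load/creation time.
    """

    id: str
    label: str = ""
    namespace: str = "phenotype"

    def __post_init__(self) -> None:
        if not self.id or self.id.count(":") != 1:
            raise OntologyError(
                f"class id must contain exactly one colon separator: {self.id!r}"
            )
        if self.namespace not in NAMESPACES:
            raise OntologyError(f"unknown namespace {self.namespace!r} for {self.id}")


@dataclass(frozen=True)
class EQDefinition:
    """The logical definition of one phenotype class in the EQ pattern.

    Represents ``P {=|<=} has_part some (Q and characteristic_of some E
    [and has_modifier some abnormal])`` where Q is a quality class and E an
    entity (or collection) class.  ``strength`` distinguishes a full
    (equivalence) definition from a mere necessary condition (subclass).
    """

    phenotype_id: str
    quality_id: str
    entity_id: str
    has_abnormal_modifier: bool = True
    strength: str = "equivalent"  # "equivalent" | "subclass"

    def __post_init__(self) -> None:
        if self.strength not in ("equivalent", "subclass"):
            raise OntologyError(f"bad definition strength {self.strength!r}")


class SubsumptionGraph:
    """A set of classes with ordered (sub, super) subsumption edges.

    ``closure()`` returns the smallest reflexive-transitive supergraph; it is
    idempotent.  The graph must be acyclic (equivalence cycles are merged at
    load time by :class:`Ontology`).
    """

    def __init__(
        self,
        nodes: Iterable[str] = (),
        edges: Iterable[tuple[str, str]] = (),
        allow_cycles: bool = False,
    ):
        self._g = nx.DiGraph()
        self._g.add_nodes_from(nodes)
        self._g.add_edges_from(edges)
        #: classification outputs may contain inferred equivalences (mutual
        #: subsumption); asserted input hierarchies may not
        self.allow_cycles = allow_cycles
        self._closed: Optional[SubsumptionGraph] = None

    # -- basic container protocol -------------------------------------------------
    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return set(self._g.edges)

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def add_node(self, node: str) -> None:
        self._g.add_node(node)
        self._closed = None

    def add_edge(self, sub: str, sup: str) -> None:
        self._g.add_edge(sub, sup)
        self._closed = None

    # -- closure ------------------------------------------------------------------
    def _check_acyclic(self) -> None:
        for scc in nx.strongly_connected_components(self._g):
            if len(scc) > 1:
                raise CycleError(scc)

    def closure(self) -> "SubsumptionGraph":
        """Reflexive-transitive closure; raises :class:`CycleError` on cycles."""
        if self._closed is None:
            if not self.allow_cycles:
                self._check_acyclic()
            closed = nx.transitive_closure(self._g, reflexive=True)
            out = SubsumptionGraph()
            out._g = closed
            out._closed = out
            self._closed = out
        return self._closed

    def ancestors(self, class_id: str) -> set[str]:
        """All ids ``a`` with ``class_id [= a`` in the closure, self included."""
        if class_id not in self._g:
            raise OntologyError(f"unknown class id {class_id!r}")
        c = self.closure()
        return {class_id} | set(c._g.successors(class_id))

    def descendants(self, class_id: str) -> set[str]:
        if class_id not in self._g:
            raise OntologyError(f"unknown class id {class_id!r}")
        c = self.closure()
        return {class_id} | set(c._g.predecessors(class_id))

    def entails(self, sub_id: str, super_id: str) -> bool:
        """Membership test ``sub [= super`` on the closed graph (reflexive)."""
        for cid in (sub_id, super_id):
            if cid not in self._g:
                raise OntologyError(f"unknown class id {cid!r}")
        if sub_id == super_id:
            return True
        return self.closure()._g.has_edge(sub_id, super_id)

    def sorted_edges(self) -> list[tuple[str, str]]:
        return sorted(self._g.edges)

    def copy(self) -> "SubsumptionGraph":
        return SubsumptionGraph(self.nodes, self.edges)


def transitive_closure(graph: SubsumptionGraph) -> SubsumptionGraph:
    """Functional alias for :meth:`SubsumptionGraph.closure`."""
    return graph.closure()


class Ontology:
    """Classes, is-a edges, EQ definitions and generated axioms.

    The is-a graph is kept per namespace-agnostic; convenience projections
    (``entity_graph``, ``quality_graph``, ``phenotype_graph``) restrict it to
    one namespace.  Synonym ids created by equivalence merging resolve through
    :meth:`canonical`.
    """

    def __init__(self) -> None:
        self.terms: dict[str, ClassTerm] = {}
        self._synonyms: dict[str, str] = {}
        self.graph = SubsumptionGraph()
        self.eq_definitions: dict[str, EQDefinition] = {}
        #: general axioms (expression trees) that fall outside the is-a/EQ model
        self.axioms: list = []
        self.individuals: set[str] = set()

    # -- class management ---------------------------------------------------------
    def canonical(self, class_id: str) -> str:
        return self._synonyms.get(class_id, class_id)

    def synonyms_of(self, class_id: str) -> set[str]:
        canon = self.canonical(class_id)
        return {canon} | {a for a, c in self._synonyms.items() if c == canon}

    def __contains__(self, class_id: str) -> bool:
        return self.canonical(class_id) in self.terms

    def __iter__(self) -> Iterator[ClassTerm]:
        return iter(self.terms.values())

    def add_class(self, term: ClassTerm) -> "Ontology":
        if term.id in self.terms or term.id in self._synonyms:
            raise OntologyError(f"duplicate class id {term.id!r}")
        self.terms[term.id] = term
        self.graph.add_node(term.id)
        return self

    def get(self, class_id: str) -> ClassTerm:
        canon = self.canonical(class_id)
        if canon not in self.terms:
            raise OntologyError(f"unknown class id {class_id!r}")
        return self.terms[canon]

    def add_subclass_of(self, sub: str, sup: str) -> None:
        self.graph.add_edge(self.canonical(sub), self.canonical(sup))

    def set_eq_definition(self, eqdef: EQDefinition) -> None:
        pid = self.canonical(eqdef.phenotype_id)
        if pid in self.eq_definitions:
            raise OntologyError(f"phenotype {pid} already has an EQ definition")
        self.eq_definitions[pid] = replace(
            eqdef,
            phenotype_id=pid,
            quality_id=self.canonical(eqdef.quality_id),
            entity_id=self.canonical(eqdef.entity_id),
        )

    # -- equivalence merging ------------------------------------------------------
    def merge_equivalents(self, pairs: Iterable[tuple[str, str]], strict: bool = True) -> int:
        """Merge declared-equivalent classes into canonical nodes.

        The lexicographically smallest id of each group becomes canonical; the
        rest become synonyms.  Returns the number of merges performed.  Unknown
        ids raise in strict mode and are skipped (with a warning) otherwise.
        """
        # union-find over canonicalized ids
        parent: dict[str, str] = {}

        def root(x: str) -> str:
            while parent.get(x, x) != x:
                parent[x] = parent.get(parent[x], parent[x])
                x = parent[x]
            return x

        n_merged = 0
        for a, b in pairs:
            a, b = self.canonical(a), self.canonical(b)
            missing = [x for x in (a, b) if x not in self.terms]
            if missing:
                msg = f"equivalence references unknown id(s): {missing}"
                if strict:
                    raise OntologyError(msg)
                logger.warning("%s -- skipped", msg)
                continue
            ra, rb = root(a), root(b)
            if ra != rb:
                lo, hi = sorted((ra, rb))
                parent[hi] = lo
                n_merged += 1
        clusters: dict[str, set[str]] = {}
        for x in list(parent) + [v for v in parent.values()]:
            clusters.setdefault(root(x), set()).add(x)
        for canon, members in clusters.items():
            members.discard(canon)
            for alias in members:
                self._absorb(alias, canon)
        return n_merged

    def _absorb(self, alias: str, canon: str) -> None:
        """Redirect ``alias`` onto ``canon``: edges, definitions, synonyms."""
        g = self.graph
        for sub, sup in list(g.edges):
            if alias in (sub, sup):
                new = (canon if sub == alias else sub, canon if sup == alias else sup)
                if new[0] != new[1]:
                    g.add_edge(*new)
        ng = SubsumptionGraph(
            (n for n in g.nodes if n != alias),
            ((s, t) for s, t in g.edges if alias not in (s, t)),
        )
        self.graph = ng
        term = self.terms.pop(alias)
        if not self.terms[canon].label and term.label:
            self.terms[canon] = replace(self.terms[canon], label=term.label)
        self._synonyms[alias] = canon
        aldef = self.eq_definitions.pop(alias, None)
        if aldef is not None and canon not in self.eq_definitions:
            self.eq_definitions[canon] = replace(aldef, phenotype_id=canon)

    def merge_mutual_subclass_cycles(self) -> int:
        """Merge 2-way mutual subclass assertions; other cycles are errors."""
        g = nx.DiGraph(self.graph.edges)
        g.add_nodes_from(self.graph.nodes)
        merged = 0
        for scc in list(nx.strongly_connected_components(g)):
            if len(scc) == 1:
                continue
            # a declared equivalence shows up as a clique of mutual edges
            if all(g.has_edge(a, b) for a in scc for b in scc if a != b):
                members = sorted(scc)
                self.merge_equivalents([(members[0], m) for m in members[1:]])
                merged += len(members) - 1
            else:
                raise CycleError(scc)
        return merged

    # -- namespace projections ----------------------------------------------------
    def namespace_graph(self, namespace: str) -> SubsumptionGraph:
        keep = {t.id for t in self.terms.values() if t.namespace == namespace}
        return SubsumptionGraph(
            keep, ((s, t) for s, t in self.graph.edges if s in keep and t in keep)
        )

    def entity_graph(self) -> SubsumptionGraph:
        return self.namespace_graph("entity")

    def quality_graph(self) -> SubsumptionGraph:
        return self.namespace_graph("quality")

    def phenotype_graph(self) -> SubsumptionGraph:
        return self.namespace_graph("phenotype")

    def ids_in_namespace(self, namespace: str) -> set[str]:
        return {t.id for t in self.terms.values() if t.namespace == namespace}

    # -- misc ----------------------------------------------------------------------
    def copy(self) -> "Ontology":
        out = Ontology()
        out.terms = dict(self.terms)
        out._synonyms = dict(self._synonyms)
        out.graph = self.graph.copy()
        out.eq_definitions = dict(self.eq_definitions)
        out.axioms = list(self.axioms)
        out.individuals = set(self.individuals)
        return out


def add_class(ontology: Ontology, term: ClassTerm) -> Ontology:
    """Functional wrapper around :meth:`Ontology.add_class`."""
    return ontology.add_class(term)


def ancestors(graph: SubsumptionGraph, class_id: str) -> set[str]:
    """Functional wrapper around :meth:`SubsumptionGraph.ancestors`."""
    return graph.ancestors(class_id)
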