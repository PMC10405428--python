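"""Seeded generators for toy entity trees, cardinality phenotype ontologies
and annotated gene/disease corpora with planted associations.

The corpus generator plants one true gene per disease (sharing phenotypes of
the disease's cell type, or of that type's direct ancestor) and builds decoy
genes that carry phenotypes of a *sibling* subtype of a disease's cell type.
Under the plain EQ classification the sibling phenotype and the disease
phenotype meet at the shared parent phenotype class, so decoys look similar
to the disease; under the collection-based classification amount phenotypes
of distinct cell types are incomparable, so the confound disappears.  This is
exactly the "NK T cell vs T cell" topology that motivates the rewrite, turned
into a testable benchmark.

All randomness flows from ``FixtureSpec.seed``; identical specs give
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .eq import (
    ABNORMAL,
    ABSENT,
    AMOUNT,
    CardinalityConfig,
    DECREASED_AMOUNT,
    INCREASED_AMOUNT,
    QUALITY_ROOT,
)
from .evaluate import AssociationTruth
from .ontology import ClassTerm, EQDefinition, Ontology, OntologyError
from .similarity import AnnotationCorpus

ENTITY_PREFIX = "ENT"
_QUALITY_TAGS = {
    INCREASED_AMOUNT: ("inc", "increased"),
    DECREASED_AMOUNT: ("dec", "decreased"),
    ABSENT: ("abs", "absent"),
}
_QUALITY_LABELS = {
    QUALITY_ROOT: "quality",
    AMOUNT: "amount",
    INCREASED_AMOUNT: "increased amount",
    DECREASED_AMOUNT: "decreased amount",
    ABSENT: "absent",
    ABNORMAL: "abnormal",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults describe the benchmark conditions: a depth-2 ternary cell-type
    tree (9 leaf types under 3 parents), all three cardinality qualities,
    6 diseases with 2-phenotype profiles, 30 genes, every decoy confounded
    with a sibling subtype, and 10% annotation noise.
    """

    depth: int = 2
    branching: int = 3
    qualities: tuple[str, ...] = (INCREASED_AMOUNT, DECREASED_AMOUNT, ABSENT)
    n_genes: int = 30
    n_diseases: int = 6
    annotations_per_profile: int = 2
    confound_rate: float = 1.0
    noise_rate: float = 0.1
    seed: int = 0

    def config(self) -> CardinalityConfig:
        return CardinalityConfig(entity_prefixes=frozenset({ENTITY_PREFIX}))

    def validate(self, need_siblings: bool = False) -> None:
        if self.depth < 1 or self.branching < 1:
            raise OntologyError("depth and branching must be positive")
        if need_siblings and (self.depth < 2 or self.branching < 2):
            raise OntologyError(
                "confound scenarios need depth >= 2 and branching >= 2"
            )


def _entity_id(path: str) -> str:
    return f"{ENTITY_PREFIX}:R{path}"


def generate_entity_ontology(spec: FixtureSpec) -> Ontology:
    """A rooted ``branching``-ary tree of cell-type-like classes."""
    spec.validate()
    onto = Ontology()
    onto.add_class(ClassTerm(_entity_id(""), "cell", "entity"))
    frontier = [""]
    for _ in range(spec.depth):
        nxt = []
        for path in frontier:
            for k in range(spec.branching):
                child = path + str(k)
                onto.add_class(
                    ClassTerm(_entity_id(child), f"cell type R{child}", "entity")
                )
                onto.add_subclass_of(_entity_id(child), _entity_id(path))
                nxt.append(child)
        frontier = nxt
    return onto


def phenotype_id(entity_id: str, quality_id: str) -> str:
    tag = _QUALITY_TAGS[quality_id][0]
    return f"PHE:{entity_id.split(':', 1)[1]}_{tag}"


def _add_quality_hierarchy(onto: Ontology, qualities: tuple[str, ...]) -> None:
    for qid in (QUALITY_ROOT, AMOUNT, ABNORMAL, *qualities):
        if qid not in onto:
            onto.add_class(ClassTerm(qid, _QUALITY_LABELS.get(qid, qid), "quality"))
    onto.add_subclass_of(AMOUNT, QUALITY_ROOT)
    onto.add_subclass_of(ABNORMAL, QUALITY_ROOT)
    for qid in qualities:
        onto.add_subclass_of(qid, AMOUNT)


def generate_phenotype_ontology(entity_ontology: Ontology, spec: FixtureSpec) -> Ontology:
    """One EQ-defined phenotype class per (entity, quality) pair, plus an
    embedded minimal quality hierarchy."""
    for qid in spec.qualities:
        if qid not in _QUALITY_TAGS:
            raise OntologyError(f"unsupported fixture quality {qid!r}")
    onto = entity_ontology.copy()
    _add_quality_hierarchy(onto, spec.qualities)
    for term in sorted(entity_ontology, key=lambda t: t.id):
        for qid in spec.qualities:
            pid = phenotype_id(term.id, qid)
            word = _QUALITY_TAGS[qid][1]
            label = (
                f"absent {term.label}s" if qid == ABSENT
                else f"{word} {term.label} number"
            )
            onto.add_class(ClassTerm(pid, label, "phenotype"))
            onto.set_eq_definition(
                EQDefinition(pid, qid, term.id, True, "equivalent")
            )
    return onto


def generate_annotated_corpus(
    phenotype_ontology: Ontology, spec: FixtureSpec
) -> tuple[AnnotationCorpus, AnnotationCorpus, AssociationTruth]:
    """Gene and disease corpora with planted truth and the sibling confound."""
    spec.validate(need_siblings=spec.confound_rate > 0)
    app = spec.annotations_per_profile
    if app < 1 or app > len(spec.qualities):
        raise OntologyError(
            f"profile size {app} exceeds the {len(spec.qualities)} phenotype "
            "classes available per cell type"
        )
    rng = np.random.default_rng(spec.seed)
    entities = sorted(phenotype_ontology.ids_in_namespace("entity"))
    depth_of = {e: len(e.split(":R", 1)[1]) for e in entities}
    leaves = [e for e in entities if depth_of[e] == spec.depth]
    parent_of = {e: _entity_id(e.split(":R", 1)[1][:-1]) for e in entities if depth_of[e] > 0}
    all_phenotypes = sorted(phenotype_ontology.eq_definitions)

    def siblings(leaf: str) -> list[str]:
        p = parent_of[leaf]
        return [l for l in leaves if parent_of[l] == p and l != leaf]

    genes, diseases = AnnotationCorpus(), AnnotationCorpus()
    disease_entity: dict[str, str] = {}
    disease_qualities: dict[str, list[str]] = {}
    truth_pairs = set()
    for i in range(spec.n_diseases):
        did = f"DIS:{i:04d}"
        e = leaves[i % len(leaves)]
        qs = [str(q) for q in rng.choice(spec.qualities, size=app, replace=False)]
        disease_entity[did] = e
        disease_qualities[did] = qs
        for q in qs:
            diseases.add(did, phenotype_id(e, q), "disease")
        gid = f"GEN:{i:04d}"
        # true gene: the same phenotype classes, except that one absence
        # annotation (if any) is recorded at the parent cell type -- absence
        # of the supertype implies absence of the subtype, so the pair stays
        # tightly related under either classification
        lifted = False
        for q in qs:
            ent = e
            if q == ABSENT and not lifted and len(qs) > 1:
                ent, lifted = parent_of[e], True
            genes.add(gid, phenotype_id(ent, q), "gene")
        truth_pairs.add((gid, did))

    used_leaves = set(disease_entity.values())
    free_leaves = [l for l in leaves if l not in used_leaves] or leaves
    disease_ids = sorted(disease_entity)
    for i in range(spec.n_diseases, spec.n_genes):
        gid = f"GEN:{i:04d}"
        if rng.random() < spec.confound_rate:
            did = disease_ids[int(rng.integers(len(disease_ids)))]
            sibs = siblings(disease_entity[did])
            ent = sibs[int(rng.integers(len(sibs)))]
            qs = disease_qualities[did]
        else:
            ent = free_leaves[int(rng.integers(len(free_leaves)))]
            qs = [str(q) for q in rng.choice(spec.qualities, size=app, replace=False)]
        for q in qs:
            genes.add(gid, phenotype_id(ent, q), "gene")

    if spec.noise_rate > 0:
        for corpus in (genes, diseases):
            for eid in sorted(corpus.annotations):
                n_extra = int(rng.binomial(len(corpus.annotations[eid]), spec.noise_rate))
                for _ in range(n_extra):
                    corpus.annotations[eid].add(
                        all_phenotypes[int(rng.integers(len(all_phenotypes)))]
                    )
    return genes, diseases, AssociationTruth.from_pairs(truth_pairs)


def generate_fixture(spec: FixtureSpec):
    """Convenience: entity tree -> phenotype ontology -> annotated corpora."""
    entity = generate_entity_ontology(spec)
    pheno = generate_phenotype_ontology(entity, spec)
    genes, diseases, truth = generate_annotated_corpus(pheno, spec)
    return pheno, genes, diseases, truth
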