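import numpy as np
import pytest

import cardphen as cp
from cardphen.eq import ABSENT, AMOUNT, DECREASED_AMOUNT, INCREASED_AMOUNT
from cardphen.ontology import ClassTerm, EQDefinition, Ontology


@pytest.fixture()
def demo():
    """The frozen NK T cell / T cell miniature ontology."""
    return cp.load_demo_ontology()


@pytest.fixture()
def config():
    return cp.CardinalityConfig()


@pytest.fixture()
def entity_chain():
    """NK T cell [= T cell [= lymphocyte as a bare entity ontology."""
    onto = Ontology()
    for cid, label in [
        ("CL:0000542", "lymphocyte"),
        ("CL:0000084", "T cell"),
        ("CL:0000814", "mature NK T cell"),
    ]:
        onto.add_class(ClassTerm(cid, label, "entity"))
    onto.add_subclass_of("CL:0000084", "CL:0000542")
    onto.add_subclass_of("CL:0000814", "CL:0000084")
    return onto


def make_random_dag(seed: int, n: int = 30) -> Ontology:
    """Random entity DAG: edges only from higher to lower index keeps it acyclic."""
    rng = np.random.default_rng(seed)
    onto = Ontology()
    ids = [f"ENT:N{i:03d}" for i in range(n)]
    for cid in ids:
        onto.add_class(ClassTerm(cid, cid, "entity"))
    for i in range(1, n):
        for j in rng.choice(i, size=min(i, int(rng.integers(0, 3))), replace=False):
            onto.add_subclass_of(ids[i], ids[int(j)])
    return onto


def make_random_phenotype_fixture(seed: int, asserted_edges: bool = True):
    """Randomized cardinality-phenotype ontology for classifier testing.

    Varies tree shape and quality set, subsamples the phenotype classes,
    demotes some definitions to subclass strength, drops the abnormal
    modifier on some, and asserts a few extra is-a edges among phenotypes.
    """
    rng = np.random.default_rng(seed)
    depth = int(rng.integers(2, 4))
    branching = int(rng.integers(2, 4))
    n_q = int(rng.integers(1, 4))
    qualities = tuple(
        str(q) for q in rng.choice(
            [INCREASED_AMOUNT, DECREASED_AMOUNT, ABSENT], size=n_q, replace=False
        )
    )
    spec = cp.FixtureSpec(depth=depth, branching=branching, qualities=qualities, seed=seed)
    entity = cp.generate_entity_ontology(spec)
    pheno = cp.generate_phenotype_ontology(entity, spec)
    pids = sorted(pheno.eq_definitions)
    keep = set(
        str(p) for p in rng.choice(pids, size=min(len(pids), 40), replace=False)
    )
    for pid in pids:
        if pid not in keep:
            del pheno.eq_definitions[pid]
            del pheno.terms[pid]
    from dataclasses import replace as dc_replace

    for pid in sorted(pheno.eq_definitions):
        if rng.random() < 0.2:
            pheno.eq_definitions[pid] = dc_replace(
                pheno.eq_definitions[pid], strength="subclass"
            )
        if rng.random() < 0.2:
            pheno.eq_definitions[pid] = dc_replace(
                pheno.eq_definitions[pid], has_abnormal_modifier=False
            )
    kept = sorted(pheno.eq_definitions)
    for _ in range(int(rng.integers(0, 4)) if asserted_edges else 0):
        i, j = sorted(rng.choice(len(kept), size=2, replace=False))
        if i != j:
            pheno.add_subclass_of(kept[int(j)], kept[int(i)])
    return pheno, spec.config()


def nonreflexive(graph) -> set:
    return {e for e in graph.closure().edges if e[0] != e[1]}
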