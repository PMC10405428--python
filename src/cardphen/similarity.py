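"""Information content, Resnik similarity and best-match-average profiles.

IC is corpus-based: each annotated entity's profile is propagated to all
ancestors in the hierarchy in use, ``p(class)`` is the fraction of annotated
entities (genes and diseases pooled) whose propagated profile contains the
class, and ``IC = -log2 p`` (bits).  Classes never used after propagation
have no IC entry and are excluded as common-ancestor candidates, so unused
classes cannot contribute unbounded similarity.

Resnik similarity of two classes is the IC of their most informative common
ancestor (MICA); profile similarity is the two-sided best-match average

    sim(g, d) = sum_i max_j sim(g_i, d_j) / (2 g_n)
              + sum_j max_i sim(d_j, g_i) / (2 d_n)
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .ontology import OntologyError, SubsumptionGraph

logger = logging.getLogger(__name__)


@dataclass
class AnnotationCorpus:
    """Annotated entities (genes/diseases) with their phenotype-class profiles."""

    annotations: dict[str, set[str]] = field(default_factory=dict)
    entity_kind: dict[str, str] = field(default_factory=dict)  # id -> gene|disease

    def add(self, entity_id: str, class_id: str, kind: str = "gene") -> None:
        self.annotations.setdefault(entity_id, set()).add(class_id)
        self.entity_kind.setdefault(entity_id, kind)

    def drop_empty(self) -> int:
        empty = [e for e, p in self.annotations.items() if not p]
        for e in empty:
            logger.warning("dropping entity %s with empty profile", e)
            del self.annotations[e]
            self.entity_kind.pop(e, None)
        return len(empty)

    def restricted(self, keep: set[str]) -> "AnnotationCorpus":
        """Profiles intersected with ``keep``; entities emptied out are dropped."""
        out = AnnotationCorpus()
        for e, prof in self.annotations.items():
            kept = prof & keep
            if kept:
                out.annotations[e] = set(kept)
                out.entity_kind[e] = self.entity_kind.get(e, "gene")
        return out

    def merged_with(self, other: "AnnotationCorpus") -> "AnnotationCorpus":
        out = AnnotationCorpus()
        for src in (self, other):
            for e, prof in src.annotations.items():
                out.annotations.setdefault(e, set()).update(prof)
                out.entity_kind.setdefault(e, src.entity_kind.get(e, "gene"))
        return out

    def __len__(self) -> int:
        return len(self.annotations)


@dataclass
class ICTable:
    ic: dict[str, float]
    corpus_size: int

    def __getitem__(self, class_id: str) -> float:
        return self.ic[class_id]

    def get(self, class_id: str, default: Optional[float] = None):
        return self.ic.get(class_id, default)

    def __contains__(self, class_id: str) -> bool:
        return class_id in self.ic


def compute_ic(corpus: AnnotationCorpus, hierarchy: SubsumptionGraph) -> ICTable:
    """Corpus IC table over a (closed) hierarchy; see module docstring."""
    if len(corpus) == 0:
        raise OntologyError("empty annotation corpus")
    counts: dict[str, int] = {}
    for entity, profile in corpus.annotations.items():
        propagated: set[str] = set()
        for cid in profile:
            if cid not in hierarchy:
                raise OntologyError(
                    f"annotation of {entity} references unknown class {cid!r}"
                )
            propagated |= hierarchy.ancestors(cid)
        for cid in propagated:
            counts[cid] = counts.get(cid, 0) + 1
    n = len(corpus)
    ic = {cid: -math.log2(c / n) for cid, c in counts.items()}
    return ICTable(ic=ic, corpus_size=n)


def resnik(
    a: str, b: str, ic: ICTable, hierarchy: SubsumptionGraph
) -> float:
    """IC of the most informative common ancestor with an IC entry; 0 if none."""
    common = hierarchy.ancestors(a) & hierarchy.ancestors(b)
    best = 0.0
    for cid in common:
        v = ic.get(cid)
        if v is not None and v > best:
            best = v
    return best


def bma(
    profile_a: Iterable[str],
    profile_b: Iterable[str],
    ic: ICTable,
    hierarchy: SubsumptionGraph,
) -> float:
    """Two-sided best-match average of Resnik similarities (see module docstring)."""
    pa, pb = sorted(set(profile_a)), sorted(set(profile_b))
    if not pa or not pb:
        raise OntologyError("best-match average requires two non-empty profiles")
    sim = {
        (x, y): resnik(x, y, ic, hierarchy) for x in pa for y in pb
    }
    left = sum(max(sim[(x, y)] for y in pb) for x in pa) / (2 * len(pa))
    right = sum(max(sim[(x, y)] for x in pa) for y in pb) / (2 * len(pb))
    return left + right


def pairwise_bma(
    gene_corpus: AnnotationCorpus,
    disease_corpus: AnnotationCorpus,
    ic: ICTable,
    hierarchy: SubsumptionGraph,
) -> dict[tuple[str, str], float]:
    """BMA score for every (gene, disease) pair in the two corpora."""
    out: dict[tuple[str, str], float] = {}
    for gene in sorted(gene_corpus.annotations):
        gp = gene_corpus.annotations[gene]
        for disease in sorted(disease_corpus.annotations):
            out[(gene, disease)] = bma(
                gp, disease_corpus.annotations[disease], ic, hierarchy
            )
    return out
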