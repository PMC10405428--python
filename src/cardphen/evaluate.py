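"""Gene ranking per disease and ROCAUC evaluation of known associations.

For each disease every gene is ranked by descending profile similarity
(average ranks on ties).  The primary metric is the pooled (micro-average)
ROCAUC over all (disease, gene) pairs, scored by within-disease rank: it
equals the probability that a true association outranks a false one, i.e. the
normalized Mann-Whitney U statistic with ties counted one half.  A
macro-average (mean per-disease AUC) is reported alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from scipy.stats import rankdata

from .ontology import OntologyError, SubsumptionGraph
from .similarity import AnnotationCorpus, compute_ic, pairwise_bma

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssociationTruth:
    pairs: frozenset[tuple[str, str]]  # (gene id, disease id)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AssociationTruth":
        return cls(frozenset(pairs))

    def genes_of(self, disease_id: str) -> set[str]:
        return {g for g, d in self.pairs if d == disease_id}


@dataclass
class EvaluationResult:
    mode: str
    per_disease_ranks: dict[str, list[float]]
    rocauc: float
    macro_rocauc: float
    n_diseases: int
    n_genes: int


def rank_genes(scores: Mapping[str, float]) -> dict[str, float]:
    """Rank genes by descending score; ties get the average rank (1 = best)."""
    genes = sorted(scores)
    vals = np.array([scores[g] for g in genes], dtype=float)
    ranks = rankdata(-vals, method="average")
    return dict(zip(genes, ranks.tolist()))


def roc_auc_from_scores(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the normalized rank-sum (Mann-Whitney) statistic, ties = 1/2."""
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise OntologyError("ROCAUC needs at least one positive and one negative")
    r = rankdata(np.asarray(scores, dtype=float), method="average")
    u = r[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc(
    rankings: Mapping[str, Mapping[str, float]], truth: AssociationTruth
) -> float:
    """Pooled AUC over all (disease, gene) pairs, scored by negative rank."""
    scores, labels = [], []
    for disease, ranks in rankings.items():
        positives = truth.genes_of(disease)
        for gene, rank in ranks.items():
            scores.append(-rank)
            labels.append(gene in positives)
    return roc_auc_from_scores(np.array(scores), np.array(labels))


def evaluate(
    gene_corpus: AnnotationCorpus,
    disease_corpus: AnnotationCorpus,
    truth: AssociationTruth,
    hierarchy: SubsumptionGraph,
    mode: str = "original",
    restrict_to: Optional[set[str]] = None,
) -> EvaluationResult:
    """IC -> BMA -> per-disease ranking -> pooled ROCAUC.

    ``restrict_to`` keeps only the given phenotype classes (e.g. cardinality
    phenotypes) in every profile; entities whose profile empties out are
    dropped, mirroring an evaluation on entities annotated with at least one
    such phenotype.
    """
    if restrict_to is not None:
        gene_corpus = gene_corpus.restricted(restrict_to)
        disease_corpus = disease_corpus.restricted(restrict_to)
        logger.info(
            "restriction kept %d genes, %d diseases",
            len(gene_corpus), len(disease_corpus),
        )
    union = gene_corpus.merged_with(disease_corpus)
    union.drop_empty()
    ic = compute_ic(union, hierarchy)
    sims = pairwise_bma(gene_corpus, disease_corpus, ic, hierarchy)
    genes = sorted(gene_corpus.annotations)
    rankings: dict[str, dict[str, float]] = {}
    for disease in sorted(disease_corpus.annotations):
        rankings[disease] = rank_genes({g: sims[(g, disease)] for g in genes})
    evaluable = {
        d: r for d, r in rankings.items()
        if any(g in gene_corpus.annotations for g in truth.genes_of(d))
    }
    pooled = roc_auc(evaluable, truth)
    per_auc = []
    for d, r in evaluable.items():
        pos = truth.genes_of(d)
        scores = np.array([-r[g] for g in genes])
        labels = np.array([g in pos for g in genes])
        if labels.any() and not labels.all():
            per_auc.append(roc_auc_from_scores(scores, labels))
    per_disease_ranks = {
        d: sorted(r[g] for g in truth.genes_of(d) if g in r)
        for d, r in evaluable.items()
    }
    return EvaluationResult(
        mode=mode,
        per_disease_ranks=per_disease_ranks,
        rocauc=pooled,
        macro_rocauc=float(np.mean(per_auc)) if per_auc else float("nan"),
        n_diseases=len(evaluable),
        n_genes=len(genes),
    )
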