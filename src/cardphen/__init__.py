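"""cardphen: collection-based rewriting of cardinality phenotypes.

Phenotype ontologies define classes such as *decreased T cell number* with
entity--quality (EQ) axioms over the member cell type, which makes the
phenotype of a subtype (decreased NK T cell number) a subclass of the
phenotype of the supertype -- an inference that does not reflect the biology,
and that inverts for absence phenotypes.  This package detects such
cardinality phenotypes, redefines them over maximal-collection classes,
computes the revised entailed hierarchy, and quantifies the effect on
phenotype-similarity-based gene--disease ranking.
"""

from importlib import resources

from .ontology import (
    ClassTerm,
    CycleError,
    EQDefinition,
    Ontology,
    OntologyError,
    SubsumptionGraph,
    transitive_closure,
)
from .eq import (
    CardinalityConfig,
    detect_cardinality_phenotypes,
    is_cardinality_phenotype,
    parse_eq_definition,
)
from .rewrite import (
    CollectionClass,
    GroupingClass,
    RewrittenAxioms,
    RewrittenOntology,
    make_collection_class,
    make_grouping_classes,
    materialize_partonomy,
    reconstruct_rewritten,
    rewrite_ontology,
    rewrite_phenotype,
)
from .classify import (
    classify_original,
    classify_original_ontology,
    classify_revised,
    entails,
    naive_saturation_oracle,
)
from .similarity import AnnotationCorpus, ICTable, bma, compute_ic, resnik
from .evaluate import (
    AssociationTruth,
    EvaluationResult,
    evaluate,
    rank_genes,
    roc_auc,
    roc_auc_from_scores,
)
from .simulate import (
    FixtureSpec,
    generate_annotated_corpus,
    generate_entity_ontology,
    generate_fixture,
    generate_phenotype_ontology,
)

__version__ = "0.1.0"


def load_demo_ontology() -> Ontology:
    """The frozen NK T cell / T cell miniature ontology shipped with the package."""
    from .io.obo import read_obo

    with resources.as_file(
        resources.files("cardphen") / "fixtures" / "nk_t_cell_demo.obo"
    ) as p:
        return read_obo(p)


__all__ = [name for name in dir() if not name.startswith("_")]
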