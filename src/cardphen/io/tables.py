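"""Simplified 2-column TSV readers for annotations, associations and mappings.

Real association files (e.g. the MGI and HP report formats) are multi-column;
a one-line ``cut -f`` extraction converts them to the shapes read here.  All
readers allow ``#`` comment lines, deduplicate with a logged count, and
report malformed lines with their line number.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterator, Optional

from ..evaluate import AssociationTruth
from ..ontology import Ontology, OntologyError
from ..similarity import AnnotationCorpus

logger = logging.getLogger(__name__)


class TableFormatError(OntologyError):
    def __init__(self, path, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"{path}:{lineno}: {message}")


def _rows(path) -> Iterator[tuple[int, list[str]]]:
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 2:
            raise TableFormatError(
                path, lineno, f"expected 2 tab-separated columns, found {len(fields)}"
            )
        yield lineno, [f.strip() for f in fields]


def read_annotations(
    path, ontology: Optional[Ontology] = None, kind: str = "gene"
) -> AnnotationCorpus:
    """Entity-to-phenotype-class annotations (entity id, class id)."""
    corpus = AnnotationCorpus()
    n_dup = 0
    for lineno, (entity, class_id) in _rows(path):
        if ontology is not None:
            if class_id not in ontology:
                raise TableFormatError(path, lineno, f"unknown phenotype class {class_id!r}")
            class_id = ontology.canonical(class_id)
        if class_id in corpus.annotations.get(entity, ()):
            n_dup += 1
            continue
        corpus.add(entity, class_id, kind)
    if n_dup:
        logger.info("%s: dropped %d duplicate annotations", path, n_dup)
    corpus.drop_empty()
    return corpus


def read_associations(path) -> AssociationTruth:
    """Gene-disease truth pairs (gene id, disease id), deduplicated."""
    pairs = set()
    n_dup = 0
    for lineno, (gene, disease) in _rows(path):
        if (gene, disease) in pairs:
            n_dup += 1
        pairs.add((gene, disease))
    if n_dup:
        logger.info("%s: dropped %d duplicate associations", path, n_dup)
    return AssociationTruth.from_pairs(pairs)


def read_mapping(path, ontology: Optional[Ontology] = None, strict: bool = False) -> list[tuple[str, str]]:
    """Cross-ontology equivalence pairs (id_a, id_b).

    If an ontology is given the pairs are merged into it immediately; unknown
    ids raise in strict mode and are skipped with a warning otherwise.
    """
    pairs = []
    seen = set()
    for lineno, (a, b) in _rows(path):
        key = tuple(sorted((a, b)))
        if key in seen:
            continue
        seen.add(key)
        pairs.append((a, b))
    if ontology is not None:
        ontology.merge_equivalents(pairs, strict=strict)
    return pairs


def write_annotations(corpus: AnnotationCorpus, path) -> None:
    lines = [
        f"{entity}\t{cid}"
        for entity in sorted(corpus.annotations)
        for cid in sorted(corpus.annotations[entity])
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_associations(truth: AssociationTruth, path) -> None:
    lines = [f"{g}\t{d}" for g, d in sorted(truth.pairs)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
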