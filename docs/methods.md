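# Methods

## Scope and model

`cardphen` operates on the is-a fragment of phenotype ontologies plus two
specific axiom families: entity–quality (EQ) phenotype definitions and the
collection axioms it generates itself.  General OWL 2 DL content is out of
scope; unknown constructs are preserved as opaque axioms and ignored by the
classifier.

An EQ definition is the pattern
`P ⊑/≡ ∃has_part.(Q ⊓ ∃characteristic_of.E [⊓ ∃has_modifier.abnormal])`.
Only this ordering (quality as genus, entity as differentia) is matched; the
dual ordering with `has_characteristic` is not.  The abnormal-modifier
conjunct is accepted both inside the inner conjunction and as an outer
conjunct — published ontologies use both nestings — and its presence is
recorded.  Definition strength matters: a `⊑` (subclass) definition is a
necessary condition only, so under classification the class can gain
superclasses but never subclasses from the pattern; `≡` definitions provide
both directions.

A phenotype is a **cardinality phenotype** when its quality is subsumed by
*amount* (PATO:0000070) in the quality hierarchy — or is whitelisted as an
absence quality (*absent*, PATO:0000462) — and its entity passes the entity
filter.  The filter accepts any class in the entity namespace by default and
can be narrowed to CURIE prefixes; the command-line tools default to `CL`
(cell types), since collections of cells are the intended application and
collections of chemicals within cells would need a nested ("stacked")
treatment that is deliberately not attempted.

## The rewrite

For every entity `X` referenced by a detection (plus all ancestors of such
entities, pulled in so the partonomy is complete) one collection class is
generated with three axioms: member typing (`⊑ ∀has_member.X`), membership
(`X ⊑ ∃member_of.X-Collection`), and a nominal (`≡ {x-collection}`, a fresh
individual used nowhere else) that forces uniqueness, approximating the
maximal collection of `X` within one body.  Every collection is asserted
under a single root collection class `C` (`COLL:root`), which the
quality-based grouping classes need as their anchor.  The entity subclass
order is materialized as `X-Collection ⊑ ∃part_of.Y-Collection` for every
non-reflexive pair `X ⊑ Y` of the entity closure; reflexive pairs are
skipped as they carry no information under reflexive parthood.

Amount phenotypes are rewritten by substituting the collection for the
entity, preserving quality, modifier, and definition strength.  Absence
phenotypes receive two definitions attached to one class id: the
empty-collection form `∃has_part.(quality ⊓ ∃characteristic_of.(X-Collection
⊓ ∀has_member.⊥) ⊓ ∃has_modifier.abnormal)` and the negative form
`¬∃has_part.(quality ⊓ ∃characteristic_of.X)` (no modifier).  Declaring both
for the same class makes their right-hand sides equivalent, tying the
empty-collection reading of absence to the parthood reading.  Because the
dual construction is inherently definitional, absence rewrites are always
recorded with equivalence strength.

Two design points were genuinely open and are resolved as follows:

* **Replace, not augment.**  The original entity-based definition of a
  rewritten phenotype is removed.  Keeping it alongside would re-derive
  exactly the subtype inferences the rewrite exists to remove.
* **Equivalence for leaf and grouping definitions.**  Rewritten `≡`-strength
  phenotypes and the grouping classes are emitted as full definitions.  With
  subclass axioms only, no class would ever be *inferred under* a grouping
  class, defeating their purpose; sources that were only `⊑`-defined keep
  subclass strength.

Generated ids are deterministic functions of the source id (`COLL:`, `CXP:`,
`CQ:` prefixes with the source CURIE colon flattened to `_`), checked for
collisions against the input id space, and recorded in a provenance table
(generated id, source id, schema).  Re-running the rewrite on its own output
is a fixpoint.

## Classification

The emitted schemata fall into a fragment where a fixed rule set is sound
and complete, so no external reasoner is required:

* original mode: `P1 ⊑ P2` iff quality and entity are pairwise subsumed,
  `P2` is `≡`-defined, and `P2`'s modifier conjunct (if any) appears in `P1`
  (existential-restriction monotonicity);
* revised mode: quality-monotone comparison *within* one collection (the
  nominal makes distinct collections incomparable); absence inversion
  (`absent_X ⊑ absent_Y` iff `Y ⊑ X`), licensed by the negative form;
  placement of every rewritten class under its collection's `CXP` and of
  amount classes under quality-matching `CQ` groupings; asserted is-a edges
  and transitivity over everything.  Non-cardinality EQ definitions still
  classify among themselves by the original rule.

Part-of assertions between collections license no `CXP ⊑ CXP` edges: without
role chains that inference is not DL-entailed, and the grouping semantics do
not use it.

Both classifiers are compared edge-for-edge against a naive saturation
oracle — an independent fixpoint computation with its own depth-first
reachability and no shared closure code — on dozens of randomized fixtures
per mode.  Classification output may contain mutual edges (inferred
equivalences, e.g. when an asserted edge meets an entailed converse);
asserted input hierarchies, by contrast, must be acyclic except for merged
equivalence cliques, and any other cycle is rejected with its members named.
Cross-ontology equivalences (mapping files, mutual subclass assertions)
merge classes into a canonical node — lexicographically smallest id — that
keeps all merged ids as synonyms.  All edge outputs are sorted for
reproducible diffs.

## Similarity and evaluation

IC is corpus-based: profiles are propagated to all ancestors, `p(class)` is
the fraction of annotated entities (genes and diseases pooled, per the
definition of annotation probability over entities) whose propagated profile
contains the class, and IC = −log₂ p, reported in bits.  Classes never used
after propagation have no IC entry and are excluded as MICA candidates,
rather than receiving infinite IC, so unused classes cannot dominate
similarity.  Resnik similarity is the maximal IC over common ancestors;
profile similarity is the literal two-sided best-match average
`Σᵢ maxⱼ sim(gᵢ,dⱼ)/(2gₙ) + Σⱼ maxᵢ sim(dⱼ,gᵢ)/(2dₙ)` with no further
normalization — each side is a half-average by construction.

Evaluation ranks all genes per disease by descending similarity with
average-rank tie handling (unbiased under ties), then pools every
(disease, gene) pair, scored by negative within-disease rank, into a single
ROCAUC computed as the normalized Mann–Whitney statistic with ties counting
one half.  A macro-average (mean per-disease AUC) is reported alongside; the
pooled number is primary because the ranking-then-single-AUC protocol is the
one the package models.  Genes and diseases without annotations are dropped,
not scored zero, and an optional restriction keeps only cardinality
phenotype annotations (entities whose profiles empty out drop with them).

## Synthetic benchmark

The generator builds a rooted `branching`-ary cell-type tree of the given
depth, one EQ-defined phenotype per (entity, quality) pair with a minimal
embedded quality hierarchy, and annotated corpora with planted truth:

* each disease is assigned a leaf cell type and a random subset of
  qualities (profile size `annotations_per_profile`);
* its true gene carries the same phenotype classes, except that one absence
  annotation (when present) is recorded at the parent cell type — absence of
  the supertype implies absence of the subtype, so the pair stays related
  under either classification while exercising the inverted direction;
* each decoy gene is, with probability `confound_rate`, annotated with the
  phenotypes of a *sibling* of some disease's cell type (same qualities):
  under the original classification sibling and disease phenotypes meet at
  the informative parent phenotype class, under the revised classification
  amount phenotypes of distinct cell types are incomparable, so the confound
  is designed to disappear.  Remaining decoys use cell types no disease was
  assigned to;
* noise adds, per profile, a binomial number of uniformly drawn extra
  annotations at rate `noise_rate`.

Defaults — depth 2, branching 3 (9 leaves under 3 parents), all three
qualities, 6 diseases, 30 genes, profiles of 2, `confound_rate` 1.0,
`noise_rate` 0.1 — are the benchmark conditions: small enough that every
leaf parent hosts both disease and sibling leaves, large enough that IC
estimates differentiate leaf from parent classes.  All randomness flows from
the single seed; identical specs give byte-identical serializations.

What the benchmark does and does not show: it plants the exact sibling
topology of the motivating mis-classification, so the before/after AUC
direction is a designed, testable property, not an accident.  It does not
emulate real HP/MP class-count distributions, real annotation depth, or
cross-species alignment noise; absolute AUC values on it say nothing about
real corpora, only the direction of the change is meaningful.  The shipped
NK T cell miniature is a frozen hand-written file, not generated, and anchors
the entailment tests.

## Serialization

Two dialects are supported.  The OBO 1.4 subset covers terms, is-a,
equivalences and EQ definitions in the genus/differentia `intersection_of`
encoding (the `has_part` wrapper is implicit, as in compiled HP/MP
releases); it is the human-editable fixture format and cannot encode
nominals, negation, universal restrictions or subclass-strength EQ
definitions — those are dropped on write with a logged manifest.  The OWL 2
functional-syntax subset covers every emitted constructor and round-trips
the full ontology, including term namespaces and synonyms carried as
annotation assertions; a structural pass rebuilds the collection/rewrite/
grouping view from a parsed file so classification after a round trip is
identical.  Writers are deterministic (sorted declarations and axioms);
readers reject malformed input with line numbers in strict mode.

## Problem sizes and numerical notes

Randomized classifier fixtures go up to depth-3/branching-3 trees with the
phenotype set subsampled to ≤40 classes — sizes where the deliberately
unoptimized saturation oracle remains fast while covering all rule
interactions.  The benchmark reports means over 20 generator replicates.
IC uses exact log₂ arithmetic; similarity comparisons in tests use a 1e-12
absolute slack for float accumulation.  Ties in ranking always take the
average rank; ROCAUC counts tied comparisons one half.

## Known limitations

* Only the first EQ ordering is parsed; post-coordinated multi-entity or
  process phenotypes are passed through untouched.
* The rule classifier is complete for the emitted schemata only; feeding the
  OWL export to a full OWL 2 DL reasoner may yield additional entailments
  for ontologies containing richer axioms (the export exists for exactly
  that cross-check).
* Temporalized membership/parthood is not modeled; collections are
  time-slices of one body.
* Real multi-column association report files must be reduced to the
  2-column TSV shapes first (a `cut -f` one-liner).
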