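format-version: 1.4
ontology: nk-t-cell-demo
! Hand-written miniature of the NK T cell / T cell cardinality scenario:
! two cell-type classes, the amount branch of the quality hierarchy, and
! four EQ-defined cardinality phenotype classes (decreased number and
! absence for each cell type).

[Term]
id: CL:0000084
name: T cell
namespace: entity

[Term]
id: CL:0000814
name: mature NK T cell
namespace: entity
is_a: CL:0000084

[Term]
id: PATO:0000001
name: quality
namespace: quality

[Term]
id: PATO:0000070
name: amount
namespace: quality
is_a: PATO:0000001

[Term]
id: PATO:0000460
name: abnormal
namespace: quality
is_a: PATO:0000001

[Term]
id: PATO:0000462
name: absent
namespace: quality
is_a: PATO:0000070

[Term]
id: PATO:0001997
name: decreased amount
namespace: quality
is_a: PATO:0000070

[Term]
id: MP:0005018
name: decreased T cell number
namespace: phenotype
intersection_of: PATO:0001997
intersection_of: characteristic_of CL:0000084
intersection_of: has_modifier PATO:0000460

[Term]
id: MP:0008040
name: decreased NK T cell number
namespace: phenotype
intersection_of: PATO:0001997
intersection_of: characteristic_of CL:0000814
intersection_of: has_modifier PATO:0000460

[Term]
id: MP:0008070
name: absent T cells
namespace: phenotype
intersection_of: PATO:0000462
intersection_of: characteristic_of CL:0000084
intersection_of: has_modifier PATO:0000460

[Term]
id: MP:0008041
name: absent NK T cells
namespace: phenotype
intersection_of: PATO:0000462
intersection_of: characteristic_of CL:0000814
intersection_of: has_modifier PATO:0000460
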