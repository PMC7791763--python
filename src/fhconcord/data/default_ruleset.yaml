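# Default family-history cancer-risk ruleset.
#
# A documented, configurable approximation of the clinical testing criteria
# (hereditary breast/ovarian and hereditary colorectal high-risk assessment
# guidelines) used to stratify probands into increased vs average familial
# cancer risk. A pedigree is increased-risk when ANY rule fires.
#
# Rule fields:
#   id            stable identifier, reported in FHRiskResult.triggered_rules
#   cancers       canonical cancer terms counted by the rule
#   degrees       relative degrees counted (1 = parent/sibling/child,
#                 2 = grandparent/aunt/uncle); 3rd-degree relatives (cousins)
#                 are stored but excluded from rule counts by default
#   same_lineage  when true, counts are taken within one side of the family
#                 (maternal or paternal; siblings and children count to both)
#   min_count     minimum number of distinct affected relatives
#   max_age       when set, every counted diagnosis must be at or under this
#                 age; a diagnosis of unknown age never satisfies an age
#                 limit on its own (it can still satisfy count-only rules),
#                 but is reported through the `ambiguous` flag when relaxing
#                 unknown ages would make the rule fire
#   min_early / early_age
#                 additionally require min_early of the counted relatives to
#                 be diagnosed at or under early_age
#   sex           restrict counted relatives to one sex (male breast cancer)
rules:
  - id: breast_early_onset
    description: breast cancer diagnosed at or under 45 in a 1st/2nd-degree relative
    cancers: [breast]
    degrees: [1, 2]
    min_count: 1
    max_age: 45

  - id: breast_pair_one_under_50
    description: two or more breast cancers on the same side, at least one at or under 50
    cancers: [breast]
    degrees: [1, 2]
    same_lineage: true
    min_count: 2
    min_early: 1
    early_age: 50

  - id: ovarian_any_age
    description: ovarian cancer at any age in a 1st/2nd-degree relative
    cancers: [ovarian]
    degrees: [1, 2]
    min_count: 1

  - id: male_breast
    description: male breast cancer at any age
    cancers: [breast]
    degrees: [1, 2]
    min_count: 1
    sex: M

  - id: hboc_cluster
    description: three or more breast/prostate/pancreatic cancers on the same side
    cancers: [breast, prostate, pancreatic]
    degrees: [1, 2]
    same_lineage: true
    min_count: 3

  - id: colorectal_endometrial_early
    description: colorectal or endometrial cancer under 50 in a 1st/2nd-degree relative
    cancers: [colorectal, endometrial]
    degrees: [1, 2]
    min_count: 1
    max_age: 49

  - id: colorectal_pair_same_side
    description: two or more colorectal cancers on the same side, any age
    cancers: [colorectal]
    degrees: [1, 2]
    same_lineage: true
    min_count: 2

  - id: lynch_spectrum_pair_early
    description: >
      two or more Lynch-spectrum cancers (colorectal, endometrial, ovarian,
      gastric, urothelial, small bowel) on the same side, at least one under 50
    cancers: [colorectal, endometrial, ovarian, gastric, urothelial, small_bowel]
    degrees: [1, 2]
    same_lineage: true
    min_count: 2
    min_early: 1
    early_age: 49

  - id: lynch_spectrum_triple
    description: three or more Lynch-spectrum cancers on the same side, any age
    cancers: [colorectal, endometrial, ovarian, gastric, urothelial, small_bowel]
    degrees: [1, 2]
    same_lineage: true
    min_count: 3

  - id: unknown_cancer_pair_early
    description: two or more cancers of unknown type under 50 on the same side
    cancers: [unknown_primary]
    degrees: [1, 2]
    same_lineage: true
    min_count: 2
    max_age: 49
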