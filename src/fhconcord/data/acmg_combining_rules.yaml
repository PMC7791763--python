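# Evidence-combining rule table for germline variant classification.
#
# Each entry under a class lists minimum counts per evidence *category*
# (PVS, PS, PM, PP on the pathogenic side; BA, BS, BP on the benign side).
# A class is met when any one entry's thresholds are all satisfied (>=).
# Pathogenic is checked before likely_pathogenic, benign before
# likely_benign; if both a pathogenic-side and a benign-side class are met,
# the evidence is treated as conflicting and the variant is reported as a
# variant of uncertain significance. These are the standard 2015
# ACMG/AMP combining rules; the table is editable so a laboratory can
# tighten or relax combinations.
pathogenic:
  - {PVS: 1, PS: 1}
  - {PVS: 1, PM: 2}
  - {PVS: 1, PM: 1, PP: 1}
  - {PVS: 1, PP: 2}
  - {PS: 2}
  - {PS: 1, PM: 3}
  - {PS: 1, PM: 2, PP: 2}
  - {PS: 1, PM: 1, PP: 4}
likely_pathogenic:
  - {PVS: 1, PM: 1}
  - {PS: 1, PM: 1}
  - {PS: 1, PP: 2}
  - {PM: 3}
  - {PM: 2, PP: 2}
  - {PM: 1, PP: 4}
benign:
  - {BA: 1}
  - {BS: 2}
likely_benign:
  - {BS: 1, BP: 1}
  - {BP: 2}
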