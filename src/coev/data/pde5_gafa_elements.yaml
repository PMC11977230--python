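# Secondary-structure element ranges for the human PDE5A1 GAFa domain
# (residues D164-I312, human numbering), following the domain's element
# order alpha-alpha-beta-beta-beta-alpha-beta-alpha-beta-beta-alpha:
#   alpha1 alpha2 beta1 beta2 beta3 alpha3 beta4 alpha4 beta5 beta6 alpha5
#
# NOTE: these ranges are ESTIMATES partitioning the domain span according
# to that element order; they are a shipped default, not an authoritative
# assignment. Landscape analyses require element ranges as explicit config
# -- verify or replace these against the structure you are analysing.
alpha1: [164, 176]
alpha2: [184, 196]
beta1: [202, 208]
beta2: [213, 219]
beta3: [227, 233]
alpha3: [238, 247]
beta4: [253, 259]
alpha4: [262, 270]
beta5: [277, 283]
beta6: [288, 294]
alpha5: [300, 311]
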