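# Category lexicon for GO/PO annotation featurization.
#
# The signaling word list and the 34 major GO terms below are editable
# stand-in defaults (drawn from the generic GO slim and common plant
# signaling vocabulary); replace this file to match a specific
# annotation release.
signaling_terms:
  - hormone
  - auxin
  - abscisic acid
  - gibberellin
  - ethylene
  - cytokinin
  - jasmonic acid
  - salicylic acid
  - brassinosteroid
  - response to light
  - light stimulus
  - red light
  - blue light
  - osmosensing
  - osmotic stress
  - signal transduction
  - signaling pathway
  - phosphorelay
  - calcium signaling
go_major_terms:
  - cell communication
  - response to abiotic stimulus
  - response to biotic stimulus
  - response to stress
  - response to chemical
  - signal transduction
  - cell differentiation
  - cell cycle
  - cell division
  - cell death
  - transport
  - protein transport
  - transcription
  - translation
  - dna repair
  - dna replication
  - rna processing
  - protein modification
  - protein folding
  - proteolysis
  - lipid metabolic process
  - carbohydrate metabolic process
  - catabolic process
  - biosynthetic process
  - photosynthesis
  - reproduction
  - embryo development
  - flower development
  - growth
  - cell wall organization
  - cytoskeleton organization
  - chromosome organization
  - homeostatic process
  - secondary metabolic process
regulatory_role_terms:
  - enhancer
  - suppressor
  - chaperon
  - chaperone
  - activator
  - repressor
  - inhibitor
  - regulator
original_qualifiers:
  - part_of
  - involved_in
  - enables
  - located_in
  - is_active_in
  - acts_upstream_of
  - acts_upstream_of_negative_effect
  - acts_upstream_of_positive_effect
  - acts_upstream_of_or_within
  - contributes_to
  - colocalizes_with
  - NOT
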