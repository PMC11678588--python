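# Default biological-process lexicon: eight categories, each with the
# keyword/phrase list used for word-boundary matching against concept
# names.  Keywords are lower-case and chosen so that no keyword of one
# category appears, as a whole word or phrase, inside another category's
# keywords; this keeps name-based multi-label mapping unambiguous.
cell cycle regulation:
  - mitosis
  - apoptosis
  - cell cycle
  - cyclin
  - tumor
  - neoplasm
  - proliferation
energy and metabolism:
  - metabolism
  - metabolic
  - mitochondrial
  - glucose
  - lipid
  - oxidative
  - redox
  - respiration
gene regulation and expression:
  - transcription
  - gene expression
  - dna repair
  - dna replication
  - promoter
  - epigenetic
  - mrna
inflammation and immune response:
  - inflammation
  - inflammatory
  - cytokine
  - immune
  - microglia
  - interleukin
  - interferon
  - chemokine
membrane regulation:
  - membrane
  - transporter
  - phospholipid
  - receptor
  - efflux
protein aggregation:
  - aggregation
  - misfolded
  - amyloid
  - tau
  - proteasome
  - ubiquitin
  - chaperone
  - plaque
stress response regulation:
  - stress response
  - cortisol
  - heat shock
  - hypothalamic
  - thyroid
  - hormone
synapse and neurotransmission:
  - synapse
  - synaptic
  - neurotransmitter
  - ion channel
  - potassium channel
  - calcium channel
  - dopamine
  - glutamate
  - axon
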