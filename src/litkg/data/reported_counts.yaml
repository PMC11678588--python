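# Published summary counts and derived values from the three-disease
# AAPP comparison: per-disease returned source-node totals, pairwise and
# triple intersection counts, the Venn shares reported for each disease,
# and the evaluator metric rows for direct-vs-indirect classification.
# The `reproduce` command recomputes every derivable number from the
# counts and precision/recall pairs and flags reported values that do
# not match the recomputation.
totals:
  AD: 67213
  ALS: 63179
  FTD: 43643
pairwise:
  AD∩FTD: 43418
  AD∩ALS: 62335
  ALS∩FTD: 43368
triple: 43176
reported_percentages:
  AD: {triple: 64.2, shared_ALS: 28.5, shared_FTD: 0.4, exclusive: 6.9}
  ALS: {triple: 68.3, shared_AD: 30.3, shared_FTD: 0.3, exclusive: 1.1}
  FTD: {triple: 98.9, shared_AD: 0.6, shared_ALS: 0.4, exclusive: 0.1}
evaluators:
  SemNet 2.0: {precision: 0.94, recall: 0.71, f_measure: 0.81, accuracy: 0.74}
  GPT-4o LLM: {precision: 0.80, recall: 0.83, f_measure: 0.82, accuracy: 0.71}
  Humans: {precision: 1.0, recall: 1.0, f_measure: 1.0, accuracy: 1.0}
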