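# Methods

This note documents the models and procedures implemented in `litkg`,
the defaults and why they were chosen, what the synthetic generator
does and does not emulate, and the design decisions taken where more
than one convention was defensible.

## Knowledge-graph model

The graph is a set of typed concept nodes (CUI, name, semantic-type
code) and a merged set of directed semantic triples with PMID
provenance.  Duplicate *(head, relation, tail)* rows merge with the
union of their PMIDs on ingest: a triple is a literature assertion, and
multiplicity is provenance rather than weight, so load order can never
affect the graph.  CUIs are compared exactly and case-sensitively —
they are opaque keys.  Candidate discovery ("within *d* hops") treats
every triple as traversable in both directions, because a search depth
is a pure hop count; assertion direction is preserved per step in
metapath signatures instead.

## HeteSim scoring

HeteSim is the pairwise-random-walk relatedness of two nodes along a
metapath: each step of a signature becomes the 0/1 incidence between
its endpoint types under its relation and traversal direction, row
normalized so each row is a uniform single-step walk distribution.  For
even path length the source walks forward through the first half and
the target backward through the second half, and the score is the
cosine of the two meeting distributions over the midpoint type.  For
odd length the middle relation is split by one artificial node per
middle-edge instance, which makes the path even; the implementation
uses the closed form of that construction (scaling the meeting masses
by middle out-/in-degrees) rather than materializing artificial nodes.
A vanished meeting distribution scores 0.  The deterministic setting is
used throughout — no sampling anywhere in the score.

Numerical notes: the cosine is clipped to [0, 1] against rounding at
the 1e-16 level; zero-degree rows are dropped from the walk (their mass
vanishes, as it does in the explicit artificial-node construction).
`hetesim_reference` recomputes the same quantity by explicit
enumeration of instance walks and exists only as an independent
cross-check; the test suite and the acceptance sweep hold the two
implementations within 1e-9 of each other on hundreds of small random
graphs (observed agreement is at machine precision).

Signature enumeration collects the distinct type-level signatures of
*simple* instance paths (no repeated node) up to the maximum length;
simplicity rules out degenerate cycling, since a metapath represents
progress from source to target.  A node's per-target score is the
arithmetic mean of HeteSim over its signatures.  The mean across
signatures is a convention choice (only the cross-target aggregation is
fixed as the exact mean); it is isolated in one place
(`rank_sources`/`aggregate_targets`) so a different per-signature
aggregator can be substituted without touching anything else.
Defaults mirror the motivating study design: search depth 2, metapath
length 3, source type `aapp`.

## Normalization, top slices, composites

HeteSim values are only comparable within one simulation, so each
per-disease table is normalized independently: z-scores use the
*population* standard deviation (the table is the full population of
returned nodes, not a sample; with a zero-variance table all z are 0
and a warning is emitted), and percentile ranks use the Hazen
definition `100·(rank − 0.5)/n` with average ranks on ties, which keeps
percentiles strictly inside (0, 100) and makes single-row tables land
at 50.  The top *p*% slice contains exactly `ceil(n·p/100)` nodes, with
threshold ties broken by ascending CUI — the boundary rule has to be
picked somewhere, and the ceiling+tie-break pair makes the slice a
deterministic function of the table.

Composite scores are computed on the *raw* per-disease HeteSim values
(not on z or percentile): the single-disease convention — composite
equals the disease score when only one disease is connected — only
holds on the raw scale, and cross-disease composites then stay in
[0, 1] and inside the [min, max] of their inputs.

## Overlap quantification

The seven exclusive Venn regions of three node sets follow from
inclusion–exclusion; the same arithmetic runs on printed summary counts
alone (`venn_summary_from_counts`), which is how the `reproduce`
command re-derives published percentages without any graph.  Counts
that imply a negative region raise a consistency error naming the
region.  Per-disease shares are always expressed on that disease's own
total and rounded to one decimal, half away from zero — that rounding
convention reproduces every published share derivable from the shipped
counts except one: the reported ALS-exclusive 1.1% computes to 1.0%
(652/63,179), and the reproduce table flags it as inconsistent rather
than reconciling it.  (A published 0.82 F-measure likewise computes to
0.81 from its own precision/recall pair and is flagged the same way.)
For downstream process profiling the default is to take each disease's
top slice first and intersect the slices; ranking each pair's full
intersection by composite and slicing that is available behind
`top_before_intersection=False`.

## Process mapping and profiles

The eight biological-process categories (cell cycle regulation; energy
and metabolism; gene regulation and expression; inflammation and
immune response; membrane regulation; protein aggregation; stress
response regulation; synapse and neurotransmission) are matched by a
keyword lexicon: a node gets a category iff any keyword matches its
lower-cased name on a word boundary, multi-label permitted, unmatched
nodes reported.  The shipped lexicon is built from the category
definitions (mitosis, apoptosis, cytokine, ion channel, …) and is
deliberately a deterministic, auditable stand-in for ontology-driven
NLP or LLM mapping; it is replaceable by any YAML file of the same
shape.  Keywords are chosen so no category's keyword appears as a whole
word inside another category's keywords, which keeps recovery on the
synthetic fixture unambiguous.

Profiles count (node, category) *assignments*, not nodes — with
multi-label assignment, node-level counting is ill-defined.  Each
pairwise intersection's column is normalized to sum to 100, and each
category is standardized across intersections with the population SD.
With three intersections the population/sample-SD choice is material
(the closed form (0, 0, 30) → (−0.7071, −0.7071, 1.4142) holds only
for population SD), so it is fixed and tested.  Z-scores are computed
on the normalized percentages by default — the normalization is what
makes intersections of different sizes comparable — with the raw-count
variant behind `zscores_on_counts=True`.  Overall shares are each
category's fraction of all assignments, reported unrounded and to the
nearest integer.

## Evidence classification and evaluation

A (node, disease) pair is *direct* iff a single triple (either
direction) links them; otherwise *indirect* — i.e. classification by
the shortest metapath link, with multi-target nodes direct if direct to
at least one target.  Evaluation computes the confusion matrix with
`direct` as the default positive class (the choice is explicit and
swappable; swapping maps precision/recall to the complementary class
and leaves accuracy invariant).  Ratios with zero denominators are
reported as not-applicable (`None`), never as 0, because silent zeros
corrupt averaged summaries.  On degenerate one-class fixtures (all
direct, or no direct edges at all), perfect recovery is asserted
against the class that is actually populated.

## The synthetic generator

The generator emulates the neighborhood a knowledge-graph query returns
around the three disease targets, with ground truth for every
downstream stage:

* **Region membership** is an i.i.d. multinomial draw per AAPP node
  over the seven exclusive Venn regions plus an "unrelated" state.
  The default probabilities are the exclusive-region proportions
  observed in the real three-disease comparison (triple ≈ 63% of the
  union, AD∩ALS ≈ 28%, AD-only ≈ 7%, the remaining regions ≈ 1% or
  less), scaled by 0.95 with a 5% unrelated remainder so that candidate
  discovery has true negatives.
* **Relevance tiers** (high/mid/low, uniform per membership) plant 4/2/1
  distinct 2-hop bridge paths to the member disease.  Every planted
  path gets a *dedicated fresh* intermediate node whose semantic type
  is sampled once per (node, disease) from the configured type weights.
  Dedicated bridges mean a 2-hop path exists iff it was planted — the
  returned per-disease sets coincide exactly with planted membership,
  which is what makes Venn-region recovery exact — and they make the
  meeting distribution grow with path count, so tier order is
  recoverable from ranks.  `n_intermediates` also sets the count of
  ambient distractor intermediates per type, each tied to each disease
  with probability 0.5; these broaden the target-side meeting
  distributions without creating unplanted source–disease paths.
* **Direct edges** are planted per membership with probability
  `direct_edge_prob` (default 0.3, so both evidence classes are well
  populated); a membership whose tier plants zero paths gets the direct
  edge regardless, keeping every membership realizable within two hops.
* **Names and labels**: each node carries one (or, with probability
  0.3, two) process labels drawn from a fixed distribution patterned on
  the reported overall process shares; with probability `keyword_rate`
  (default 0.9) per label, a lexicon keyword of that category is
  embedded in the node name.  At `keyword_rate = 1` the mapper recovers
  the planted labels exactly.

A single seeded stream is consumed in a fixed, documented order —
regions, then tier/edge draws, then ambient links, then label/name
draws — so identical configurations are byte-identical on disk, and a
fixture regenerated from its saved config equals the saved fixture.

What the generator does **not** emulate: the real graph's scale (tens
of thousands of returned nodes per disease versus hundreds here), its
133-type/54-relation heterogeneity (type counts are config, three
intermediate types by default), degree distributions, citation counts,
negation, or relation-type semantics.  Passing tests therefore
demonstrate correctness of the algorithms and exact recovery of planted
structure — they do not certify behavior on literature-scale graphs,
and the study-scale outputs themselves (the published per-disease
totals, HeteSim tables, and process percentages) are not reproducible
at desk scale.  Those published values are covered instead by the
in-paper arithmetic reproduction (Venn shares from printed counts,
F-measures from printed precision/recall) and by the property suites
on the planted fixture.

## Problem sizes and determinism

The analysis drivers and the acceptance script use a 500-source-node
graph (≈3,500 nodes, ≈6,300 triples after bridges and distractors),
which the full three-disease ranking pipeline processes in a few
seconds while leaving every Venn region with the default probabilities
populated in expectation.  The oracle sweep uses 200 random graphs of
4–12 nodes, where exhaustive instance-path enumeration is exact and
fast.  The analysis drivers profile the top 5% slice (a 1% slice of
~500 ranked nodes holds only a handful of nodes); the library and
pipeline default remains the top 1%.  All randomness flows through
explicit integer seeds; pipeline reruns with identical configuration
are bit-identical, and the run manifest records a hash of the
canonical configuration.

## Known limitations

* The per-signature mean is one defensible aggregation; path-instance-
  level aggregation before the cross-target mean would weight
  signatures by instance multiplicity and can reorder nodes.
* Word-boundary keyword matching cannot resolve synonyms, abbreviations
  or context ("tau" in an unrelated enzyme name would still map to
  protein aggregation); the lexicon is a transparent stand-in for
  ontology- or model-based mapping, not a replacement.
* Evidence classification by shortest link inherits the knowledge
  graph's noise: a spurious length-1 triple is, by definition, direct
  evidence.
* `neighborhood` and signature enumeration are exact and therefore
  exponential in depth on dense graphs; defaults (depth 2, length 3)
  keep this tractable on query-neighborhood-sized graphs, not on a full
  literature graph.
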