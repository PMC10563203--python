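# Methods

This note documents the models and procedures implemented in `mammokg`,
the design choices made where the design was genuinely open, and what
the synthetic benchmark does and does not establish.

## Concept layer

The ontology is a three-level hierarchy: four first-level sign groups
(Common signs, Special signs, Merge signs, Category descriptions), nine
second-level entities (Mass, Calcification, Structure, Duct change,
Intramammary lymph nodes, Asymmetrical, Vascular change, Axillary lymph
nodes, Association anomaly) and 39 attribute slots distributed over the
second-level entities and the Category-descriptions group
(8+8+1+1+5+2+3+5+4+2). Exactly four relation predicates exist:
`has_a` (report → its three report-level children), `instance_of`
(mammography information → first-level group), `part_of` (first-level
group → second-level entity or data-layer feature type) and `select`
(entity → attribute value). The schema is shipped as YAML and validated
on load; `validate_triple` accepts exactly the licensed
subject/predicate/object patterns.

Two choices were open and are fixed here as schema data:

* **Feature-type parents.** The data layer tags 15 feature types, six of
  which (Density, Distribute, Location, Margin, Number, Shape, Size —
  plus Negation) are attribute-like and have no second-level
  counterpart. Each of the 15 types is assigned exactly one first-level
  parent (the attribute-like types and Negation under Common signs;
  Special and Lymph Node under Special signs; Merge under Merge signs;
  Category descriptions under itself), so every report instantiates
  exactly 15 `part_of` edges. This is the only assignment that makes the
  per-report structural counts content-independent constants
  (3/4/15 edges per report).
* **Category selection.** The triple table has no row attaching the
  BI-RADS category; the schema therefore licenses the BI-RADS
  information node as a `select` subject alongside Basic information, so
  the assessment category is stored both as a node property and as an
  attribute value node reachable by path queries.

## Character-level tagging

Tokenization is character-level: offsets count code points and one BIO
tag is assigned per character (a three-character shape term yields
`B-Shape I-Shape I-Shape`), giving 31 tags for 15 types. Word
segmentation is deliberately avoided — segmentation errors would
propagate into spans, and the annotation format is character-offset
based. Malformed predicted tag sequences are repaired leniently on
decoding: an `I-X` without an open `X` span opens one (I-as-B), and any
label change closes the running span. Gold annotations with overlapping
spans are rejected at load time; the schema has no nested entities.

## Taggers

All four architectures share the start/stop-augmented linear-chain CRF
core: a path `t_1..t_L` scores
`trans[START,t_1] + Σ em[i,t_i] + Σ trans[t_{i-1},t_i] + trans[t_L,STOP]`,
the partition function is computed by the forward recursion in log
space, gradients by forward–backward (expected minus observed counts),
and decoding by Viterbi with ties broken toward the lowest tag index.
The core is verified against exhaustive path enumeration (L ≤ 5,
K ≤ 6) and finite differences.

* **HMM** — supervised maximum likelihood with add-k smoothing
  (default k = 0.1). Unseen characters emit a tag-independent uniform
  log-probability so decoding is total even at k = 0.
* **Feature CRF** — seven feature templates per position (unigrams at
  offsets −2..+2, the two adjacent bigrams) crossed with the current
  tag, plus transition weights; L-BFGS on the L2-regularized NLL
  (convex, zero initialization).
* **BiLSTM-CRF** — character embeddings → one BiLSTM layer (hidden size
  per direction configurable) → affine map to tag scores → CRF.
* **BiLSTM-Highway-CRF** — the BiLSTM output (2h) is affinely projected
  back to the embedding dimension d; the highway layer then combines
  this contextual path with the raw character embedding x:
  `y = tanh(W_H u + b_H) · T + x · (1 − T)` with
  `T = sigmoid(W_T x + b_T)`. Gating from x is what makes the layer an
  arbiter between trained features and the original vector: with the
  transfer gate forced shut the model degenerates, by construction, to
  a CRF over affinely projected embeddings (verified in the tests).
  The carry gate is defined as `1 − T` and has no parameters. One
  highway layer is used; the transfer-gate bias starts at −1
  (carry-biased), standard highway practice.

Character vectors are trained by skip-gram with negative sampling
(window 2, 5 negatives, unigram^0.75 noise), single-threaded and
seed-deterministic; the unknown-character vector is the vocabulary mean.
CBOW vs skip-gram was an open choice; skip-gram is the variant that
behaves better on small corpora.

Neural training uses Adam (default lr 1e-3, batch 16, 30 epochs,
dropout 0.5 on the BiLSTM output, gradient-norm clipping at 5). All
backpropagation is hand-derived numpy and checked against finite
differences for every parameter tensor of both architectures. The
hidden/embedding defaults (128/100) follow common BiLSTM-CRF practice;
the benchmark and acceptance runs use a smaller, faster configuration
(d = 48, h = 48, lr 3e-3, 6–8 epochs, batch 8) that converges to the
same held-out scores on the synthetic corpus — problem sizes chosen as
the package's standard benchmark scale.

Evaluation is strict entity-level: a prediction is correct only if
start, end and label all match; overall scores are micro-averages of
pooled TP/FP/FN. Zero denominators score 0.

## Knowledge fusion

Surface normalization tries, in order: exact canonical hit; explicit
replacement table (semantic-error spellings such as 欠清 → 模糊); best
edit-distance similarity `1 − lev/max(|a|,|b|)` against the canonical
terms of the span's type, accepted at ≥ 0.6 (first-listed canonical wins
ties). The threshold is the lowest value at which every fixture variant
maps to its own canonical while unrelated strings do not; the packaged
lexicon is constructed so each variant is strictly closest to its own
canonical. Below-threshold surfaces are kept and flagged, never dropped.

Finding assembly uses a same-sentence, nearest-anchor rule: anchor
entities (Mass, Calcification, Structure, Lymph Node, Special, Merge,
Category descriptions) each seed a finding; attribute entities attach to
the nearest anchor in the same 句号-delimited sentence whose owner
licenses the slot (ties to the left); negation cues flip their nearest
anchor. Each anchor type licenses slots through a designated
concept-layer owner (Lymph Node → Axillary lymph nodes, Special →
Asymmetrical, Merge → Association anomaly). Duplicate findings with the
same kind, canonical value and identical non-empty Location merge,
union-ing attributes and flagging conflicting slot values; findings
without a Location are never merged, since nothing identifies them as
the same physical finding. These rules are the simplest ones consistent
with one-finding-per-sentence report style, and the synthetic generator
is built so they have an exact gold answer.

## Knowledge graph

Each report instantiates the full schema skeleton regardless of content
— 3 `has_a`, 4 `instance_of` and 15 `part_of` edges — so those totals
are 3n/4n/15n for any n-report corpus. Extracted attribute values,
demographics and the category become value nodes (shared per distinct
value within a report, not globally) linked by `select`; polarity is a
property of the finding's select edge so that a negated and a positive
finding may share a value node. Every edge is validated against the
concept layer at insertion and again by `validate_graph`. Exports:
GraphML (lossless re-import), a Cypher script with one CREATE statement
per element, and CSV node/edge tables; loading into a live Neo4j server
is out of scope — the file exports are the tested contract.

Association queries count reports in which a *single* non-negated
finding satisfies all conditions and return the conditional BI-RADS
distribution among them.

## Synthetic corpus

The generator emulates the statistical structure of a 1,171-report
hospital corpus that is not publicly available. Defaults are fixed to
the published conditions: per-type mention proportions from the
annotation counts (Location most frequent at ~26% of mentions,
Distribute rarest at ~0.6%), one finding per sentence, female patients
aged 30–80 with mass in the screening band, and BI-RADS categories
drawn from feature-conditional rules, including
P(4C | irregular shape ∧ spiculated margin) = 0.9.

Sentence-level inclusion probabilities are *derived* from the
configured proportions (expected mentions per report are measured in
units of the Mass share; anchor sentence counts follow
floor + Bernoulli; attribute inclusion rates are rescaled analytically),
so the realized shares track `type_proportions` in expectation — the
suite checks ±20% relative at n = 2000. Spiculated margins are
up-weighted conditional on irregular shape (include 0.8, spiculated
0.65), which is both clinically sensible and gives the 4C rule support
of roughly 0.11 per report, enough for a tight conditional-probability
estimate at n = 1000. Surface variants (default rate 0.15) draw from
the lexicon's variant and replacement tables so fusion is exercised
end-to-end; at variant_rate 0 every surface is canonical and fusion
must reproduce the gold findings exactly.

What the benchmark shows: that the implementation learns, fuses and
compiles correctly under controlled conditions with a known answer.
What it does not show: performance on real hospital text. Real reports
have freer syntax, longer-range attachments, typos beyond the
replacement table, nested or discontinuous mentions and
hospital-specific conventions; the near-perfect synthetic scores are a
correctness check, not a clinical claim. The published extraction
scores on the hospital corpus are not reproducible here for the same
reason.

## Numerical choices

* Blocked CRF transitions use −1e30 rather than −inf so arithmetic
  stays finite; with all scores zero the partition equals L·log K,
  pinning the augmentation convention.
* Viterbi tie-break: lowest tag index at every backtrack step
  (first-maximum argmax).
* Similarity of two empty strings is 1; a zero-length comparison never
  divides by zero.
* Splits, sampling, embedding training and neural initialization all
  flow from explicit integer seeds; the generator is byte-reproducible.

## Known limitations

* No discontinuous or nested entities; BRAT relation/attribute lines
  are ignored.
* Negation scope is the sentence and flips a single nearest anchor.
* The classical CRF baseline is practical at toy scale only (feature
  matrices are dense over the 31-tag space).
* No pretrained transformer encoders and no GPU path; CPU training at
  synthetic scale is the contract.
* The select-edge total depends on extraction content and generator
  configuration; only the skeleton totals are content-independent.
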