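# mammokg

Extraction of BI-RADS mammography features from Chinese free-text
mammography reports and compilation of the results into a
concept-layer-constrained knowledge graph for breast-cancer diagnosis
support.

Free-text mammography reports describe masses, calcifications,
architectural distortion, lymph nodes and associated signs, together
with a BI-RADS assessment category. This package implements the full
workflow that turns such reports into structured, queryable knowledge:

1. **Concept layer** (`mammokg.schema`) — a three-level ontology of 4
   first-level sign groups, 9 second-level entities and 39 attribute
   slots, with exactly four relation predicates (`has_a`,
   `instance_of`, `part_of`, `select`). The schema is data
   (`data/concept_layer.yaml`), so the engine can be re-targeted at
   other report types.
2. **Corpus I/O** (`mammokg.corpus_io`) — BRAT standoff annotation
   parsing/writing, character-level BIO tag encoding/decoding for the 15
   data-layer feature types (31 tags), and seeded train/val/test splits.
3. **Sequence taggers** (`mammokg.ner`) — four architectures behind one
   contract: a supervised HMM, a feature-template linear-chain CRF, a
   BiLSTM-CRF and a **BiLSTM-Highway-CRF**. The highway layer
   `y = H(W_H, x) · T(W_T, x) + x · (1 − T(W_T, x))` arbitrates per
   dimension between the BiLSTM's contextual features and the raw
   character vector (transfer gate `T`, carry gate `1 − T`). The CRF
   core (partition function, forward–backward gradients, Viterbi) and
   all neural backpropagation are implemented in numpy and verified
   against exhaustive enumeration and finite differences.
4. **Knowledge fusion** (`mammokg.fusion`) — normalization of variant
   surface forms (毛刺 / 毛刺状 / 毛刺状边缘 → 毛刺状) by explicit semantic
   replacement plus edit-distance similarity, and assembly of entities
   into findings with attached attributes and negation flags.
5. **Knowledge graph** (`mammokg.graph`) — per-report instantiation of
   the concept-layer skeleton plus content-derived `select` edges;
   GraphML / Cypher / CSV exports, semantic queries (age × BI-RADS
   category) and feature→category association for computer-assisted
   diagnosis.
6. **Synthetic corpus** (`mammokg.synthetic`) — a generator of Chinese
   mammography reports with gold spans, findings, demographics and
   rule-conditioned BI-RADS categories, emulating the per-type mention
   proportions of a hospital corpus of 1,171 reports. It is the test
   oracle for every downstream stage.

Entity extraction is evaluated with strict entity-level precision,
recall and F1 (`F1 = 2PR/(P+R)`), per feature type and micro-averaged
overall.

## Worked example

```python
from mammokg import synthetic, fusion, graph, schema
from mammokg.ner import as_tagged, train_char_embeddings, train_neural, predict

bundle = synthetic.generate_corpus(synthetic.GeneratorConfig(n_reports=350, seed=7))
train, test = bundle.reports[:300], bundle.reports[300:]

tagged = as_tagged(train)
emb = train_char_embeddings([t for t, _ in tagged], d=48, window=2, epochs=2, seed=7)
model = train_neural("bilstm_highway_crf", tagged,
                     {"hidden_dim": 48, "epochs": 8, "batch_size": 8,
                      "learning_rate": 3e-3}, seed=7, embeddings=emb)

from mammokg.evaluation import entity_prf
gold = {r.report_id: r.entities for r in test}
pred = {r.report_id: predict(model, r.text) for r in test}
print(entity_prf(gold, pred).overall)
# PRF(precision=100.0, recall=100.0, f1=100.0)
```

On this 300/50 synthetic benchmark the trained tagger recovers every
held-out entity span; the count-based HMM baseline reaches F1 ≈ 99.4%
on the same split, so the contextual model closes the residual errors
the per-character emission model cannot.

Building the knowledge graph over 1,171 generated reports:

```python
layer = schema.default_schema()
lex = fusion.default_lexicon()
bundle = synthetic.generate_corpus(synthetic.GeneratorConfig(n_reports=1171, seed=1))
records = [graph.ReportRecord(r.report_id, r.demographics,
                              fusion.assemble_findings(r, layer, lex).findings,
                              r.birads_category)
           for r in bundle.reports]
kg = graph.build_graph(records, layer)
print(graph.edge_counts(kg))
# {'has_a': 3513, 'select': 23427, 'instance_of': 4684, 'part_of': 17565}
```

The `has_a` / `instance_of` / `part_of` totals are content-independent
consequences of the schema skeleton (3, 4 and 15 edges per report);
`select` counts the extracted attribute values, demographics and
categories, so it varies with content. Association queries quantify
feature→category risk:

```python
res = graph.feature_category_association(
    kg, [("Shape", "不规则形"), ("Margin", "毛刺状")], lexicon=lex)
print(res.support, res.top_category, res.category_distribution)
# 110 4C {'4B': 0.027, '4C': 0.936, '5': 0.036}
```

A mass with irregular shape and spiculated margins is overwhelmingly
assessed BI-RADS 4C — the computer-assisted-diagnosis signal the graph
is built to expose.

A `mammokg` console command wraps the same steps
(`mammokg synth | split | train | predict | evaluate | fuse |
build-graph | query | assoc`).

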