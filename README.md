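# labkg

Disease prediction from routine laboratory panels, with the clinical
knowledge made explicit.  `labkg` encodes each lab indicator's published
reference range as a small knowledge graph of severity relations, learns
translational embeddings of indicators and values, represents every
patient as a matrix of indicator→value relation vectors, and classifies
with a self-attention + convolutional network whose attention weights are
exportable for interpretation.  It is aimed at researchers studying
knowledge-informed models for tabular clinical data (the motivating
application is diabetes screening from an 11-indicator exam panel).

## Method in brief

1. **Knowledge graph.** For each indicator with normal range `[low, high]`
   (width `W`), a grid of value entities is linked to the indicator entity
   by one of seven severity relations (severely low … severely high), e.g.
   `(triglycerides, normal, 0.45 mmol/L)`.  Band boundaries are
   `low/high ∓/± α·W` with `α₁ = 0.25`, `α₂ = 0.75` by default.
2. **Embeddings.** TransE / TransH / TransR (TransH default): for a true
   fact, `l_h + l_r ≈ l_t` after the model's projection; trained with a
   margin-ranking loss over corrupted triples and evaluated by link
   prediction (Mean Rank, Hit@10, exhaustive corruption).
3. **Patient encoding.** A measured value is matched to its nearest grid
   entity (`<UNK>` / `<HIGHEST>` / `<LOWEST>` for missing / off-grid), and
   indicator j contributes the column `e_value − e_indicator`; the k × m
   relation matrix feeds the classifier.
4. **SAC classifier.** Two stacked self-attention layers
   (`V softmax(KᵀQ/√D_k)`), convolution windows {2, 3, 4} × 100 filters
   with max-pooling to a 300-vector, dropout 0.5, affine + softmax to two
   classes; cross-entropy, Adam.  Implemented in NumPy with hand-written,
   numerically verified backpropagation.
5. **Evaluation.** Accuracy / recall / F1 (diseased = positive),
   stratified splits or five-fold CV, SMOTE rebalancing of the training
   data, and a synthetic-cohort generator with known ground truth.

See `docs/methods.md` for assumptions, parameter meanings and
limitations.

## Worked example

```python
import numpy as np
import labkg as L

# synthetic cohort: 11 indicators, 3 of them causal, known ground truth
ranges = L.gen_ranges(11, seed=7)
spec = L.strong_signal_spec(n=1200, m=11, seed=7)
records, labels, truth = L.gen_cohort(ranges, spec)

catalog, triples = L.build_graph(ranges)          # severity-band graph
print(len(catalog.relation_to_int), catalog.n_entities, len(triples))
# 7 3180 3166

params = L.train("transH", triples, catalog,
                 L.TrainConfig(epochs=100, seed=7), dim_k=32)
print(L.evaluate_ranking(params, triples[:300], catalog).mean_rank)
# 2.19  (true indicator ranked ~2nd among 3180 corruptions)

order = [r.indicator for r in ranges]
X = L.encode_dataset(records, catalog, params, order)   # (1200, 32, 11)
model = L.train_classifier(X[:960], labels[:960],
                           L.SACConfig(dim_k=32, epochs=20, seed=7))
rep = L.metrics(labels[960:], model.predict_label(X[960:]))
print(round(rep.accuracy, 3), round(rep.recall, 3))
# 0.975 0.959
```

The first line of output confirms the graph registers exactly the seven
severity relations; Mean Rank ≈ 2 says the embeddings have internalized
the indicator–value structure; the final accuracy is read against the
cohort's Bayes ceiling of 1.0 (labels are deterministic given the values
in this cohort).

The same pipeline is available from the shell:

```bash
labkg simulate --m 11 --n 4000 --seed 7 --out cohort/
labkg build-kg --ranges cohort/ranges.csv --out kg/
labkg train-embed --kg kg/ --model transH --dim 64 --seed 7 --out emb/
labkg eval-embed --kg kg/ --emb emb/ --side head
labkg encode --kg kg/ --emb emb/ --patients cohort/patients.csv --out enc/
labkg train-clf --enc enc/ --epochs 30 --seed 7 --out model/
labkg export-attn --model model/ --enc enc/
```

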