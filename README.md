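# clinmine

Clinical and social-determinant text mining for epidemiological
surveillance: extract typed entities (Disease, Symptom, Drug, SDOH) and
inter-entity relations from pre-tokenized clinical free text, score the
extractors rigorously, and aggregate the results into surveillance tables
(symptom distributions, prevalence by syndrome, conditions following a
disorder, drug adverse effects).

The package is aimed at public-health informatics researchers who need a
transparent, fully seeded, desk-scale pipeline: every model is trained
from scratch on CPU in seconds-to-minutes, every random choice is driven
by an explicit seed, and a synthetic-corpus generator provides annotated
data with known ground truth so every claim the package makes is testable.

## What is inside

**Named-entity recognition.** A BiLSTM-CRF sequence labeler over
contextual word vectors. For a sentence `x_1..x_L`, an embedder produces
vectors `e_i`, a bidirectional LSTM produces hidden states
`h_i = [h_i^f ; h_i^b]`, an affine projection yields per-tag emission
scores `E ∈ R^{L×|T|}`, and a linear-chain CRF scores tag paths

```
s(y) = A[START, y_1] + Σ_i E[i, y_i] + Σ_i A[y_i, y_{i+1}] + A[y_L, STOP]
```

with `p(y|x) = exp s(y) / Z`, `Z` computed exactly by the forward
algorithm. Decoding is Viterbi under a hard IOB2 transition mask (no
`O → I-x`, no type-switching `I`), so every decoded sequence is a legal
chunking. Training minimizes the exact negative log-likelihood by
mini-batch SGD with analytically derived gradients; inference (forward,
Viterbi, forward–backward) is verified against brute-force path
enumeration in the test suite. The default embedder is a trainable hashed
word-vector table; a frozen pretrained contextual encoder can be slotted
in behind the same contract.

**Few-shot self-training.** Starting from a small seed annotation set,
the tagger predicts on an unlabeled pool; sentences whose Viterbi path has
high posterior confidence (minimum per-token marginal) are selected,
verified by an oracle (a human in practice, a simulated annotator here),
added to the training set, and the model is retrained until the dev
metric converges.

**Few-shot relation extraction.** Entity-pair instances (sentences with
`[E1]`/`[E2]` markers) and short textual relation descriptors are embedded
in one shared space; a margin loss pulls each instance toward its own
descriptor, and classification is nearest-descriptor by cosine distance
with a NO_RELATION threshold.

**Evaluation.** Strict entity-level P/R/F1 (exact start/end/label match),
document-grouped 70/15/15 splits and k-fold cross-validation, Welch's
two-sample t-test, and Fleiss' kappa for inter-annotator agreement.

**Surveillance.** Document-prevalence and mention-share tables with
explicit denominators, per-syndrome prevalence breakdowns, a
frequency-thresholded "conditions following a disorder" table (heads kept
only above 70% document prevalence), and per-drug adverse-effect lists.

## Worked example

```python
from clinmine import (TrainConfig, entity_prf, generate_corpus,
                      predict_entities, preset, split_70_15_15, train_ner)

corpus = generate_corpus(preset("small"), seed=11)
train, dev, test = split_70_15_15(corpus, seed=11)
params, history = train_ner(train, dev, TrainConfig(seed=5, epochs=30,
                                                    hidden=8, dim=16))
report = entity_prf([s.spans for s in test], predict_entities(test, params))
print(round(max(h["dev_f1"] for h in history), 3), round(report.f1, 3))
```

prints

```
1.0 1.0
```

meaning the tagger reaches perfect dev entity F1 during training (the
generator's disjoint lexicons guarantee a perfect tagger exists — the
learnability ceiling) and scores F1 = 1.0 on held-out documents under the
strict exact-match criterion. Epoch-by-epoch numbers are in `history`;
`examples/02_train_ner.py` prints the full table (dev F1 0.00 → 1.00
within 7 epochs, train NLL 7.29 → 0.66).

The `examples/` directory has one narrative script per capability:
corpus generation, NER training, self-training, relation extraction, the
metric battery, and surveillance tables. Run them from any directory,
e.g. `python examples/03_self_training.py`.

A thin CLI wires the same functions for shell use (`clinmine synth`,
`train-ner`, `predict-ner`, `selftrain`, `train-re`, `extract-re`, `eval`,
`kappa`, `surveil`, `convert`); every command writes a JSON run manifest
beside its output. `clinmine --help` lists the commands.

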