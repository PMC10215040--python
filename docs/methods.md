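# Methods

This note documents the models, the numerical choices, the synthetic data
the package is validated on, and the limits of what those validations
show.

## Sequence labeling model

Entities are encoded per token in the IOB2 scheme: every chunk starts
with `B-label`, continues with `I-label`, and everything else is `O`. The
tag inventory is ordered deterministically (`O` first, then `B-x, I-x`
for labels in sorted order) so transition matrices are reproducible. When
decoding tag sequences produced outside the constrained decoder, the
conlleval repair convention applies: an `I-x` that does not continue a
chunk of type `x` opens a new chunk as if it were `B-x`. Untyped chunks
(bare `B-`/`I-`) decode and are then dropped.

The tagger stack is:

1. **Embedder.** A hashed word-vector table: each lowercased token hashes
   (blake2b, 64-bit, mod `vocab_buckets`) to a row of a
   `vocab_buckets × d` table initialized i.i.d. Normal(0, 1/√d) from the
   seed. Row `i` of the output is the mean of looked-up vectors in the
   window `[i−w, i+w]`; the tagger default is `w = 0` because the BiLSTM
   supplies context. The table is trained jointly with everything else. A
   frozen pretrained contextual encoder can replace it behind the same
   `(tokens → L×d)` contract; such an adapter handles its own sub-word
   pooling and is not part of the tested core.
2. **BiLSTM.** Standard cells (input/forget/output gates, tanh
   candidate), zero initial states, forget-gate bias initialized to +1.
   Forward and backward states are concatenated (dimension `2h`).
3. **Projection.** Affine map `2h → |T|` giving emission scores.
4. **Linear-chain CRF.** Globally normalized over tag paths with learned
   transition scores including virtual START/STOP states. All recursions
   (forward partition, Viterbi, forward–backward) run in log space with
   log-sum-exp stabilization. IOB2 legality is a boolean mask whose
   forbidden cells act as score −∞.

**Training.** The loss is the exact mean CRF negative log-likelihood.
Gradients are analytic: posterior-minus-gold for emissions and expected-
minus-gold transition counts for the CRF (via forward–backward), then
standard backpropagation-through-time through the projection, both LSTM
directions, and the embedding table. The whole gradient is verified
against finite differences in the test suite. Optimization is plain
mini-batch SGD with global-norm gradient clipping — minimal and exactly
reproducible; defaults: lr 0.3, batch 8, clip 5.0, `h = 8`, `d = 16`,
4096 hash buckets. Early stopping tracks dev entity micro-F1 with
patience 10 and returns the best-dev parameters (ties to the earlier
epoch).

**Constraints in training vs decoding.** By default the mask is applied
at decode time only and the training partition runs unconstrained — the
classical choice that keeps the loss smooth; `constrain_loss=True`
applies the mask inside the partition as well. Transition scores are
learned in both cases.

**Determinism and ties.** Viterbi breaks ties toward the lower tag index
at every backtracking step, so the all-zero model decodes to all-`O`.
All randomness (init, shuffling) flows from the mandatory config seed;
identical seeds give bitwise-identical parameters.

## Self-training loop

Confidence of a predicted sentence is the **minimum** per-position
forward–backward posterior of the Viterbi tag — conservative: one
uncertain token disqualifies the sentence (a mean rule is available).
Selection keeps sentences with confidence ≥ τ (default 0.9 in the config;
the validation experiments use τ = 0.5 so that early rounds can sample),
ranked descending with exact ties resolved to the earlier corpus
position, capped by a per-round budget. Verified sentences join the
training set with the oracle's tags (spans re-derived by the IOB codec);
the model is retrained from its seeded initialization each round.
Convergence is declared when dev F1 changes by less than ε between
consecutive rounds — the natural operationalization of "repeat until
convergence" when the loop's own metric is dev F1. The loop returns the
best-dev model across rounds. The simulated oracle returns hidden gold
tags, flipping each non-`O` tag to `O` with a configurable error rate, a
simple model of annotators that miss entities more often than they invent
them.

## Relation extractor

An instance is its sentence with `[E1] … [/E1]` around the head span and
`[E2] … [/E2]` around the tail (a closing marker precedes an opening one
at the same position, so adjacent spans nest correctly). Instances and
descriptors are embedded by mean-pooling hashed word vectors (window 0)
and unit-normalizing; the distance is cosine (scale-free in a shared
space; Euclidean on unit vectors is monotonically equivalent). Training
minimizes the margin loss `Σ max(0, d(s, r⁺) − d(s, r⁻) + m)` with
`m = 0.2` by SGD on the shared table, with gradients flowing through both
the instance and descriptor embeddings (including the normalization
Jacobian). Classification takes the nearest descriptor, `NO_RELATION`
beyond the threshold θ (default 1.0 — the midpoint of the [0, 2] cosine
range; lowering θ can only remove extractions, which the tests assert as
a monotonicity property). Candidate pairs are restricted to same-sentence
co-occurrence filtered by a (head type, tail type) → labels rule map.

## Evaluation battery

- **Entity F1**: strict exact (start, end, label) match, micro-averaged,
  with per-label breakdown. No partial credit — the most conservative
  reading of entity-level scoring.
- **Splits**: 70/15/15 and k-fold operate on documents, not sentences, so
  sentences of one case report never straddle a train/test boundary.
- **Welch's t** (unequal variances, Welch–Satterthwaite df), two-sided;
  the degenerate both-samples-constant-and-equal case is defined as
  (t = 0, p = 1).
- **Fleiss' kappa** from the standard observed/expected agreement
  formulas on an items × categories count table; defined as 1 under
  perfect agreement even when expected agreement is 1. Cross-checked
  against statsmodels in the tests.

## Surveillance tables

Document prevalence counts a canonical term once per document; mention
mode counts raw mentions. Denominators are recorded in every table
because percentage claims are meaningless without them.
Canonicalization is case-folding plus an optional synonym map — no
external ontology. The "conditions following a disorder" table keeps
heads whose document prevalence — among documents containing any head of
the requested type — is **strictly greater** than the threshold (default
0.70), then lists the top-k tails by co-occurrence count, ties
alphabetical.

## Synthetic corpus generator

The generator emulates the statistical skeleton of an annotated clinical
case-report corpus: documents of 3–6 sentences; entity mentions drawn
from per-label lexicons (realistic clinical surface forms, some
multi-token) inserted among filler tokens at Poisson(`entity_density`,
default ≈1.2 — one to two clinical concepts per sentence, typical of
case-report prose); relations realized as head–cue–tail patterns with
per-rule probabilities (default 0.15 each for symptom-follows-disease
and drug-causes-effect); and optional document-level planting of symptom
terms at fixed prevalences for recovery experiments. Annotation noise
(random tag deletion) uses a separate random stream so the noise knob
never changes the generated text. Fixture presets: `tiny` (6 docs, unit
tests), `small` (40 docs, learnability), `medium` (200 docs with planted
prevalences 0.50/0.35/0.45, aggregate statistics).

By default entity lexicons are pairwise disjoint and disjoint from the
filler vocabulary, so a Bayes-optimal tagger with entity F1 = 1 exists
and trained models are benchmarked against that ceiling; an `ambiguity`
knob shares a fraction of surface forms across labels to break
separability deliberately. Relation cue tokens make relations learnable
by a purely lexical encoder — the point is to exercise the few-shot
mechanism, not world knowledge.

**What passing tests do and do not show.** Synthetic text has none of
the hard parts of clinical language: no ambiguous or polysemous mentions
(unless the ambiguity knob is turned), no misspellings or abbreviations,
no long-range or cross-sentence structure, no class imbalance beyond the
configured rates. Perfect scores here certify the machinery — exact
inference, correct gradients, sound bookkeeping — not clinical-grade
accuracy; real-corpus performance additionally depends on the pretrained
encoder plugged into the embedder contract.

## Validation experiment sizes

The experiments behind the test suite and `scripts/acceptance.py` use:
200+ random CRF instances (|T|^L ≤ 1024) against brute-force
enumeration; 1,000 random span sets for the codec round trip; 1,000
synthetic sentences for constrained decoding; the `small` fixture for
learnability (h = 8, d = 16, ≤ 30 epochs); self-training with ~50 seed
sentences, a ~500-sentence pool and a perfect oracle (five replicate
seeds in the test suite, three in the acceptance script); ~150 labeled
relation instances with a 70/30 split, plus a one-example-per-class run
over four relation types; and 200 documents for prevalence recovery,
judged against binomial 95% confidence intervals. Prevalence recovery is
run with `entity_density = 0` so the planted document-prevalence channel
is isolated from background mentions of the same terms.

## Known limitations

- The built-in hashed embedder has no semantics beyond token identity;
  generalization to unseen surface forms requires the pretrained-encoder
  adapter.
- Entities are contiguous and non-overlapping (IOB2); nested or
  discontinuous mentions are out of scope, as are cross-sentence
  relations.
- Tokenization and sentence splitting are assumed done upstream; the
  whitespace tokenizer shipped is for demos only.
- Hash collisions can merge rare tokens into one bucket (4096 buckets by
  default); harmless at desk scale, configurable when it matters.
- The oracle simulation models annotator errors as entity deletions
  only; real annotator disagreement is richer (boundary and type errors).
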