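"""Few-shot annotation loop: train, predict on a pool, selectively sample
confident predictions, verify with an oracle, grow the training set,
retrain until the dev metric converges.

Selection confidence for a sentence is the minimum over positions of the
forward-backward posterior of the Viterbi-predicted tag — a conservative
rule: one uncertain token disqualifies the whole sentence. A mean rule is
available via config. Convergence is declared when the dev entity micro-F1
changes by less than ``epsilon`` between consecutive rounds.

The oracle contract models human verification: given a sentence and the
model's predicted tags it returns a corrected tag sequence of the same
length. :class:`SimulatedOracle` implements it from the generator's hidden
gold, flipping each tag to O with a configurable error rate to model
imperfect annotators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import crf
from .corpus import AnnotatedSentence, Corpus
from .encoder import embed_tokens
from .ner import NERParams, TrainConfig, emissions, train_ner
from .synthetic import HiddenGold
from .tagging import allowed_transitions, decode_iob


class SelfTrainError(ValueError):
    pass


@dataclass
class SelfTrainConfig:
    """Loop knobs: rounds, per-round sentence budget, confidence threshold
    tau, dev-F1 convergence tolerance epsilon."""

    seed: int
    max_rounds: int = 5
    per_round_budget: int = 50
    tau: float = 0.9
    epsilon: float = 1e-3
    confidence_rule: str = "min"  # or "mean"

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau <= 1.0):
            raise SelfTrainError("tau must lie in [0, 1]")
        if self.epsilon < 0:
            raise SelfTrainError("epsilon must be >= 0")
        if self.per_round_budget < 1:
            raise SelfTrainError("per_round_budget must be >= 1")
        if self.confidence_rule not in ("min", "mean"):
            raise SelfTrainError("confidence_rule must be 'min' or 'mean'")


@dataclass
class SimulatedOracle:
    """Verification oracle backed by hidden gold tags.

    Returns the gold tags for a sentence, flipping each to O independently
    with probability ``error_rate`` (seeded).
    """

    hidden: HiddenGold
    error_rate: float = 0.0
    seed: int = 0
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate <= 1.0):
            raise SelfTrainError("error_rate must lie in [0, 1]")
        self._rng = np.random.default_rng(self.seed)

    def verify(self, sentence: AnnotatedSentence, predicted_tags) -> tuple:
        gold = self.hidden.lookup(sentence.doc_id, sentence.sent_id)
        if len(gold) != len(sentence):
            raise SelfTrainError("hidden gold length mismatch")
        if self.error_rate == 0.0:
            return tuple(gold)
        return tuple(
            "O" if (t != "O" and self._rng.random() < self.error_rate) else t
            for t in gold
        )


def sentence_confidence(
    marginal_probs: np.ndarray, path: Sequence[int], rule: str = "min"
) -> float:
    """Confidence of a predicted path from its per-position posteriors."""
    post = np.asarray(marginal_probs, dtype=float)
    path = np.asarray(path, dtype=np.int64)
    if len(path) != post.shape[0]:
        raise SelfTrainError("path length does not match marginal rows")
    on_path = post[np.arange(len(path)), path]
    return float(on_path.min() if rule == "min" else on_path.mean())


def select_candidates(scored: Sequence, tau: float, budget: int) -> list:
    """Pick up to ``budget`` ids with confidence >= tau.

    ``scored`` is an iterable of (id, confidence) in corpus order; ranking
    is by confidence descending with exact ties resolved toward the
    earlier corpus position.
    """
    eligible = [(i, sid) for i, (sid, c) in enumerate(scored) if c >= tau]
    confs = {sid: c for sid, c in scored}
    eligible.sort(key=lambda t: (-confs[t[1]], t[0]))
    return [sid for _, sid in eligible[:budget]]


@dataclass
class LoopHistory:
    """Per-round record of the self-training loop."""

    rounds: list = field(default_factory=list)

    def append(self, **row) -> None:
        self.rounds.append(row)

    @property
    def train_sizes(self) -> list:
        return [r["train_size"] for r in self.rounds]

    def to_rows(self) -> list:
        return list(self.rounds)


def _pool_predictions(pool_sentences, params: NERParams, rule: str):
    mask = allowed_transitions(params.tagset)
    out = []
    for s in pool_sentences:
        X = embed_tokens(s.texts, params.embedder)
        E = emissions(X, params)
        path = crf.viterbi(E, params.trans, mask)
        post = crf.marginals(E, params.trans)
        conf = sentence_confidence(post, path, rule)
        tags = tuple(params.tagset.tags[i] for i in path)
        out.append((s, tags, conf))
    return out


def self_train(
    seed_corpus: Corpus,
    pool: Corpus,
    oracle,
    dev: Corpus,
    train_cfg: TrainConfig,
    loop_cfg: SelfTrainConfig,
):
    """Run the annotate-verify-retrain loop; returns (params, history).

    Stops when the dev F1 change between consecutive rounds falls below
    ``epsilon``, the pool is exhausted, or ``max_rounds`` is reached.
    Returns the model with the best dev F1 seen across rounds.
    """
    if len(seed_corpus) == 0:
        raise SelfTrainError("seed corpus is empty")

    history = LoopHistory()
    train_sents = list(seed_corpus.sentences)
    remaining = list(pool.sentences)

    params, ner_hist = train_ner(Corpus(train_sents), dev, train_cfg)
    dev_f1 = max((h["dev_f1"] for h in ner_hist), default=0.0)
    dev_acc = max((h["dev_token_acc"] for h in ner_hist), default=0.0)
    history.append(
        round=0, train_size=len(train_sents), dev_f1=dev_f1,
        dev_token_acc=dev_acc, n_sampled=0, n_corrected=0,
    )
    best_params, best_f1 = params, dev_f1

    prev_f1 = dev_f1
    for rnd in range(1, loop_cfg.max_rounds + 1):
        if not remaining:
            break
        preds = _pool_predictions(remaining, params, loop_cfg.confidence_rule)
        scored = [((s.doc_id, s.sent_id), conf) for s, _, conf in preds]
        chosen = set(select_candidates(scored, loop_cfg.tau,
                                       loop_cfg.per_round_budget))
        if not chosen:
            break
        n_corrected = 0
        still_remaining = []
        for s, tags, _conf in preds:
            if (s.doc_id, s.sent_id) in chosen:
                verified = oracle.verify(s, tags)
                if tuple(verified) != tuple(tags):
                    n_corrected += 1
                train_sents.append(
                    AnnotatedSentence(
                        s.doc_id, s.sent_id, s.tokens,
                        spans=decode_iob(verified), tags=tuple(verified),
                    )
                )
            else:
                still_remaining.append(s)
        remaining = still_remaining

        params, ner_hist = train_ner(Corpus(train_sents), dev, train_cfg)
        dev_f1 = max((h["dev_f1"] for h in ner_hist), default=0.0)
        dev_acc = max((h["dev_token_acc"] for h in ner_hist), default=0.0)
        history.append(
            round=rnd, train_size=len(train_sents), dev_f1=dev_f1,
            dev_token_acc=dev_acc, n_sampled=len(chosen),
            n_corrected=n_corrected,
        )
        if dev_f1 > best_f1:
            best_params, best_f1 = params, dev_f1
        if abs(dev_f1 - prev_f1) < loop_cfg.epsilon:
            break
        prev_f1 = dev_f1
    return best_params, history
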