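"""Scoring and experimental-design utilities.

Entity scoring is strict span-level: a prediction is a true positive only
when (start, end, label) all match a gold span — no partial credit for
boundary or type near-misses. Precision/recall/F1 are micro-averaged over
sentences, with a per-label breakdown.

Splitting and k-fold cross-validation operate at document granularity so
that sentences of one case report never straddle a train/test boundary.
Significance testing uses Welch's unequal-variance two-sample t-test.
Inter-annotator agreement uses Fleiss' kappa over an items x categories
count table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .corpus import Corpus


class EvaluationError(ValueError):
    pass


def _prf(tp: int, n_pred: int, n_gold: int) -> tuple:
    p = tp / n_pred if n_pred else 0.0
    r = tp / n_gold if n_gold else 0.0
    f1 = 2 * p * r / (p + r) if (p + r) else 0.0
    return p, r, f1


@dataclass
class EvalReport:
    """Micro and per-label precision/recall/F1 with support counts."""

    precision: float
    recall: float
    f1: float
    n_gold: int
    n_pred: int
    n_correct: int
    per_label: dict = field(default_factory=dict)
    fold: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "n_gold": self.n_gold,
            "n_pred": self.n_pred,
            "n_correct": self.n_correct,
            "per_label": {
                lab: dict(zip(("precision", "recall", "f1", "support"), vals))
                for lab, vals in self.per_label.items()
            },
            "fold": self.fold,
        }


def entity_prf(gold: Sequence, pred: Sequence, fold: Optional[int] = None) -> EvalReport:
    """Exact-match entity-level scores over aligned sentence lists.

    ``gold`` and ``pred`` are equal-length sequences of span collections
    (anything iterable of objects with start/end/label, e.g.
    :class:`~clinmine.corpus.EntitySpan` sets).
    """
    if len(gold) != len(pred):
        raise EvaluationError(
            f"gold has {len(gold)} sentences, pred has {len(pred)}"
        )
    tp = n_gold = n_pred = 0
    by_label: dict = {}
    for g_spans, p_spans in zip(gold, pred):
        g = {(s.start, s.end, s.label) for s in g_spans}
        p = {(s.start, s.end, s.label) for s in p_spans}
        inter = g & p
        tp += len(inter)
        n_gold += len(g)
        n_pred += len(p)
        labels = {t[2] for t in g | p}
        for lab in labels:
            row = by_label.setdefault(lab, [0, 0, 0])  # tp, pred, gold
            row[0] += sum(1 for t in inter if t[2] == lab)
            row[1] += sum(1 for t in p if t[2] == lab)
            row[2] += sum(1 for t in g if t[2] == lab)
    micro_p, micro_r, micro_f = _prf(tp, n_pred, n_gold)
    per_label = {}
    for lab in sorted(by_label):
        l_tp, l_pred, l_gold = by_label[lab]
        lp, lr, lf = _prf(l_tp, l_pred, l_gold)
        per_label[lab] = (lp, lr, lf, l_gold)
    return EvalReport(micro_p, micro_r, micro_f, n_gold, n_pred, tp, per_label, fold)


def token_accuracy(gold_tags: Sequence, pred_tags: Sequence) -> float:
    """Fraction of tokens whose predicted tag equals gold, over all
    sentences."""
    correct = total = 0
    for g, p in zip(gold_tags, pred_tags):
        if len(g) != len(p):
            raise EvaluationError("tag sequence length mismatch")
        correct += sum(1 for a, b in zip(g, p) if a == b)
        total += len(g)
    return correct / total if total else 0.0


def split_70_15_15(corpus: Corpus, seed: int) -> tuple:
    """Seeded 70/15/15 train/validation/test split at document level."""
    docs = corpus.doc_ids
    if len(docs) < 3:
        raise EvaluationError(f"need >= 3 documents to split, have {len(docs)}")
    rng = np.random.default_rng(seed)
    order = [docs[i] for i in rng.permutation(len(docs))]
    n = len(order)
    n_train = int(0.70 * n)
    n_dev = int(0.15 * n)
    train_ids = order[:n_train]
    dev_ids = order[n_train : n_train + n_dev]
    test_ids = order[n_train + n_dev :]
    return corpus.subset(train_ids), corpus.subset(dev_ids), corpus.subset(test_ids)


def kfold(corpus: Corpus, k: int = 5, seed: int = 0) -> list:
    """Seeded k-fold partition of documents; fold sizes differ by <= 1 doc.

    Returns a list of ``(train_corpus, test_corpus)`` pairs.
    """
    if k < 2:
        raise EvaluationError(f"k must be >= 2, got {k}")
    docs = corpus.doc_ids
    if len(docs) < k:
        raise EvaluationError(f"need >= {k} documents, have {len(docs)}")
    rng = np.random.default_rng(seed)
    order = [docs[i] for i in rng.permutation(len(docs))]
    fold_ids = [order[i::k] for i in range(k)]
    folds = []
    for i in range(k):
        test_ids = set(fold_ids[i])
        train_ids = [d for d in order if d not in test_ids]
        folds.append((corpus.subset(train_ids), corpus.subset(fold_ids[i])))
    return folds


def two_sample_t(a: Sequence[float], b: Sequence[float]) -> tuple:
    """Welch's unequal-variance two-sample t-test, two-sided.

    Degenerate case: both samples constant with equal means is defined as
    (t=0, p=1) rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise EvaluationError("each sample needs >= 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return (np.inf if np.mean(a) > np.mean(b) else -np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def fleiss_kappa(table) -> float:
    """Fleiss' kappa for an N x k items-by-categories count matrix.

    Every row must sum to the same number of raters n >= 2. Defined as 1
    when observed agreement is perfect even if expected agreement is 1
    (all mass in a single category).
    """
    m = np.asarray(table, dtype=float)
    if m.ndim != 2 or m.shape[0] < 1 or m.shape[1] < 2:
        raise EvaluationError("rating table must be N x k with k >= 2")
    if np.any(m < 0) or np.any(m != np.round(m)):
        raise EvaluationError("rating table entries must be non-negative counts")
    n_raters = m[0].sum()
    if n_raters < 2:
        raise EvaluationError("need >= 2 raters")
    if not np.allclose(m.sum(axis=1), n_raters):
        raise EvaluationError("all rows must sum to the same rater count")
    N = m.shape[0]
    # per-item observed agreement
    p_i = (np.sum(m * m, axis=1) - n_raters) / (n_raters * (n_raters - 1))
    p_bar = p_i.mean()
    p_j = m.sum(axis=0) / (N * n_raters)
    p_e = float(np.sum(p_j * p_j))
    if p_e >= 1.0:
        return 1.0 if p_bar >= 1.0 else 0.0
    return float((p_bar - p_e) / (1.0 - p_e))
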