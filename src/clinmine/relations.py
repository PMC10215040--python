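"""Few-shot relation extraction by descriptor distance.

An entity-pair instance is represented by its sentence with the head span
wrapped in ``[E1] ... [/E1]`` markers and the tail in ``[E2] ... [/E2]``;
each relation type is represented by a short textual descriptor (e.g.
"drug causes adverse effect"). Both are embedded in one shared space —
mean-pooled hashed word vectors, unit-normalized — and classification is
nearest-descriptor by cosine distance, with a NO_RELATION outcome when the
nearest descriptor is farther than a threshold.

Training minimizes a margin (triplet) loss over the shared embedding
table: for every labeled instance, the distance to its own descriptor must
undercut the distance to every other descriptor by at least the margin.
Because instances and descriptors share the table, a handful of labeled
examples per class suffices to organize the space, and classes unseen in
training can still be classified through their descriptors alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .corpus import Corpus, EntitySpan
from .encoder import EmbedderParams, embed_tokens, token_buckets

NO_RELATION = "NO_RELATION"

E1_OPEN, E1_CLOSE = "[E1]", "[/E1]"
E2_OPEN, E2_CLOSE = "[E2]", "[/E2]"
_MARKERS = {E1_OPEN, E1_CLOSE, E2_OPEN, E2_CLOSE}


class RelationError(ValueError):
    pass


@dataclass(frozen=True)
class RelationInstance:
    """A marked entity pair in one sentence, optionally gold-labeled."""

    tokens: tuple
    head: EntitySpan
    tail: EntitySpan
    label: Optional[str] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))
        n = len(self.tokens)
        if self.head.end > n or self.tail.end > n:
            raise RelationError("head/tail span exceeds sentence length")
        if self.head.overlaps(self.tail):
            raise RelationError("head and tail spans overlap")


@dataclass(frozen=True)
class RelationDescriptor:
    """A relation label plus the token sequence describing it."""

    label: str
    descriptor_text: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "descriptor_text", tuple(self.descriptor_text))
        if not self.descriptor_text:
            raise RelationError(f"descriptor for {self.label!r} is empty")


DEFAULT_DESCRIPTORS = (
    RelationDescriptor("symptom-follows-disease",
                       tuple("symptom follows or accompanies disease".split())),
    RelationDescriptor("drug-causes-effect",
                       tuple("drug caused adverse effect or reaction".split())),
)


@dataclass
class REParams:
    """Shared-space parameters: embedder, margin, NO_RELATION threshold."""

    embedder: EmbedderParams
    margin: float = 0.2
    threshold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise RelationError("margin must be > 0")
        if not (0.0 <= self.threshold <= 2.0):
            raise RelationError("threshold must lie in [0, 2]")


@dataclass
class REConfig:
    seed: int
    epochs: int = 30
    lr: float = 0.5
    dim: int = 32
    vocab_buckets: int = 4096
    margin: float = 0.2
    threshold: float = 1.0


def mark_instance(instance: RelationInstance) -> tuple:
    """Insert entity markers at the head/tail span boundaries."""
    # at equal positions a closing marker precedes an opening one, so
    # adjacent spans bracket correctly
    inserts = sorted(
        [
            (instance.head.start, 1, E1_OPEN),
            (instance.head.end, 0, E1_CLOSE),
            (instance.tail.start, 1, E2_OPEN),
            (instance.tail.end, 0, E2_CLOSE),
        ]
    )
    out: list = []
    k = 0
    for pos, _, marker in inserts:
        out.extend(instance.tokens[k:pos])
        out.append(marker)
        k = pos
    out.extend(instance.tokens[k:])
    return tuple(out)


def strip_markers(tokens: Sequence[str]) -> tuple:
    return tuple(t for t in tokens if t not in _MARKERS)


def embed_text(tokens: Sequence[str], params: EmbedderParams) -> np.ndarray:
    """Mean-pooled, unit-normalized text embedding in the shared space."""
    if len(tokens) == 0:
        raise RelationError("cannot embed empty token sequence")
    mat = embed_tokens(tokens, params)
    v = mat.mean(axis=0)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise RelationError("zero-vector embedding")
    return v / norm


def re_distance(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine distance between unit vectors; lies in [0, 2]."""
    if np.linalg.norm(u) == 0 or np.linalg.norm(v) == 0:
        raise RelationError("distance undefined for zero vectors")
    return float(1.0 - float(np.dot(u, v)))


def _instance_tokens(instance: RelationInstance) -> tuple:
    return mark_instance(instance)


def _mean_embed_raw(tokens, params: EmbedderParams):
    """Pre-normalization mean vector and the bucket rows feeding it."""
    buckets = token_buckets(tokens, params)
    u = params.table[buckets].mean(axis=0)
    return u, buckets


def _normalize_grad(u: np.ndarray, d_s: np.ndarray) -> np.ndarray:
    """Backprop through s = u / ||u||: d_u = (I - s s^T) d_s / ||u||."""
    norm = np.linalg.norm(u)
    s = u / norm
    return (d_s - s * float(np.dot(s, d_s))) / norm


def train_re(
    instances: Sequence[RelationInstance],
    descriptors: Sequence[RelationDescriptor],
    config: REConfig,
) -> tuple:
    """Fit the shared space by margin loss; returns (REParams, loss log).

    Every gold label among the instances must have a descriptor, and the
    instances must all be labeled. The margin loss for instance s with
    true descriptor r+ and each wrong descriptor r- is
    ``max(0, d(s, r+) - d(s, r-) + margin)``; gradients flow into the
    hashed embedding table through both the instance and the descriptors.
    """
    labeled = [inst for inst in instances]
    if not labeled:
        raise RelationError("no training instances")
    desc_by_label = {d.label: d for d in descriptors}
    for inst in labeled:
        if inst.label is None:
            raise RelationError("training instance lacks a gold label")
        if inst.label not in desc_by_label:
            raise RelationError(f"label {inst.label!r} has no descriptor")

    params = REParams(
        EmbedderParams(config.dim, config.vocab_buckets, window=0,
                       seed=config.seed),
        margin=config.margin, threshold=config.threshold, seed=config.seed,
    )
    desc_list = list(descriptors)
    rng = np.random.default_rng(config.seed + 1)
    loss_log = []
    for _epoch in range(config.epochs):
        order = rng.permutation(len(labeled))
        total = 0.0
        for idx in order:
            inst = labeled[int(idx)]
            toks = _instance_tokens(inst)
            u, inst_buckets = _mean_embed_raw(toks, params.embedder)
            s = u / np.linalg.norm(u)
            d_s = np.zeros_like(s)
            d_table = np.zeros_like(params.embedder.table)
            pos = desc_by_label[inst.label]
            v_pos, pos_buckets = _mean_embed_raw(pos.descriptor_text,
                                                 params.embedder)
            r_pos = v_pos / np.linalg.norm(v_pos)
            d_pos = 1.0 - float(np.dot(s, r_pos))
            any_active = False
            for neg in desc_list:
                if neg.label == inst.label:
                    continue
                v_neg, neg_buckets = _mean_embed_raw(neg.descriptor_text,
                                                     params.embedder)
                r_neg = v_neg / np.linalg.norm(v_neg)
                d_neg = 1.0 - float(np.dot(s, r_neg))
                hinge = d_pos - d_neg + params.margin
                if hinge <= 0:
                    continue
                any_active = True
                total += hinge
                # dL/ds = -r_pos + r_neg ; dL/dr_pos = -s ; dL/dr_neg = +s
                d_s += -r_pos + r_neg
                du_neg = _normalize_grad(v_neg, s)
                np.add.at(d_table, neg_buckets,
                          du_neg / len(neg_buckets))
                du_pos = _normalize_grad(v_pos, -s)
                np.add.at(d_table, pos_buckets,
                          du_pos / len(pos_buckets))
            if any_active:
                du = _normalize_grad(u, d_s)
                np.add.at(d_table, inst_buckets, du / len(inst_buckets))
                params.embedder.table -= config.lr * d_table
        loss_log.append(total / len(labeled))
    return params, loss_log


def classify_relation(
    instance: RelationInstance,
    descriptors: Sequence[RelationDescriptor],
    params: REParams,
) -> tuple:
    """Nearest-descriptor label and its distance; NO_RELATION beyond the
    threshold. Equidistant descriptors resolve to the earlier list entry.
    """
    if not descriptors:
        raise RelationError("need at least one descriptor")
    s = embed_text(_instance_tokens(instance), params.embedder)
    best_label, best_dist = None, np.inf
    for d in descriptors:
        r = embed_text(d.descriptor_text, params.embedder)
        dist = re_distance(s, r)
        if dist < best_dist:
            best_label, best_dist = d.label, dist
    if best_dist > params.threshold:
        return NO_RELATION, float(best_dist)
    return best_label, float(best_dist)


def extract_relations(
    corpus: Corpus,
    predicted_spans: Sequence,
    pair_rules: dict,
    descriptors: Sequence[RelationDescriptor],
    params: REParams,
) -> list:
    """Classify every same-sentence entity pair licensed by ``pair_rules``.

    ``pair_rules`` maps (head label, tail label) to the candidate relation
    labels for that pair; classification is restricted to the matching
    descriptors. NO_RELATION outcomes are dropped. Returns records with
    doc/sentence ids, the two spans with surface text, the relation label
    and the embedding distance.
    """
    desc_by_label = {d.label: d for d in descriptors}
    records = []
    for sent, spans in zip(corpus, predicted_spans):
        ordered = sorted(spans)
        for head in ordered:
            for tail in ordered:
                if head == tail or head.overlaps(tail):
                    continue
                candidates = pair_rules.get((head.label, tail.label))
                if not candidates:
                    continue
                cand_desc = [desc_by_label[c] for c in candidates
                             if c in desc_by_label]
                if not cand_desc:
                    continue
                inst = RelationInstance(sent.texts, head, tail)
                label, dist = classify_relation(inst, cand_desc, params)
                if label == NO_RELATION:
                    continue
                records.append(
                    {
                        "doc_id": sent.doc_id,
                        "sent_id": sent.sent_id,
                        "head": [head.start, head.end, head.label],
                        "head_text": sent.span_text(head),
                        "tail": [tail.start, tail.end, tail.label],
                        "tail_text": sent.span_text(tail),
                        "label": label,
                        "distance": dist,
                    }
                )
    return records
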