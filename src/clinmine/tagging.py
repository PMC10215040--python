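"""IOB2 tag codec and the legal-transition structure for constrained decoding.

Entity chunks are encoded per token as ``B-label`` (chunk begin),
``I-label`` (chunk continuation) or ``O`` (outside). The IOB2 convention is
used: every chunk starts with ``B-``. Decoding applies the conlleval repair
rule to model-free inputs — an ``I-x`` that does not continue a ``B-x``/
``I-x`` chunk opens a new chunk as if it were ``B-x``. The same chunk
grammar, expressed as a boolean transition matrix over tags plus virtual
START/STOP states, is what the CRF layer uses to constrain decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import EntitySpan


class TaggingError(ValueError):
    pass


@dataclass(frozen=True)
class TagSet:
    """Deterministically ordered tag inventory for a set of entity labels.

    Tag order is ``O`` first, then ``B-x, I-x`` for each label in sorted
    order, so transition matrices are reproducible across runs. Virtual
    START and STOP states occupy the two indices after the real tags.
    """

    labels: tuple
    tags: tuple = field(init=False)

    def __post_init__(self) -> None:
        labs = tuple(sorted(set(self.labels)))
        if any(not l for l in labs):
            raise TaggingError("entity labels must be non-empty strings")
        object.__setattr__(self, "labels", labs)
        tags = ["O"]
        for lab in labs:
            tags.extend([f"B-{lab}", f"I-{lab}"])
        object.__setattr__(self, "tags", tuple(tags))

    @property
    def n_tags(self) -> int:
        return len(self.tags)

    @property
    def start_index(self) -> int:
        return self.n_tags

    @property
    def stop_index(self) -> int:
        return self.n_tags + 1

    def index(self, tag: str) -> int:
        try:
            return self.tags.index(tag)
        except ValueError:
            raise TaggingError(f"tag {tag!r} not in tagset {self.tags}") from None

    def indices(self, tags: Sequence[str]) -> np.ndarray:
        return np.array([self.index(t) for t in tags], dtype=np.int64)


def _parse_tag(tag: str) -> tuple:
    """Split a tag into (prefix, label); label may be '' for bare B-/I-."""
    if tag == "O":
        return "O", ""
    if tag[:2] in ("B-", "I-"):
        return tag[0], tag[2:]
    raise TaggingError(f"malformed IOB tag {tag!r}")


def encode_iob(length: int, spans: Sequence[EntitySpan]) -> tuple:
    """Encode non-overlapping spans over ``length`` tokens as IOB2 tags."""
    ordered = sorted(spans)
    for a, b in zip(ordered, ordered[1:]):
        if a.overlaps(b):
            raise TaggingError(f"overlapping spans: {a} and {b}")
    tags = ["O"] * length
    for sp in ordered:
        if sp.end > length:
            raise TaggingError(f"span {sp} exceeds length {length}")
        tags[sp.start] = f"B-{sp.label}"
        for i in range(sp.start + 1, sp.end):
            tags[i] = f"I-{sp.label}"
    return tuple(tags)


def decode_iob_with_repairs(tags: Sequence[str]) -> tuple:
    """Decode IOB tags to spans, returning ``(spans, n_repairs)``.

    ``n_repairs`` counts positions where the repair rule fired (an ``I-x``
    not continuing a chunk of type x). Untyped chunks (bare ``B-``/``I-``)
    are decoded and then dropped.
    """
    spans: list = []
    n_repairs = 0
    open_start = None
    open_label = None

    def close(end: int) -> None:
        nonlocal open_start, open_label
        if open_start is not None and open_label:
            spans.append(EntitySpan(open_start, end, open_label))
        open_start = open_label = None

    for i, tag in enumerate(tags):
        prefix, label = _parse_tag(tag)
        if prefix == "O":
            close(i)
        elif prefix == "B":
            close(i)
            open_start, open_label = i, label
        else:  # I-
            if open_start is not None and label == open_label:
                continue
            # orphan or type-switching I- : repair to a chunk begin
            n_repairs += 1
            close(i)
            open_start, open_label = i, label
    close(len(tags))
    return frozenset(spans), n_repairs


def decode_iob(tags: Sequence[str]) -> frozenset:
    """Decode an IOB tag sequence into the set of entity spans."""
    spans, _ = decode_iob_with_repairs(tags)
    return spans


def allowed_transitions(tagset: TagSet) -> np.ndarray:
    """Boolean legality matrix over tags plus START/STOP.

    Cell ``[a, b]`` is True when tag ``b`` may directly follow tag ``a``.
    The IOB2 grammar forbids entering ``I-x`` from anything other than
    ``B-x`` or ``I-x`` (including from START). START has no in-edges and
    STOP no out-edges; every real tag may end the sequence.
    """
    n = tagset.n_tags
    start, stop = tagset.start_index, tagset.stop_index
    allowed = np.zeros((n + 2, n + 2), dtype=bool)
    parsed = [_parse_tag(t) for t in tagset.tags]

    for a in range(n):
        for b in range(n):
            b_prefix, b_label = parsed[b]
            if b_prefix == "I":
                a_prefix, a_label = parsed[a]
                allowed[a, b] = a_prefix in ("B", "I") and a_label == b_label
            else:
                allowed[a, b] = True
        allowed[a, stop] = True
    for b in range(n):
        allowed[start, b] = parsed[b][0] != "I"
    allowed[start, stop] = True  # empty sequence is legal
    return allowed
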