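"""Core text data model and corpus I/O.

The unit of annotation is the sentence: a pre-tokenized word sequence with
typed entity spans (token-indexed, half-open) and/or a per-token IOB tag
sequence. Documents are ordered groups of sentences sharing a ``doc_id``;
a :class:`Corpus` is an ordered sequence of sentences plus free-form
metadata.

Two carrier formats are supported:

* CoNLL-style two-column files (``token TAG`` per line, blank line between
  sentences, ``-DOCSTART-`` lines opening a new document);
* JSON-lines documents, one sentence object per line, which additionally
  carry entity spans, typed relations, and corpus metadata losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence


class CorpusError(ValueError):
    """Raised for malformed corpora, annotations, or carrier files."""


@dataclass(frozen=True)
class Token:
    """A single word with its 0-based position in the sentence."""

    text: str
    index: int

    def __post_init__(self) -> None:
        if not self.text or any(c.isspace() for c in self.text):
            raise CorpusError(
                f"token text must be non-empty and whitespace-free: {self.text!r}"
            )
        if self.index < 0:
            raise CorpusError(f"token index must be >= 0, got {self.index}")


@dataclass(frozen=True, order=True)
class EntitySpan:
    """A typed entity mention: token indices ``[start, end)`` plus a label."""

    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise CorpusError(
                f"span must satisfy 0 <= start < end, got ({self.start}, {self.end})"
            )
        if not self.label:
            raise CorpusError("span label must be non-empty")

    def overlaps(self, other: "EntitySpan") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class Relation:
    """A typed directed relation between two spans of one sentence."""

    head: EntitySpan
    tail: EntitySpan
    label: str

    def __post_init__(self) -> None:
        if self.head.overlaps(self.tail):
            raise CorpusError("relation head and tail spans must be disjoint")


def _check_spans(spans: Sequence[EntitySpan], n_tokens: int) -> tuple:
    ordered = tuple(sorted(spans))
    for sp in ordered:
        if sp.end > n_tokens:
            raise CorpusError(
                f"span {sp} exceeds sentence length {n_tokens}"
            )
    for a, b in zip(ordered, ordered[1:]):
        if a.overlaps(b):
            raise CorpusError(f"overlapping spans: {a} and {b}")
    return ordered


@dataclass(frozen=True)
class AnnotatedSentence:
    """One sentence with optional gold spans, IOB tags, and relations.

    When both ``tags`` and ``spans`` are present they must agree under the
    IOB codec; :func:`clinmine.tagging.encode_iob` /
    :func:`~clinmine.tagging.decode_iob` define the correspondence.
    """

    doc_id: str
    sent_id: int
    tokens: tuple
    spans: tuple = ()
    tags: Optional[tuple] = None
    relations: tuple = ()

    def __post_init__(self) -> None:
        toks = tuple(
            t if isinstance(t, Token) else Token(str(t), i)
            for i, t in enumerate(self.tokens)
        )
        object.__setattr__(self, "tokens", toks)
        for i, t in enumerate(toks):
            if t.index != i:
                raise CorpusError(f"token index {t.index} at position {i}")
        object.__setattr__(self, "spans", _check_spans(tuple(self.spans), len(toks)))
        if self.tags is not None:
            tags = tuple(self.tags)
            if len(tags) != len(toks):
                raise CorpusError(
                    f"({self.doc_id}, {self.sent_id}): {len(tags)} tags for "
                    f"{len(toks)} tokens"
                )
            object.__setattr__(self, "tags", tags)
        for rel in self.relations:
            _check_spans([rel.head], len(toks))
            _check_spans([rel.tail], len(toks))

    @property
    def texts(self) -> tuple:
        return tuple(t.text for t in self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def span_text(self, span: EntitySpan) -> str:
        return " ".join(self.texts[span.start : span.end])

    def with_tags(self, tags: Sequence[str]) -> "AnnotatedSentence":
        return replace(self, tags=tuple(tags))


@dataclass
class Corpus:
    """An ordered collection of annotated sentences with free metadata."""

    sentences: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for s in self.sentences:
            key = (s.doc_id, s.sent_id)
            if key in seen:
                raise CorpusError(f"duplicate sentence key {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self) -> Iterator[AnnotatedSentence]:
        return iter(self.sentences)

    def __getitem__(self, i):
        return self.sentences[i]

    @property
    def doc_ids(self) -> list:
        """Document ids in first-appearance order."""
        out, seen = [], set()
        for s in self.sentences:
            if s.doc_id not in seen:
                seen.add(s.doc_id)
                out.append(s.doc_id)
        return out

    def documents(self) -> dict:
        """Sentences grouped by doc_id, preserving order."""
        docs: dict = {}
        for s in self.sentences:
            docs.setdefault(s.doc_id, []).append(s)
        return docs

    def subset(self, doc_ids: Iterable[str]) -> "Corpus":
        keep = set(doc_ids)
        return Corpus(
            [s for s in self.sentences if s.doc_id in keep], dict(self.metadata)
        )

    def labels(self) -> list:
        """Sorted entity-type labels present in spans or tags."""
        labs = set()
        for s in self.sentences:
            labs.update(sp.label for sp in s.spans)
            for t in s.tags or ():
                if t != "O" and len(t) > 2:
                    labs.add(t[2:])
        return sorted(labs)


def whitespace_tokenize(text: str) -> tuple:
    """Trivial whitespace tokenizer, for demos only — inputs normally
    arrive pre-tokenized."""
    return tuple(text.split())


# ---------------------------------------------------------------------------
# CoNLL two-column carrier


def read_conll(path) -> Corpus:
    """Read a two-column ``token TAG`` file into a :class:`Corpus`.

    Blank lines separate sentences; a line starting with ``-DOCSTART-``
    opens a new document. Tags must be ``O`` or ``B-x``/``I-x``. Spans are
    derived from the tags via the IOB codec.
    """
    from .tagging import decode_iob  # deferred: tagging imports corpus types

    path = Path(path)
    sentences: list = []
    cur_tokens: list = []
    cur_tags: list = []
    doc_idx = 0
    sent_idx = 0
    started_doc = False

    def flush() -> None:
        nonlocal sent_idx
        if not cur_tokens:
            return
        spans = decode_iob(cur_tags)
        sentences.append(
            AnnotatedSentence(
                doc_id=f"d{doc_idx}",
                sent_id=sent_idx,
                tokens=tuple(cur_tokens),
                spans=spans,
                tags=tuple(cur_tags),
            )
        )
        sent_idx += 1
        cur_tokens.clear()
        cur_tags.clear()

    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                flush()
                continue
            if line.startswith("-DOCSTART-"):
                flush()
                if started_doc:
                    doc_idx += 1
                    sent_idx = 0
                started_doc = True
                continue
            cols = line.split()
            if len(cols) != 2:
                raise CorpusError(
                    f"{path}:{lineno}: expected 2 columns, got {len(cols)}"
                )
            tok, tag = cols
            if not (tag == "O" or tag[:2] in ("B-", "I-")):
                raise CorpusError(f"{path}:{lineno}: malformed IOB tag {tag!r}")
            cur_tokens.append(tok)
            cur_tags.append(tag)
            started_doc = True
    flush()
    return Corpus(sentences)


def write_conll(corpus: Corpus, path) -> None:
    """Write a tagged corpus in two-column CoNLL form.

    Every sentence must carry tags; documents after the first are preceded
    by a ``-DOCSTART-`` line so that document grouping round-trips.
    """
    path = Path(path)
    lines: list = []
    prev_doc = None
    for s in corpus:
        if s.tags is None:
            raise CorpusError(
                f"sentence ({s.doc_id}, {s.sent_id}) lacks tags; cannot write CoNLL"
            )
        if prev_doc is not None and s.doc_id != prev_doc:
            lines.append("-DOCSTART- O")
            lines.append("")
        prev_doc = s.doc_id
        for tok, tag in zip(s.texts, s.tags):
            lines.append(f"{tok} {tag}")
        lines.append("")
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# ---------------------------------------------------------------------------
# JSON-lines carrier

_META_KEY = "_corpus_metadata"


def _span_to_json(sp: EntitySpan) -> list:
    return [sp.start, sp.end, sp.label]


def _rel_to_json(r: Relation) -> dict:
    return {
        "head": _span_to_json(r.head),
        "tail": _span_to_json(r.tail),
        "label": r.label,
    }


def read_docs_jsonl(path) -> Corpus:
    """Read a JSON-lines corpus: one sentence object per line.

    Each object carries ``doc_id``, ``sent_id``, ``tokens`` and optionally
    ``spans`` (``[start, end, label]`` triples), ``tags`` and ``relations``.
    A line holding only ``{"_corpus_metadata": {...}}`` restores corpus
    metadata.
    """
    path = Path(path)
    sentences: list = []
    metadata: dict = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusError(f"{path}:{lineno}: invalid JSON: {exc}") from exc
            if _META_KEY in obj:
                metadata.update(obj[_META_KEY])
                continue
            try:
                tokens = tuple(obj["tokens"])
                spans = tuple(EntitySpan(*sp) for sp in obj.get("spans", []))
                relations = tuple(
                    Relation(
                        EntitySpan(*r["head"]), EntitySpan(*r["tail"]), r["label"]
                    )
                    for r in obj.get("relations", [])
                )
                sentences.append(
                    AnnotatedSentence(
                        doc_id=str(obj["doc_id"]),
                        sent_id=int(obj["sent_id"]),
                        tokens=tokens,
                        spans=spans,
                        tags=tuple(obj["tags"]) if obj.get("tags") else None,
                        relations=relations,
                    )
                )
            except (KeyError, CorpusError, TypeError) as exc:
                raise CorpusError(f"{path}:{lineno}: {exc}") from exc
    return Corpus(sentences, metadata)


def write_docs_jsonl(corpus: Corpus, path) -> None:
    """Write a corpus as JSON-lines; lossless inverse of
    :func:`read_docs_jsonl`."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if corpus.metadata:
            fh.write(json.dumps({_META_KEY: corpus.metadata}, sort_keys=True) + "\n")
        for s in corpus:
            obj: dict = {
                "doc_id": s.doc_id,
                "sent_id": s.sent_id,
                "tokens": list(s.texts),
                "spans": [_span_to_json(sp) for sp in s.spans],
            }
            if s.tags is not None:
                obj["tags"] = list(s.tags)
            if s.relations:
                obj["relations"] = [_rel_to_json(r) for r in s.relations]
            fh.write(json.dumps(obj) + "\n")


def read_corpus(path) -> Corpus:
    """Dispatch on extension: ``.conll`` or ``.jsonl``."""
    p = Path(path)
    if p.suffix == ".conll":
        return read_conll(p)
    if p.suffix == ".jsonl":
        return read_docs_jsonl(p)
    raise CorpusError(f"unrecognized corpus extension: {p.suffix!r}")


def write_corpus(corpus: Corpus, path) -> None:
    p = Path(path)
    if p.suffix == ".conll":
        write_conll(corpus, p)
    elif p.suffix == ".jsonl":
        write_docs_jsonl(corpus, p)
    else:
        raise CorpusError(f"unrecognized corpus extension: {p.suffix!r}")
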