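"""Contextual word-vector layer: the first layer of the tagger stack.

The contract is a function from a token sequence to an ``L x d`` real
matrix, deterministic given its parameters. The built-in implementation is
a seeded hashed-lookup embedder: each lowercased token hashes to one of
``vocab_buckets`` rows of a trainable table, and row ``i`` of the output is
the mean of the looked-up vectors in the context window ``[i-w, i+w]``
(clipped to the sentence). The table is trained jointly with the tagger.

A pretrained contextual encoder (e.g. a fine-tuned biomedical transformer)
can be plugged in behind the same contract via :class:`EncoderAdapter`;
such adapters are frozen and are responsible for their own sub-word
alignment (first-subtoken pooling recommended). The tested core never
requires one.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np


class EncoderError(ValueError):
    pass


def token_bucket(text: str, n_buckets: int) -> int:
    """Stable 64-bit hash of the lowercased token, mod the bucket count."""
    digest = hashlib.blake2b(text.lower().encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "little") % n_buckets


@dataclass
class EmbedderParams:
    """Hashed-lookup embedder: seeded table plus a context window.

    ``table`` rows are i.i.d. Normal(0, 1/sqrt(dim)) draws from ``seed``,
    so the full parameter set is reproducible from (dim, vocab_buckets,
    window, seed) alone until training updates the table.
    """

    dim: int
    vocab_buckets: int
    window: int
    seed: int
    table: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise EncoderError(f"dim must be >= 1, got {self.dim}")
        if self.vocab_buckets < 1:
            raise EncoderError("vocab_buckets must be >= 1")
        if self.window < 0:
            raise EncoderError("window must be >= 0")
        if self.table is None:
            rng = np.random.default_rng(self.seed)
            scale = 1.0 / np.sqrt(self.dim)
            self.table = rng.normal(
                0.0, scale, size=(self.vocab_buckets, self.dim)
            )
        self.table = np.asarray(self.table, dtype=np.float64)
        if self.table.shape != (self.vocab_buckets, self.dim):
            raise EncoderError(
                f"table shape {self.table.shape} inconsistent with "
                f"({self.vocab_buckets}, {self.dim})"
            )

    def copy(self) -> "EmbedderParams":
        return EmbedderParams(
            self.dim, self.vocab_buckets, self.window, self.seed,
            table=self.table.copy(),
        )


def token_buckets(tokens: Sequence[str], params: EmbedderParams) -> np.ndarray:
    return np.array(
        [token_bucket(t, params.vocab_buckets) for t in tokens], dtype=np.int64
    )


def embed_tokens(tokens: Sequence[str], params: EmbedderParams) -> np.ndarray:
    """Embed a token sequence as an ``L x d`` matrix of windowed means."""
    if len(tokens) == 0:
        raise EncoderError("cannot embed an empty token sequence")
    buckets = token_buckets(tokens, params)
    vecs = params.table[buckets]  # L x d
    if params.window == 0:
        return vecs.copy()
    L = len(tokens)
    out = np.empty_like(vecs)
    w = params.window
    for i in range(L):
        lo, hi = max(0, i - w), min(L, i + w + 1)
        out[i] = vecs[lo:hi].mean(axis=0)
    return out


def embed_tokens_backward(
    tokens: Sequence[str], params: EmbedderParams, d_out: np.ndarray
) -> None:
    """Gradient of a loss w.r.t. the embedding table.

    ``d_out`` is the loss gradient at the embedder output (``L x d``); the
    windowed mean distributes each row equally over the buckets of the
    tokens in its window. Returns a dense table-shaped gradient.
    """
    buckets = token_buckets(tokens, params)
    L = len(tokens)
    w = params.window
    d_table = np.zeros_like(params.table)
    if w == 0:
        np.add.at(d_table, buckets, d_out)
        return d_table
    for i in range(L):
        lo, hi = max(0, i - w), min(L, i + w + 1)
        share = d_out[i] / (hi - lo)
        for j in range(lo, hi):
            d_table[buckets[j]] += share
    return d_table


@dataclass
class EncoderAdapter:
    """Frozen external encoder behind the embedding contract.

    ``fn`` maps a token-text sequence to an ``L x dim`` array. Used to slot
    a pretrained contextual model into the tagger without changing any
    downstream code; not trained and not serialized with models.
    """

    dim: int
    fn: Callable[[Sequence[str]], np.ndarray]

    def __call__(self, tokens: Sequence[str]) -> np.ndarray:
        out = np.asarray(self.fn(tokens), dtype=np.float64)
        if out.shape != (len(tokens), self.dim):
            raise EncoderError(
                f"adapter returned shape {out.shape}, expected "
                f"({len(tokens)}, {self.dim})"
            )
        return out
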