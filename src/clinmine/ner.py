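"""BiLSTM-CRF named-entity tagger.

Layer stack: contextual word vectors (see :mod:`clinmine.encoder`) feed a
bidirectional LSTM; the concatenated forward/backward hidden states pass
through an affine projection to per-tag emission scores; a linear-chain CRF
(:mod:`clinmine.crf`) scores whole tag sequences and constrains decoding to
the IOB2 chunk grammar.

The LSTM cell is the standard one — input/forget/output gates with a tanh
candidate, zero initial states:

    a = W x_t + U h_{t-1} + b,   a -> (a_i, a_f, a_o, a_g)
    i = sigma(a_i), f = sigma(a_f), o = sigma(a_o), g = tanh(a_g)
    c_t = f * c_{t-1} + i * g,   h_t = o * tanh(c_t)

Training minimizes the mean CRF negative log-likelihood by mini-batch SGD
with global-norm gradient clipping, gradients derived analytically
(posterior-minus-gold for the CRF, standard backpropagation-through-time
for the LSTM). The embedding table, LSTM weights, projection and CRF
transition matrix are all learned jointly. Transition constraints are hard
-inf masks applied at decode time by default; the training loss can also
be masked via config. Early stopping tracks dev-set entity micro-F1.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np

from . import crf
from .corpus import Corpus
from .encoder import EmbedderParams, embed_tokens, embed_tokens_backward
from .evaluation import entity_prf, token_accuracy
from .tagging import TagSet, allowed_transitions, decode_iob


class NERError(ValueError):
    pass


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class LSTMWeights:
    """One direction's cell parameters; gate order (i, f, o, g) stacked."""

    W: np.ndarray  # 4h x d
    U: np.ndarray  # 4h x h
    b: np.ndarray  # 4h

    @classmethod
    def init(cls, d: int, h: int, rng: np.random.Generator) -> "LSTMWeights":
        scale = 1.0 / np.sqrt(max(d, h))
        W = rng.normal(0.0, scale, size=(4 * h, d))
        U = rng.normal(0.0, scale, size=(4 * h, h))
        b = np.zeros(4 * h)
        b[h : 2 * h] = 1.0  # forget-gate bias: remember by default
        return cls(W, U, b)

    def zeros_like(self) -> "LSTMWeights":
        return LSTMWeights(
            np.zeros_like(self.W), np.zeros_like(self.U), np.zeros_like(self.b)
        )

    def copy(self) -> "LSTMWeights":
        return LSTMWeights(self.W.copy(), self.U.copy(), self.b.copy())


def lstm_forward(X: np.ndarray, w: LSTMWeights):
    """Run the cell left-to-right over rows of X; returns (H, cache)."""
    L, d = X.shape
    h = w.U.shape[1]
    H = np.zeros((L, h))
    cache = []
    h_prev = np.zeros(h)
    c_prev = np.zeros(h)
    for t in range(L):
        a = w.W @ X[t] + w.U @ h_prev + w.b
        i, f, o = (_sigmoid(a[:h]), _sigmoid(a[h : 2 * h]), _sigmoid(a[2 * h : 3 * h]))
        g = np.tanh(a[3 * h :])
        c = f * c_prev + i * g
        tanh_c = np.tanh(c)
        h_t = o * tanh_c
        cache.append((X[t], h_prev, c_prev, i, f, o, g, tanh_c))
        H[t] = h_t
        h_prev, c_prev = h_t, c
    return H, cache


def lstm_backward(cache, w: LSTMWeights, dH: np.ndarray):
    """Backpropagate dL/dH through the cell; returns (dX, dW grads)."""
    L = len(cache)
    h = w.U.shape[1]
    grads = w.zeros_like()
    dX = np.zeros((L, w.W.shape[1]))
    dh_next = np.zeros(h)
    dc_next = np.zeros(h)
    for t in range(L - 1, -1, -1):
        x_t, h_prev, c_prev, i, f, o, g, tanh_c = cache[t]
        dh = dH[t] + dh_next
        do = dh * tanh_c
        dc = dc_next + dh * o * (1.0 - tanh_c * tanh_c)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dc_next = dc * f
        da = np.concatenate(
            [
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                do * o * (1.0 - o),
                dg * (1.0 - g * g),
            ]
        )
        grads.W += np.outer(da, x_t)
        grads.U += np.outer(da, h_prev)
        grads.b += da
        dX[t] = w.W.T @ da
        dh_next = w.U.T @ da
    return dX, grads


@dataclass
class NERParams:
    """All learned parameters of the tagger plus its tag inventory."""

    embedder: EmbedderParams
    fwd: LSTMWeights
    bwd: LSTMWeights
    proj_W: np.ndarray  # 2h x T
    proj_b: np.ndarray  # T
    trans: np.ndarray  # (T+2) x (T+2)
    tagset: TagSet
    seed: int

    @property
    def hidden(self) -> int:
        return self.fwd.U.shape[1]

    def copy(self) -> "NERParams":
        return NERParams(
            self.embedder.copy(),
            self.fwd.copy(),
            self.bwd.copy(),
            self.proj_W.copy(),
            self.proj_b.copy(),
            self.trans.copy(),
            self.tagset,
            self.seed,
        )

    def arrays(self) -> dict:
        return {
            "table": self.embedder.table,
            "fwd_W": self.fwd.W, "fwd_U": self.fwd.U, "fwd_b": self.fwd.b,
            "bwd_W": self.bwd.W, "bwd_U": self.bwd.U, "bwd_b": self.bwd.b,
            "proj_W": self.proj_W, "proj_b": self.proj_b,
            "trans": self.trans,
        }

    def param_hash(self) -> str:
        """Stable digest of every learned array, for determinism checks."""
        h = hashlib.blake2b(digest_size=16)
        for name in sorted(self.arrays()):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.arrays()[name]).tobytes())
        return h.hexdigest()


@dataclass
class TrainConfig:
    """Tagger hyperparameters; ``seed`` is mandatory for reproducibility."""

    seed: int
    epochs: int = 30
    batch_size: int = 8
    lr: float = 0.3
    hidden: int = 8
    dim: int = 16
    clip: float = 5.0
    patience: int = 10
    vocab_buckets: int = 4096
    window: int = 0
    constrain_decode: bool = True
    constrain_loss: bool = False

    def __post_init__(self) -> None:
        for name in ("epochs", "batch_size", "lr", "hidden", "dim", "clip",
                     "patience", "vocab_buckets"):
            if getattr(self, name) <= 0:
                raise NERError(f"TrainConfig.{name} must be positive")
        if self.window < 0:
            raise NERError("window must be >= 0")


def init_params(tagset: TagSet, config: TrainConfig) -> NERParams:
    rng = np.random.default_rng(config.seed)
    d, h, T = config.dim, config.hidden, tagset.n_tags
    embedder = EmbedderParams(d, config.vocab_buckets, config.window,
                              seed=config.seed)
    fwd = LSTMWeights.init(d, h, rng)
    bwd = LSTMWeights.init(d, h, rng)
    proj_W = rng.normal(0.0, 1.0 / np.sqrt(2 * h), size=(2 * h, T))
    proj_b = np.zeros(T)
    trans = np.zeros((T + 2, T + 2))
    return NERParams(embedder, fwd, bwd, proj_W, proj_b, trans, tagset,
                     config.seed)


def compute_emissions(embeddings: np.ndarray, params: NERParams):
    """L x |T| emission scores; returns (emissions, cache) for backprop."""
    X = np.asarray(embeddings, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != params.embedder.dim:
        raise NERError(
            f"embedding matrix shape {X.shape} does not match dim "
            f"{params.embedder.dim}"
        )
    Hf, cache_f = lstm_forward(X, params.fwd)
    Hb_rev, cache_b = lstm_forward(X[::-1], params.bwd)
    Hb = Hb_rev[::-1]
    H = np.concatenate([Hf, Hb], axis=1)  # L x 2h
    E = H @ params.proj_W + params.proj_b
    return E, (X, cache_f, cache_b, H)


def emissions(embeddings: np.ndarray, params: NERParams) -> np.ndarray:
    return compute_emissions(embeddings, params)[0]


def _sentence_grads(sentence, params: NERParams, mask):
    """NLL and parameter gradients for one tagged sentence."""
    texts = sentence.texts
    X = embed_tokens(texts, params.embedder)
    E, (X, cache_f, cache_b, H) = compute_emissions(X, params)
    tag_idx = params.tagset.indices(sentence.tags)
    value, d_E, d_A = crf.nll_gradients(E, params.trans, tag_idx, mask)
    h = params.hidden
    d_proj_W = H.T @ d_E
    d_proj_b = d_E.sum(axis=0)
    dH = d_E @ params.proj_W.T  # L x 2h
    dXf, g_fwd = lstm_backward(cache_f, params.fwd, dH[:, :h])
    dXb_rev, g_bwd = lstm_backward(cache_b, params.bwd, dH[::-1, h:])
    dX = dXf + dXb_rev[::-1]
    d_table = embed_tokens_backward(texts, params.embedder, dX)
    return value, {
        "table": d_table,
        "fwd_W": g_fwd.W, "fwd_U": g_fwd.U, "fwd_b": g_fwd.b,
        "bwd_W": g_bwd.W, "bwd_U": g_bwd.U, "bwd_b": g_bwd.b,
        "proj_W": d_proj_W, "proj_b": d_proj_b,
        "trans": d_A,
    }


def _apply_update(params: NERParams, grads: dict, lr: float, clip: float) -> None:
    total_sq = sum(float(np.sum(g * g)) for g in grads.values())
    norm = np.sqrt(total_sq)
    scale = lr * (clip / norm if norm > clip else 1.0)
    arrs = params.arrays()
    for name, g in grads.items():
        arrs[name] -= scale * g


def predict_tags(sentences, params: NERParams, constrain: bool = True) -> list:
    """Constrained Viterbi tag sequences for each sentence."""
    mask = allowed_transitions(params.tagset) if constrain else None
    out = []
    for s in sentences:
        if len(s) == 0:
            out.append(())
            continue
        X = embed_tokens(s.texts, params.embedder)
        E = emissions(X, params)
        path = crf.viterbi(E, params.trans, mask)
        out.append(tuple(params.tagset.tags[i] for i in path))
    return out


def predict_entities(sentences, params: NERParams, constrain: bool = True) -> list:
    """Per-sentence entity span sets: embed -> BiLSTM -> constrained
    Viterbi -> IOB decode."""
    tag_seqs = predict_tags(sentences, params, constrain)
    return [decode_iob(tags) if tags else frozenset() for tags in tag_seqs]


def _gold_spans(sentence) -> frozenset:
    if sentence.spans:
        return frozenset(sentence.spans)
    if sentence.tags is not None:
        return decode_iob(sentence.tags)
    return frozenset()


def _dev_scores(dev: Corpus, params: NERParams, constrain: bool) -> tuple:
    tag_seqs = predict_tags(dev, params, constrain)
    pred_spans = [decode_iob(t) if t else frozenset() for t in tag_seqs]
    report = entity_prf([_gold_spans(s) for s in dev], pred_spans)
    acc = token_accuracy([s.tags for s in dev], tag_seqs)
    return report.f1, acc


def train_ner(train: Corpus, dev: Corpus, config: TrainConfig):
    """Train the tagger; returns (best-dev params, per-epoch history).

    History rows carry epoch index, mean train NLL, dev entity micro-F1
    and dev token accuracy. The parameters returned are those of the epoch
    with the highest dev F1 (ties to the earlier epoch); training stops
    early after ``patience`` epochs without improvement.
    """
    if len(train) == 0:
        raise NERError("training corpus is empty")
    for s in train:
        if s.tags is None:
            raise NERError(f"untagged training sentence ({s.doc_id}, {s.sent_id})")
    labels = sorted(set(train.labels()) | set(dev.labels()))
    tagset = TagSet(tuple(labels))
    for corpus_name, corp in (("train", train), ("dev", dev)):
        for s in corp:
            for t in s.tags or ():
                if t != "O" and t[2:] not in tagset.labels:
                    raise NERError(f"{corpus_name} tag {t!r} outside tagset")

    params = init_params(tagset, config)
    loss_mask = allowed_transitions(tagset) if config.constrain_loss else None
    rng = np.random.default_rng(config.seed + 1)

    history = []
    best = params.copy()
    best_f1 = -1.0
    since_best = 0
    n = len(train)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        total_loss = 0.0
        for lo in range(0, n, config.batch_size):
            batch = order[lo : lo + config.batch_size]
            agg: dict = {}
            for idx in batch:
                s = train[int(idx)]
                if len(s) == 0:
                    continue
                value, grads = _sentence_grads(s, params, loss_mask)
                total_loss += value
                for name, g in grads.items():
                    if name in agg:
                        agg[name] += g
                    else:
                        agg[name] = g
            if not agg:
                continue
            for name in agg:
                agg[name] /= len(batch)
            _apply_update(params, agg, config.lr, config.clip)
        dev_f1, dev_acc = _dev_scores(dev, params, config.constrain_decode) \
            if len(dev) else (0.0, 0.0)
        history.append(
            {
                "epoch": epoch,
                "train_nll": total_loss / n,
                "dev_f1": dev_f1,
                "dev_token_acc": dev_acc,
            }
        )
        if dev_f1 > best_f1:
            best_f1 = dev_f1
            best = params.copy()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    if len(dev) == 0:  # no dev set: return final params
        best = params
    return best, history


# ---------------------------------------------------------------------------
# Serialization: one .nermodel file = npz container with a JSON meta entry


def save_model(params: NERParams, path) -> None:
    meta = {
        "labels": list(params.tagset.labels),
        "seed": params.seed,
        "embedder": {
            "dim": params.embedder.dim,
            "vocab_buckets": params.embedder.vocab_buckets,
            "window": params.embedder.window,
            "seed": params.embedder.seed,
        },
    }
    arrays = {k: v for k, v in params.arrays().items()}
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode("utf-8"), dtype=np.uint8
    )
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_model(path) -> NERParams:
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"].tobytes()).decode("utf-8"))
        emb_meta = meta["embedder"]
        embedder = EmbedderParams(
            emb_meta["dim"], emb_meta["vocab_buckets"], emb_meta["window"],
            emb_meta["seed"], table=z["table"],
        )
        params = NERParams(
            embedder,
            LSTMWeights(z["fwd_W"], z["fwd_U"], z["fwd_b"]),
            LSTMWeights(z["bwd_W"], z["bwd_U"], z["bwd_b"]),
            z["proj_W"], z["proj_b"], z["trans"],
            TagSet(tuple(meta["labels"])), meta["seed"],
        )
    return params
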