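"""Emotion extraction network: a TextCNN pretrained on 3-class emotion
classification (positive / negative / neutral).

After pretraining the network is frozen and used only as a feature
extractor: the activation of its fully-connected layer is the per-post
emotion vector e_t, and a user's emotion representation v_emo is the
arithmetic mean (expectation) of the per-post vectors over their T posts.

Architecture: word embeddings -> parallel 1-D convolutions with three
filter heights (Z filters each) -> ReLU -> max-over-time pooling ->
concatenation -> fully-connected layer (the emotion vector) -> 3-class
output head. The output head uses an independent sigmoid per class by
default; a softmax head is available behind a config flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .corpus_io import EmotionCorpus, Vocabulary, tokenize_and_pad, EMOTION_LABELS
from .nn import Tensor


@dataclass
class EmotionNetConfig:
    filter_heights: tuple[int, ...] = (3, 4, 5)
    n_filters: int = 100          # Z filters per height
    hidden_dim: int = 128         # d_e, the emotion-vector dimension
    post_len: int = 32            # n, padded post length
    head: str = "sigmoid"         # "sigmoid" (default) or "softmax"
    lr: float = 1e-3
    max_epochs: int = 60
    batch_size: int = 64
    patience: int = 5
    dev_fraction: float = 0.15

    def validate(self) -> None:
        if len(set(self.filter_heights)) != len(self.filter_heights):
            raise ValueError("filter heights must be distinct")
        if self.post_len < max(self.filter_heights):
            raise ValueError("padded post length must be >= max filter height")
        if self.head not in ("sigmoid", "softmax"):
            raise ValueError("head must be 'sigmoid' or 'softmax'")


class TextCnnParams:
    """Parameter container for the emotion TextCNN."""

    def __init__(self, vocab: Vocabulary, config: EmotionNetConfig, seed: int):
        config.validate()
        self.config = config
        self.vocab = vocab
        rng = np.random.default_rng(seed)
        d = vocab.dim
        self.embedding = Tensor(vocab.embeddings.copy(), requires_grad=True)
        # one filter bank per height: shape (h*d, Z)
        self.filters: dict[int, Tensor] = {}
        self.filter_bias: dict[int, Tensor] = {}
        for h in config.filter_heights:
            limit = np.sqrt(6.0 / (h * d + config.n_filters))
            self.filters[h] = Tensor(
                rng.uniform(-limit, limit, size=(h * d, config.n_filters)),
                requires_grad=True,
            )
            self.filter_bias[h] = Tensor(np.zeros(config.n_filters), requires_grad=True)
        pooled_dim = config.n_filters * len(config.filter_heights)
        self.fc = nn.Linear(pooled_dim, config.hidden_dim, rng)
        self.out = nn.Linear(config.hidden_dim, len(EMOTION_LABELS), rng)

    def parameters(self) -> list[Tensor]:
        params = [self.embedding]
        for h in self.config.filter_heights:
            params += [self.filters[h], self.filter_bias[h]]
        return params + self.fc.parameters() + self.out.parameters()

    def state_arrays(self) -> dict[str, np.ndarray]:
        arrays = {"embedding": self.embedding.data}
        for h in self.config.filter_heights:
            arrays[f"filters_{h}"] = self.filters[h].data
            arrays[f"filter_bias_{h}"] = self.filter_bias[h].data
        arrays.update(fc_W=self.fc.W.data, fc_b=self.fc.b.data,
                      out_W=self.out.W.data, out_b=self.out.b.data)
        return arrays

    def param_hash(self) -> int:
        """Order-stable hash of all parameter bytes; used to assert freezing."""
        h = 0
        for name in sorted(self.state_arrays()):
            h ^= hash((name, self.state_arrays()[name].tobytes()))
        return h


def conv_feature(window: np.ndarray, filt: np.ndarray, bias: float,
                 activation: str = "relu") -> float:
    """Single convolution feature c = alpha(F . window + b) for one window of
    h consecutive word embeddings."""
    window = np.asarray(window, dtype=np.float64)
    filt = np.asarray(filt, dtype=np.float64)
    if window.shape != filt.shape:
        raise ValueError(f"window shape {window.shape} != filter shape {filt.shape}")
    z = float(np.sum(window * filt) + bias)
    if activation == "relu":
        return max(z, 0.0)
    if activation == "tanh":
        return float(np.tanh(z))
    raise ValueError(f"unknown activation {activation!r}")


def max_over_time(feature_map: np.ndarray) -> float:
    """Max-pooling over one feature map (the convolution outputs of one
    filter slid over the post)."""
    feature_map = np.asarray(feature_map, dtype=np.float64)
    if feature_map.size == 0:
        raise ValueError(
            "empty feature map: post length n is shorter than the filter "
            "height; pad posts to n >= max filter height"
        )
    return float(feature_map.max())


def _conv_bank(emb: Tensor, filt: Tensor, bias: Tensor, h: int) -> Tensor:
    """All windows of height h at once: emb (B, n, d) -> (B, n-h+1, Z).

    Implemented as a sum of shifted slices so gradients flow back into the
    embedding rows.
    """
    B, n, d = emb.shape
    m = n - h + 1
    Z = filt.shape[1]
    acc: Tensor | None = None
    for j in range(h):
        part = emb[:, j:j + m, :] @ filt[j * d:(j + 1) * d, :]
        acc = part if acc is None else acc + part
    return acc + bias


def textcnn_hidden(token_ids: np.ndarray, params: TextCnnParams) -> Tensor:
    """Batched forward to the FC layer: (B, n) int ids -> (B, d_e) hidden.

    The hidden activation is the emotion vector e_t.
    """
    cfg = params.config
    ids = np.atleast_2d(np.asarray(token_ids, dtype=np.int64))
    if ids.shape[1] < max(cfg.filter_heights):
        raise ValueError(
            f"post length {ids.shape[1]} < max filter height "
            f"{max(cfg.filter_heights)}; pad posts longer"
        )
    emb = params.embedding[ids]                     # (B, n, d)
    pooled = []
    for h in cfg.filter_heights:
        fmap = _conv_bank(emb, params.filters[h], params.filter_bias[h], h).relu()
        pooled.append(fmap.max(axis=1))             # (B, Z)
    o = nn.concat(pooled, axis=1)                   # (B, 3Z)
    return params.fc(o).relu()                      # (B, d_e)


def textcnn_forward(token_ids: np.ndarray,
                    params: TextCnnParams) -> tuple[np.ndarray, np.ndarray]:
    """Forward pass returning (class probabilities (B,3), emotion vectors
    (B, d_e)) as plain arrays (no gradient tracking)."""
    hidden = textcnn_hidden(token_ids, params)
    logits = params.out(hidden)
    if params.config.head == "softmax":
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        ez = np.exp(z)
        probs = ez / ez.sum(axis=1, keepdims=True)
    else:
        probs = 1.0 / (1.0 + np.exp(-logits.data))
    squeeze = np.asarray(token_ids).ndim == 1
    if squeeze:
        return probs[0], hidden.data[0]
    return probs, hidden.data


def _encode_corpus(corpus: EmotionCorpus, vocab: Vocabulary, n: int):
    X = np.stack([tokenize_and_pad(t, vocab, n) for t, _ in corpus.records])
    label_idx = {c: i for i, c in enumerate(EMOTION_LABELS)}
    y = np.asarray([label_idx[l] for _, l in corpus.records], dtype=np.int64)
    return X, y


def _head_loss(logits: Tensor, y: np.ndarray, head: str) -> Tensor:
    B = logits.shape[0]
    onehot = np.zeros((B, len(EMOTION_LABELS)))
    onehot[np.arange(B), y] = 1.0
    if head == "softmax":
        shift = logits - Tensor(logits.data.max(axis=1, keepdims=True))
        logz = shift.exp().sum(axis=1, keepdims=True).log()
        logp = shift - logz
        return -(logp * Tensor(onehot)).sum() * (1.0 / B)
    # independent per-class sigmoid with binary cross-entropy
    p = logits.sigmoid()
    eps = 1e-12
    one = Tensor(np.ones_like(onehot))
    return -(
        (Tensor(onehot) * (p + eps).log()
         + (one - Tensor(onehot)) * (one - p + eps).log()).sum()
    ) * (1.0 / B)


def pretrain_emotion_classifier(corpus: EmotionCorpus, vocab: Vocabulary,
                                config: EmotionNetConfig, seed: int,
                                return_history: bool = False):
    """Train the TextCNN on the emotion corpus until the held-out loss stops
    improving; returns the (to-be-frozen) parameters.

    Deterministic given (corpus, vocab, config, seed) on a single thread.
    """
    config.validate()
    counts = corpus.class_counts()
    missing = [c for c, k in counts.items() if k < 2]
    if missing:
        raise ValueError(f"emotion corpus needs >=2 examples per class; short: {missing}")
    params = TextCnnParams(vocab, config, seed)
    rng = np.random.default_rng(seed + 1)
    X, y = _encode_corpus(corpus, vocab, config.post_len)
    order = rng.permutation(len(y))
    n_dev = max(1, int(len(y) * config.dev_fraction))
    dev_idx, train_idx = order[:n_dev], order[n_dev:]
    opt = nn.Adam(params.parameters(), lr=config.lr)
    best_dev = np.inf
    best_state = {k: v.copy() for k, v in params.state_arrays().items()}
    stale = 0
    history: list[tuple[float, float]] = []
    for _epoch in range(config.max_epochs):
        perm = rng.permutation(train_idx)
        total = 0.0
        for start in range(0, len(perm), config.batch_size):
            batch = perm[start:start + config.batch_size]
            opt.zero_grad()
            logits = params.out(textcnn_hidden(X[batch], params))
            loss = _head_loss(logits, y[batch], config.head)
            loss.backward()
            opt.step()
            total += loss.item() * len(batch)
        dev_logits = params.out(textcnn_hidden(X[dev_idx], params))
        dev_loss = _head_loss(dev_logits, y[dev_idx], config.head).item()
        history.append((total / len(perm), dev_loss))
        if dev_loss < best_dev - 1e-4:
            best_dev = dev_loss
            best_state = {k: v.copy() for k, v in params.state_arrays().items()}
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    _load_state(params, best_state)
    if return_history:
        return params, history
    return params


def _load_state(params: TextCnnParams, state: dict[str, np.ndarray]) -> None:
    params.embedding.data = state["embedding"].copy()
    for h in params.config.filter_heights:
        params.filters[h].data = state[f"filters_{h}"].copy()
        params.filter_bias[h].data = state[f"filter_bias_{h}"].copy()
    params.fc.W.data = state["fc_W"].copy()
    params.fc.b.data = state["fc_b"].copy()
    params.out.W.data = state["out_W"].copy()
    params.out.b.data = state["out_b"].copy()


def emotion_vectors(token_ids: np.ndarray, params: TextCnnParams) -> np.ndarray:
    """Frozen feature extraction: (B, n) ids -> (B, d_e) emotion vectors."""
    return textcnn_hidden(token_ids, params).data


def user_emotion_expectation(vectors: np.ndarray) -> np.ndarray:
    """v_emo: arithmetic mean of a user's T per-post emotion vectors."""
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2 or vectors.shape[0] == 0:
        raise ValueError("need a non-empty (T, d_e) array of emotion vectors")
    return vectors.mean(axis=0)


def save_params(params: TextCnnParams, path) -> None:
    cfg = params.config
    meta = dict(filter_heights=list(cfg.filter_heights), n_filters=cfg.n_filters,
                hidden_dim=cfg.hidden_dim, post_len=cfg.post_len, head=cfg.head)
    np.savez(path, __meta__=np.frombuffer(repr(meta).encode(), dtype=np.uint8),
             **params.state_arrays())
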