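"""Sentence-level attention over the selected posts, fusion with the user
emotion vector, and the final 2-class softmax classifier.

Attention (default tanh-projected scoring, a bilinear form is available
behind a config switch):

    u_t    = tanh(W_s p_t + b_s)
    alpha  = masked_softmax_t(u_t . u_s)
    pooled = sum_t alpha_t p_t

The pooled vector is concatenated with the user's emotion expectation
v_emo and projected to two output neurons with a softmax; training uses
categorical cross-entropy averaged over the batch.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor

NEG_INF = -1e30
EPS = 1e-12


class AttentionParams:
    """Projection W_s, b_s and the trainable context vector u_s."""

    def __init__(self, post_dim: int, proj_dim: int, rng: np.random.Generator,
                 scoring: str = "tanh"):
        if scoring not in ("tanh", "bilinear"):
            raise ValueError("scoring must be 'tanh' or 'bilinear'")
        self.scoring = scoring
        self.proj = nn.Linear(post_dim, proj_dim, rng)
        self.context = Tensor(rng.uniform(-0.1, 0.1, size=proj_dim), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return self.proj.parameters() + [self.context]

    def scores(self, post_vectors: Tensor) -> Tensor:
        """Unnormalized attention logits: (..., M, post_dim) -> (..., M)."""
        if self.scoring == "tanh":
            return self.proj(post_vectors).tanh() @ self.context
        return self.proj(post_vectors) @ self.context


def masked_softmax(logits: Tensor, mask: np.ndarray) -> Tensor:
    """Softmax over the last axis restricted to mask==1 positions.

    Masked slots get weight exactly 0; the unmasked weights sum to 1.
    Raises if a row has no unmasked slot.
    """
    mask = np.asarray(mask, dtype=np.float64)
    if mask.shape != logits.shape:
        raise ValueError(f"mask shape {mask.shape} != logits shape {logits.shape}")
    if np.any(mask.sum(axis=-1) == 0):
        raise ValueError("masked softmax over an all-masked row (empty selection)")
    shifted = logits + Tensor((1.0 - mask) * NEG_INF)
    shifted = shifted - Tensor(shifted.data.max(axis=-1, keepdims=True))
    ez = shifted.exp() * Tensor(mask)
    return ez / ez.sum(axis=-1, keepdims=True)


def attention_weights(post_vectors: Tensor, mask: np.ndarray,
                      params: AttentionParams) -> Tensor:
    """Attention distribution over (padded) selected posts.

    post_vectors: (..., M, post_dim); mask: (..., M) with 1 = real post.
    """
    return masked_softmax(params.scores(post_vectors), mask)


def attention_pool(post_vectors: Tensor, weights: Tensor) -> Tensor:
    """Weighted sum of post vectors: (..., M, D) x (..., M) -> (..., D)."""
    w = weights.reshape(*weights.shape, 1)
    return (post_vectors * w).sum(axis=-2)


def uniform_weights(mask: np.ndarray) -> Tensor:
    """Uniform averaging weights over unmasked slots (the no-attention
    ablation: attention replaced by plain averaging)."""
    mask = np.asarray(mask, dtype=np.float64)
    denom = mask.sum(axis=-1, keepdims=True)
    if np.any(denom == 0):
        raise ValueError("uniform weights over an all-masked row")
    return Tensor(mask / denom)


class ClassifierParams:
    """Final 2-class head over [pooled ; v_emo]."""

    def __init__(self, fused_dim: int, rng: np.random.Generator):
        self.out = nn.Linear(fused_dim, 2, rng)

    def parameters(self) -> list[Tensor]:
        return self.out.parameters()


def softmax2(logits: Tensor) -> Tensor:
    shifted = logits - Tensor(logits.data.max(axis=-1, keepdims=True))
    ez = shifted.exp()
    return ez / ez.sum(axis=-1, keepdims=True)


def classify_user(pooled: Tensor, v_emo: Tensor | None,
                  params: ClassifierParams) -> Tensor:
    """2-class probabilities from the pooled posts representation fused with
    the emotion expectation (v_emo may be None for the no-emotion ablation)."""
    fused = pooled if v_emo is None else nn.concat([pooled, v_emo], axis=-1)
    return softmax2(params.out(fused))


def classification_loss(probs: Tensor, labels: np.ndarray) -> Tensor:
    """Categorical cross-entropy, averaged over the batch.

    `probs` rows are (P(class 0), P(class 1)); `labels` in {0,1}.
    Gold-class probabilities are clamped at 1e-12 before the log.
    """
    labels = np.asarray(labels, dtype=np.int64)
    B = probs.shape[0]
    onehot = np.zeros((B, 2))
    onehot[np.arange(B), labels] = 1.0
    return -((probs + EPS).log() * Tensor(onehot)).sum() * (1.0 / B)
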