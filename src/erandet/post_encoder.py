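"""BiLSTM post encoder.

Each post's word embeddings are run through a forward and a backward LSTM;
the post representation p_t is the concatenation of the final forward
hidden state and the final backward hidden state (dimension 2u).

PAD positions (token id 0) are masked: the recurrent state simply carries
through them, so appending PAD tokens never changes the encoding, and an
all-PAD post encodes to the zero vector.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import Tensor


class LstmParams:
    """One direction's gate parameters.

    The four gates (forget f, input i, output o, candidate g) each apply an
    affine map to the concatenation [h_{k-1}, x_k]:

        f_k = sigmoid(W_f . [h, x] + b_f)         i_k, o_k analogous
        g_k = tanh(W_c . [h, x] + b_c)
        c_k = f_k * c_{k-1} + i_k * g_k
        h_k = o_k * tanh(c_k)
    """

    GATES = ("f", "i", "o", "c")

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim
        limit = np.sqrt(6.0 / (input_dim + 2 * hidden_dim))
        self.W = {
            g: Tensor(rng.uniform(-limit, limit, size=(hidden_dim + input_dim, hidden_dim)),
                      requires_grad=True)
            for g in self.GATES
        }
        self.b = {g: Tensor(np.zeros(hidden_dim), requires_grad=True) for g in self.GATES}
        # start the forget gate open-ish: standard initialization
        self.b["f"].data[:] = 1.0

    def parameters(self) -> list[Tensor]:
        return [self.W[g] for g in self.GATES] + [self.b[g] for g in self.GATES]


def lstm_step(x: Tensor, h_prev: Tensor, c_prev: Tensor,
              params: LstmParams) -> tuple[Tensor, Tensor]:
    """One LSTM step over a batch: x (B, d), h_prev/c_prev (B, u)."""
    if x.shape[-1] != params.input_dim or h_prev.shape[-1] != params.hidden_dim:
        raise ValueError(
            f"shape mismatch: x dim {x.shape[-1]} (want {params.input_dim}), "
            f"h dim {h_prev.shape[-1]} (want {params.hidden_dim})"
        )
    hx = nn.concat([h_prev, x], axis=-1)
    f = (hx @ params.W["f"] + params.b["f"]).sigmoid()
    i = (hx @ params.W["i"] + params.b["i"]).sigmoid()
    o = (hx @ params.W["o"] + params.b["o"]).sigmoid()
    g = (hx @ params.W["c"] + params.b["c"]).tanh()
    c = f * c_prev + i * g
    h = o * c.tanh()
    return h, c


class BiLstmParams:
    """Forward + backward LSTM over a post; output dimension 2u."""

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.hidden_dim = hidden_dim
        self.forward = LstmParams(input_dim, hidden_dim, rng)
        self.backward = LstmParams(input_dim, hidden_dim, rng)

    @property
    def output_dim(self) -> int:
        return 2 * self.hidden_dim

    def parameters(self) -> list[Tensor]:
        return self.forward.parameters() + self.backward.parameters()


def _run_direction(emb: Tensor, mask: np.ndarray, params: LstmParams,
                   reverse: bool) -> Tensor:
    """Run one direction over (B, n, d) embeddings with a (B, n) PAD mask.

    Masked positions carry the previous state through unchanged; with
    right-padded sequences the reversed pass therefore idles over the PAD
    tail and starts at the last real token, ending at token 1.
    """
    B, n, _ = emb.shape
    u = params.hidden_dim
    h = Tensor(np.zeros((B, u)))
    c = Tensor(np.zeros((B, u)))
    steps = range(n - 1, -1, -1) if reverse else range(n)
    for t in steps:
        m = Tensor(mask[:, t:t + 1])
        h_new, c_new = lstm_step(emb[:, t, :], h, c, params)
        h = m * h_new + (1.0 - m) * h
        c = m * c_new + (1.0 - m) * c
    return h


def bilstm_encode(token_ids: np.ndarray, embedding: Tensor,
                  params: BiLstmParams) -> Tensor:
    """Encode padded posts: (B, n) int ids -> (B, 2u) post vectors.

    Returns [h_fwd_L ; h_bwd_1] per post; all-PAD posts encode to zeros.
    """
    ids = np.atleast_2d(np.asarray(token_ids, dtype=np.int64))
    mask = (ids != 0).astype(np.float64)
    emb = embedding[ids]
    h_fwd = _run_direction(emb, mask, params.forward, reverse=False)
    h_bwd = _run_direction(emb, mask, params.backward, reverse=True)
    out = nn.concat([h_fwd, h_bwd], axis=-1)
    if np.asarray(token_ids).ndim == 1:
        return out[0]
    return out
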