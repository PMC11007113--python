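"""A compact BERT-style transformer encoder (post-LayerNorm, learned positions).

Used by the masked-language-model embedder; there is deliberately no
next-sentence-prediction head — the training objective is MLM only.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, softmax
from .layers import Embedding, LayerNorm, Linear, Module


class MultiHeadAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.h = n_heads
        self.dh = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def forward(self, x: Tensor, attn_bias: np.ndarray | None = None) -> Tensor:
        B, L, d = x.shape

        def heads(t: Tensor) -> Tensor:
            return t.reshape(B, L, self.h, self.dh).transpose(0, 2, 1, 3)

        q, k, v = heads(self.wq(x)), heads(self.wk(x)), heads(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.dh))
        if attn_bias is not None:
            scores = scores + Tensor(attn_bias)  # (B,1,1,L) additive, -inf on PAD keys
        attn = softmax(scores, axis=-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(B, L, d)
        return self.wo(out)


class EncoderBlock(Module):
    def __init__(self, d_model: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        super().__init__()
        self.attn = MultiHeadAttention(d_model, n_heads, rng)
        self.ln1 = LayerNorm(d_model)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)
        self.ln2 = LayerNorm(d_model)

    def forward(self, x: Tensor, attn_bias: np.ndarray | None = None) -> Tensor:
        x = self.ln1(x + self.attn(x, attn_bias))
        x = self.ln2(x + self.ff2(self.ff1(x).relu()))
        return x


class TransformerEncoder(Module):
    """Token + position embeddings, N encoder blocks, and an MLM output head."""

    def __init__(self, vocab_size: int, d_model: int, n_layers: int, n_heads: int,
                 max_len: int, rng: np.random.Generator, d_ff: int | None = None):
        super().__init__()
        self.tok = Embedding(vocab_size, d_model, rng)
        self.pos = Embedding(max_len, d_model, rng)
        self.ln_in = LayerNorm(d_model)
        self.blocks = [EncoderBlock(d_model, n_heads, d_ff or 4 * d_model, rng)
                       for _ in range(n_layers)]
        self.mlm_head = Linear(d_model, vocab_size, rng)
        self.d_model = d_model
        self.max_len = max_len

    def hidden(self, ids: np.ndarray, valid: np.ndarray | None = None) -> Tensor:
        """Per-token hidden states: ids (B,L) -> (B,L,d_model)."""
        B, L = ids.shape
        if L > self.max_len:
            raise ValueError(f"sequence of {L} tokens exceeds max_len={self.max_len}")
        x = self.tok(ids) + self.pos(np.arange(L))
        bias = None
        if valid is not None and not valid.all():
            bias = np.where(valid[:, None, None, :], 0.0, -1e9)
        x = self.ln_in(x)
        for block in self.blocks:
            x = block(x, bias)
        return x

    def mlm_logits(self, ids: np.ndarray, valid: np.ndarray | None = None) -> Tensor:
        return self.mlm_head(self.hidden(ids, valid))
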