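"""Small transformer encoder for the sequence branch.

Learned token + position embeddings, post-norm encoder blocks
(multi-head self-attention with key-padding masking, then a two-layer
feed-forward sublayer), producing one d-dimensional state per input
token. Randomly initialized — it plays the architectural role of a
pretrained masked-language-model encoder at a size that trains on a desk
machine; any module with the same (ids, mask) -> (B, T, d) contract can
be plugged in instead.
"""

from __future__ import annotations

import numpy as np

from sleepscan.nn.layers import Dense, LayerNorm, ReLU

__all__ = ["MultiHeadSelfAttention", "TransformerBlock", "TransformerEncoder"]

_NEG = -1e9


class MultiHeadSelfAttention:
    def __init__(self, d: int, n_heads: int, rng: np.random.Generator):
        if d % n_heads:
            raise ValueError(f"model dim {d} not divisible by {n_heads} heads")
        self.d = d
        self.h = n_heads
        self.dk = d // n_heads
        self.wq = Dense(d, d, rng)
        self.wk = Dense(d, d, rng)
        self.wv = Dense(d, d, rng)
        self.wo = Dense(d, d, rng)
        self._cache = None

    def _split(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        return x.reshape(B, T, self.h, self.dk).transpose(0, 2, 1, 3)  # B,h,T,dk

    def _merge(self, x: np.ndarray) -> np.ndarray:
        B, h, T, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, h * dk)

    def forward(self, x: np.ndarray, mask: np.ndarray, train: bool = False) -> np.ndarray:
        q = self._split(self.wq.forward(x, train))
        k = self._split(self.wk.forward(x, train))
        v = self._split(self.wv.forward(x, train))
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.dk)  # B,h,T,T
        key_mask = mask[:, None, None, :]  # mask keys, not queries
        scores = np.where(key_mask > 0, scores, _NEG)
        scores -= scores.max(axis=-1, keepdims=True)
        e = np.exp(scores)
        attn = e / e.sum(axis=-1, keepdims=True)
        ctx = attn @ v
        out = self.wo.forward(self._merge(ctx), train)
        self._cache = (q, k, v, attn)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        q, k, v, attn = self._cache
        dctx = self._split(self.wo.backward(dout))
        dattn = dctx @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dctx
        # softmax backward (rows sum to 1)
        ds = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        ds /= np.sqrt(self.dk)
        dq = ds @ k
        dk_ = ds.transpose(0, 1, 3, 2) @ q
        dx = (
            self.wq.backward(self._merge(dq))
            + self.wk.backward(self._merge(dk_))
            + self.wv.backward(self._merge(dv))
        )
        return dx

    def _subs(self):
        return {"wq": self.wq, "wk": self.wk, "wv": self.wv, "wo": self.wo}

    def params(self):
        return {f"{n}.{k}": v for n, s in self._subs().items() for k, v in s.params().items()}

    def grads(self):
        return {f"{n}.{k}": v for n, s in self._subs().items() for k, v in s.grads().items()}


class TransformerBlock:
    """Post-norm encoder block: x -> LN(x + MHA(x)) -> LN(. + FFN(.))."""

    def __init__(self, d: int, n_heads: int, d_ff: int, rng: np.random.Generator):
        self.attn = MultiHeadSelfAttention(d, n_heads, rng)
        self.ln1 = LayerNorm(d)
        self.ff1 = Dense(d, d_ff, rng)
        self.relu = ReLU()
        self.ff2 = Dense(d_ff, d, rng)
        self.ln2 = LayerNorm(d)

    def forward(self, x: np.ndarray, mask: np.ndarray, train: bool = False) -> np.ndarray:
        a = self.ln1.forward(x + self.attn.forward(x, mask, train), train)
        f = self.ff2.forward(self.relu.forward(self.ff1.forward(a, train), train), train)
        return self.ln2.forward(a + f, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        da = self.ln2.backward(dout)
        df = self.ff1.backward(self.relu.backward(self.ff2.backward(da)))
        da = da + df
        dx = self.ln1.backward(da)
        return dx + self.attn.backward(dx)

    def _subs(self):
        return {"attn": self.attn, "ln1": self.ln1, "ff1": self.ff1,
                "ff2": self.ff2, "ln2": self.ln2}

    def params(self):
        return {f"{n}.{k}": v for n, s in self._subs().items() for k, v in s.params().items()}

    def grads(self):
        return {f"{n}.{k}": v for n, s in self._subs().items() for k, v in s.grads().items()}


class TransformerEncoder:
    """Token ids (B, T) -> contextual states (B, T, d)."""

    def __init__(self, n_vocab: int, d: int = 32, n_heads: int = 2, n_layers: int = 2,
                 d_ff: int = 64, max_len: int = 32, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        from sleepscan.nn.layers import Embedding

        self.tok = Embedding(n_vocab, d, rng)
        self.pos = rng.normal(0.0, 0.02, size=(max_len, d))
        self.dpos = np.zeros_like(self.pos)
        self.blocks = [TransformerBlock(d, n_heads, d_ff, rng) for _ in range(n_layers)]
        self.d = d
        self._T = None

    @property
    def out_dim(self) -> int:
        return self.d

    def forward(self, ids: np.ndarray, mask: np.ndarray, train: bool = False) -> np.ndarray:
        T = ids.shape[1]
        self._T = T
        x = self.tok.forward(ids, train) + self.pos[:T]
        for blk in self.blocks:
            x = blk.forward(x, mask, train)
        return x

    def backward(self, dout: np.ndarray) -> None:
        for blk in reversed(self.blocks):
            dout = blk.backward(dout)
        self.dpos[: self._T] += dout.sum(axis=0)
        self.tok.backward(dout)

    def params(self):
        out = {f"tok.{k}": v for k, v in self.tok.params().items()}
        out["pos"] = self.pos
        for i, blk in enumerate(self.blocks):
            out |= {f"blk{i}.{k}": v for k, v in blk.params().items()}
        return out

    def grads(self):
        out = {f"tok.{k}": v for k, v in self.tok.grads().items()}
        out["pos"] = self.dpos
        for i, blk in enumerate(self.blocks):
            out |= {f"blk{i}.{k}": v for k, v in blk.grads().items()}
        return out
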