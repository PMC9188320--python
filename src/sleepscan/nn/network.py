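"""The dual-branch parent network for candidate classification.

Structured branch: the 6 layout floats are batch-normalized, then pass
through two 100-unit feed-forward layers with 20% dropout each.
Sequence branch: the encoded 32-token segment goes through an encoder —
a 2-layer bidirectional LSTM over corpus-trained CBOW embeddings (the
second layer's final hidden state feeds onward) or a transformer encoder
(all token states flattened) — followed by a feed-forward layer.
The branches are concatenated and fully connected to a 200-unit
classifier layer with 20% dropout, ending in 3 sigmoid outputs
(per-class probabilities for AHI / SaO2 / Other; a softmax head is
available behind a flag). Setting ``use_structured=False`` omits the
structured branch entirely (the ablation architecture).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from sleepscan.nn.layers import (
    Adam,
    BatchNorm1d,
    Dense,
    Dropout,
    Embedding,
    ReLU,
    bce_with_logits,
    sigmoid,
    softmax_ce_with_logits,
)
from sleepscan.nn.lstm import BiLSTM
from sleepscan.nn.transformer import TransformerEncoder

__all__ = ["Encoder", "NetworkSpec", "DualBranchNet"]

N_STRUCTURED = 6  # 4 position indicators + page number + numeric value
N_CLASSES = 3


class Encoder(enum.Enum):
    BILSTM = "bilstm"
    TRANSFORMER = "transformer"


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture hyperparameters of the parent network."""

    encoder: Encoder = Encoder.BILSTM
    use_structured: bool = True
    max_len: int = 32
    emb_dim: int = 100          # BiLSTM path embedding width
    lstm_hidden: int = 100      # per direction, both layers
    tf_dim: int = 32            # transformer model width
    tf_heads: int = 2
    tf_layers: int = 2
    tf_ff: int = 64
    ffnn_struct: int = 100
    ffnn_seq: int = 100
    ffnn_head: int = 200
    dropout: float = 0.2
    loss: str = "sigmoid"       # "sigmoid" (per-class BCE) or "softmax"

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if self.max_len < 1:
            raise ValueError("max_len must be >= 1")
        if self.loss not in ("sigmoid", "softmax"):
            raise ValueError(f"unknown loss {self.loss!r}")


class DualBranchNet:
    """Trainable network mapping (structured, ids, mask) -> 3 class scores."""

    def __init__(self, spec: NetworkSpec, n_vocab: int, seed: int = 0,
                 pretrained_emb: np.ndarray | None = None):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(rng.integers(2**31))

        def drop():
            return Dropout(spec.dropout, self._dropout_rng)

        if spec.use_structured:
            self.bn = BatchNorm1d(N_STRUCTURED)
            self.s1 = Dense(N_STRUCTURED, spec.ffnn_struct, rng)
            self.s1r = ReLU()
            self.s1d = drop()
            self.s2 = Dense(spec.ffnn_struct, spec.ffnn_struct, rng)
            self.s2r = ReLU()
            self.s2d = drop()

        if spec.encoder is Encoder.BILSTM:
            if pretrained_emb is not None:
                if pretrained_emb.shape[1] != spec.emb_dim:
                    raise ValueError("pretrained embedding width != spec.emb_dim")
                self.emb = Embedding(pretrained_emb.shape[0], spec.emb_dim, rng,
                                     trainable=False, weights=pretrained_emb)
            else:
                self.emb = Embedding(n_vocab, spec.emb_dim, rng, trainable=True)
            self.lstm1 = BiLSTM(spec.emb_dim, spec.lstm_hidden, rng)
            self.lstm2 = BiLSTM(2 * spec.lstm_hidden, spec.lstm_hidden, rng)
            seq_out = 2 * spec.lstm_hidden
        else:
            self.encoder = TransformerEncoder(
                n_vocab, d=spec.tf_dim, n_heads=spec.tf_heads, n_layers=spec.tf_layers,
                d_ff=spec.tf_ff, max_len=spec.max_len, rng=rng,
            )
            seq_out = spec.max_len * spec.tf_dim

        self.q1 = Dense(seq_out, spec.ffnn_seq, rng)
        self.q1r = ReLU()
        self.q1d = drop()

        head_in = spec.ffnn_seq + (spec.ffnn_struct if spec.use_structured else 0)
        self.h1 = Dense(head_in, spec.ffnn_head, rng)
        self.h1r = ReLU()
        self.h1d = drop()
        self.out = Dense(spec.ffnn_head, N_CLASSES, rng)

    # -- module bookkeeping -------------------------------------------------

    def _modules(self) -> dict:
        names = ["q1", "h1", "out"]
        if self.spec.use_structured:
            names = ["bn", "s1", "s2"] + names
        if self.spec.encoder is Encoder.BILSTM:
            names += ["emb", "lstm1", "lstm2"]
        else:
            names += ["encoder"]
        return {n: getattr(self, n) for n in names}

    def param_pairs(self) -> list[tuple[np.ndarray, np.ndarray]]:
        pairs = []
        for mod in self._modules().values():
            p, g = mod.params(), mod.grads()
            for k in p:
                pairs.append((p[k], g[k]))
        return pairs

    def param_count(self) -> int:
        return sum(p.size for p, _ in self.param_pairs())

    def get_weights(self) -> list[np.ndarray]:
        w = [p.copy() for p, _ in self.param_pairs()]
        if self.spec.use_structured:
            w += [self.bn.running_mean.copy(), self.bn.running_var.copy()]
        return w

    def set_weights(self, weights: list[np.ndarray]) -> None:
        pairs = self.param_pairs()
        for (p, _), w in zip(pairs, weights):
            p[...] = w
        if self.spec.use_structured:
            self.bn.running_mean[...] = weights[len(pairs)]
            self.bn.running_var[...] = weights[len(pairs) + 1]

    def zero_grads(self) -> None:
        for _, g in self.param_pairs():
            g[...] = 0.0

    # -- forward / backward -------------------------------------------------

    def forward(self, structured: np.ndarray | None, ids: np.ndarray,
                mask: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits (B, 3)."""
        if self.spec.encoder is Encoder.BILSTM:
            x = self.emb.forward(ids, train)
            h1 = self.lstm1.forward(x, mask, train)
            h2 = self.lstm2.forward(h1, mask, train)
            self._T = ids.shape[1]
            seq = self.lstm2.last_state(h2)
        else:
            states = self.encoder.forward(ids, mask, train)
            seq = states.reshape(states.shape[0], -1)
        q = self.q1d.forward(self.q1r.forward(self.q1.forward(seq, train), train), train)

        if self.spec.use_structured:
            if structured is None:
                raise ValueError("network was built with a structured branch; structured input required")
            s = self.bn.forward(structured, train)
            s = self.s1d.forward(self.s1r.forward(self.s1.forward(s, train), train), train)
            s = self.s2d.forward(self.s2r.forward(self.s2.forward(s, train), train), train)
            z = np.concatenate([s, q], axis=1)
        else:
            z = q
        h = self.h1d.forward(self.h1r.forward(self.h1.forward(z, train), train), train)
        return self.out.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> None:
        dh = self.out.backward(dlogits)
        dz = self.h1.backward(self.h1r.backward(self.h1d.backward(dh)))
        if self.spec.use_structured:
            ns = self.spec.ffnn_struct
            ds, dq = dz[:, :ns], dz[:, ns:]
            ds = self.s2.backward(self.s2r.backward(self.s2d.backward(ds)))
            ds = self.s1.backward(self.s1r.backward(self.s1d.backward(ds)))
            self.bn.backward(ds)
        else:
            dq = dz
        dseq = self.q1.backward(self.q1r.backward(self.q1d.backward(dq)))
        if self.spec.encoder is Encoder.BILSTM:
            dh2 = self.lstm2.last_state_grad(dseq, self._T)
            dh1 = self.lstm2.backward(dh2)
            dx = self.lstm1.backward(dh1)
            self.emb.backward(dx)
        else:
            B = dseq.shape[0]
            self.encoder.backward(dseq.reshape(B, self.spec.max_len, self.spec.tf_dim))

    def loss_and_grad(self, logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
        if self.spec.loss == "sigmoid":
            return bce_with_logits(logits, targets)
        return softmax_ce_with_logits(logits, targets)

    def scores(self, logits: np.ndarray) -> np.ndarray:
        """Per-class scores in [0, 1] (sigmoid; softmax when configured)."""
        if self.spec.loss == "sigmoid":
            return sigmoid(logits)
        zs = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(zs)
        return e / e.sum(axis=1, keepdims=True)

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.param_pairs(), lr=lr)
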