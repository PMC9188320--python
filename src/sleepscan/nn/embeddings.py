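"""Corpus-trained CBOW word embeddings and segment encoding.

The sequence branch of the BiLSTM network uses 100-dimensional word
vectors trained on the training-set context windows with the continuous
bag-of-words objective: the mean of the context vectors predicts the
center token through a full softmax (vocabularies here are small).
Out-of-vocabulary tokens map to the zero vector.

Segment encoding pads/truncates whitespace tokens to a fixed length
(default 32) and returns ids plus the real-token mask. Id 0 is padding,
id 1 the out-of-vocabulary token.
"""

from __future__ import annotations

import numpy as np

__all__ = ["build_token_vocab", "encode_segment", "encode_batch", "train_cbow", "embedding_matrix"]

PAD_ID = 0
UNK_ID = 1
MAX_LEN = 32


def build_token_vocab(windows, min_count: int = 2, lowercase: bool = True) -> dict[str, int]:
    """Token -> id map from training windows (0/1 reserved for pad/unk).

    ``min_count`` drops hapax tokens (mostly the unique numeric strings),
    keeping the vocabulary compact.
    """
    counts: dict[str, int] = {}
    for w in windows:
        for t in w:
            t = t.lower() if lowercase else t
            counts[t] = counts.get(t, 0) + 1
    kept = sorted((t for t, c in counts.items() if c >= min_count), key=lambda t: (-counts[t], t))
    return {t: i + 2 for i, t in enumerate(kept)}


def encode_segment(window, vocab: dict[str, int], max_len: int = MAX_LEN,
                   lowercase: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Encode one window: (ids, mask), truncated/right-padded to max_len."""
    toks = [t.lower() if lowercase else t for t in window][:max_len]
    ids = np.full(max_len, PAD_ID, dtype=np.int64)
    mask = np.zeros(max_len)
    for i, t in enumerate(toks):
        ids[i] = vocab.get(t, UNK_ID)
        mask[i] = 1.0
    return ids, mask


def encode_batch(windows, vocab: dict[str, int], max_len: int = MAX_LEN) -> tuple[np.ndarray, np.ndarray]:
    ids = np.zeros((len(windows), max_len), dtype=np.int64)
    mask = np.zeros((len(windows), max_len))
    for i, w in enumerate(windows):
        ids[i], mask[i] = encode_segment(w, vocab, max_len)
    return ids, mask


def train_cbow(
    train_windows,
    dim: int = 100,
    context: int = 2,
    epochs: int = 3,
    lr: float = 0.05,
    min_count: int = 2,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Train CBOW vectors on the training windows; returns token -> vector.

    Full-softmax CBOW with linearly decaying learning rate; deterministic
    for a given seed. Unknown tokens are absent from the map (callers fall
    back to the zero vector).
    """
    if len(train_windows) == 0:
        raise ValueError("empty training corpus")
    vocab = build_token_vocab(train_windows, min_count=min_count)
    V = len(vocab)
    if V == 0:
        raise ValueError("no token occurs at least min_count times")
    rng = np.random.default_rng(seed)
    W_in = rng.uniform(-0.5 / dim, 0.5 / dim, size=(V, dim))
    W_out = np.zeros((V, dim))

    sents = []
    for w in train_windows:
        ids = [vocab[t.lower()] - 2 for t in w if t.lower() in vocab]
        if len(ids) >= 2:
            sents.append(np.array(ids))

    steps = sum(len(s) for s in sents) * epochs
    step = 0
    for _ in range(epochs):
        order = rng.permutation(len(sents))
        for si in order:
            s = sents[si]
            for pos in range(len(s)):
                lo = max(0, pos - context)
                ctx = np.concatenate([s[lo:pos], s[pos + 1 : pos + 1 + context]])
                step += 1
                if len(ctx) == 0:
                    continue
                alpha = lr * max(1e-4, 1 - step / max(steps, 1))
                h = W_in[ctx].mean(axis=0)
                z = W_out @ h
                z -= z.max()
                p = np.exp(z)
                p /= p.sum()
                p[s[pos]] -= 1.0
                dh = W_out.T @ p
                W_out -= alpha * np.outer(p, h)
                W_in[ctx] -= alpha * dh / len(ctx)

    return {t: W_in[i - 2].copy() for t, i in vocab.items()}


def embedding_matrix(vocab: dict[str, int], vectors: dict[str, np.ndarray], dim: int) -> np.ndarray:
    """Build an (|vocab|+2, dim) embedding table aligned to the id map.

    Rows 0 (padding) and 1 (out-of-vocabulary) are zero, as are rows for
    vocabulary tokens without a trained vector.
    """
    W = np.zeros((len(vocab) + 2, dim))
    for t, i in vocab.items():
        v = vectors.get(t)
        if v is not None:
            W[i] = v
    return W
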