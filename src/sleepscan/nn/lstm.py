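"""Mask-aware LSTM and bidirectional wrapper.

Sequences are right-padded; at padded steps the hidden and cell states
pass through unchanged, so the state at the final time step equals the
state after the last real token. The bidirectional layer runs a second
LSTM over the time-reversed sequence and concatenates features.
"""

from __future__ import annotations

import numpy as np

from sleepscan.nn.layers import sigmoid

__all__ = ["LSTM", "BiLSTM"]


class LSTM:
    """Single-direction LSTM over (B, T, D) inputs with a (B, T) mask."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(d_hidden)
        self.W = rng.uniform(-s, s, size=(d_in, 4 * d_hidden))
        self.U = rng.uniform(-s, s, size=(d_hidden, 4 * d_hidden))
        self.b = np.zeros(4 * d_hidden)
        # forget-gate bias of 1 for stable early training
        self.b[d_hidden : 2 * d_hidden] = 1.0
        self.dW = np.zeros_like(self.W)
        self.dU = np.zeros_like(self.U)
        self.db = np.zeros_like(self.b)
        self.H = d_hidden
        self._cache = None

    def forward(self, x: np.ndarray, mask: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, _ = x.shape
        H = self.H
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        hs = np.zeros((B, T, H))
        cache = []
        for t in range(T):
            m = mask[:, t][:, None]
            a = x[:, t] @ self.W + h @ self.U + self.b
            i = sigmoid(a[:, :H])
            f = sigmoid(a[:, H : 2 * H])
            g = np.tanh(a[:, 2 * H : 3 * H])
            o = sigmoid(a[:, 3 * H :])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            h_next = m * h_new + (1 - m) * h
            c_next = m * c_new + (1 - m) * c
            cache.append((x[:, t], h, c, i, f, g, o, c_new, tanh_c, m))
            h, c = h_next, c_next
            hs[:, t] = h
        self._cache = cache
        return hs

    def backward(self, dhs: np.ndarray) -> np.ndarray:
        cache = self._cache
        B, T, H = dhs.shape
        d_in = self.W.shape[0]
        dx = np.zeros((B, T, d_in))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in reversed(range(T)):
            x_t, h_prev, c_prev, i, f, g, o, c_new, tanh_c, m = cache[t]
            dh = dhs[:, t] + dh_next
            # through the mask select: padded rows pass state straight through
            dh_new = m * dh
            dh_prev_carry = (1 - m) * dh
            dc_new = m * dc_next
            dc_prev_carry = (1 - m) * dc_next

            do = dh_new * tanh_c
            dc = dh_new * o * (1 - tanh_c**2) + dc_new
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_prev = dc * f + dc_prev_carry

            da = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g**2), do * o * (1 - o)],
                axis=1,
            )
            self.dW += x_t.T @ da
            self.dU += h_prev.T @ da
            self.db += da.sum(axis=0)
            dx[:, t] = da @ self.W.T
            dh_next = da @ self.U.T + dh_prev_carry
            dc_next = dc_prev
        return dx

    def params(self):
        return {"W": self.W, "U": self.U, "b": self.b}

    def grads(self):
        return {"W": self.dW, "U": self.dU, "b": self.db}


class BiLSTM:
    """Bidirectional LSTM: (B, T, D) -> (B, T, 2H)."""

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator):
        self.fwd = LSTM(d_in, d_hidden, rng)
        self.bwd = LSTM(d_in, d_hidden, rng)
        self.H = d_hidden
        self._mask = None

    def forward(self, x: np.ndarray, mask: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = mask
        hf = self.fwd.forward(x, mask, train)
        hb = self.bwd.forward(x[:, ::-1], mask[:, ::-1], train)[:, ::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        H = self.H
        dxf = self.fwd.backward(dout[:, :, :H])
        dxb = self.bwd.backward(dout[:, ::-1, H:])[:, ::-1]
        return dxf + dxb

    def last_state(self, hs: np.ndarray) -> np.ndarray:
        """Final hidden state of each direction, concatenated (B, 2H).

        Forward direction: state at the last time step (mask carry makes
        this the last real token's state). Backward direction: its final
        state sits at original position 0 after re-reversal.
        """
        return np.concatenate([hs[:, -1, : self.H], hs[:, 0, self.H :]], axis=1)

    def last_state_grad(self, dlast: np.ndarray, T: int) -> np.ndarray:
        """Scatter a (B, 2H) last-state gradient into the (B, T, 2H) output grad."""
        B = dlast.shape[0]
        dout = np.zeros((B, T, 2 * self.H))
        dout[:, -1, : self.H] = dlast[:, : self.H]
        dout[:, 0, self.H :] = dlast[:, self.H :]
        return dout

    def params(self):
        return {f"fwd.{k}": v for k, v in self.fwd.params().items()} | {
            f"bwd.{k}": v for k, v in self.bwd.params().items()
        }

    def grads(self):
        return {f"fwd.{k}": v for k, v in self.fwd.grads().items()} | {
            f"bwd.{k}": v for k, v in self.bwd.grads().items()
        }
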