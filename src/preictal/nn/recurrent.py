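"""A single-layer LSTM with full backpropagation through time."""

from __future__ import annotations

import numpy as np

from .layers import Layer, _glorot_uniform

__all__ = ["LSTM"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _orthogonal(rng: np.random.Generator, n: int, cols: int, dtype) -> np.ndarray:
    """Column-stacked orthogonal blocks, the standard recurrent-weight init."""
    blocks = []
    for _ in range(cols // n + (1 if cols % n else 0)):
        q, r = np.linalg.qr(rng.standard_normal((n, n)))
        q *= np.sign(np.diag(r))
        blocks.append(q)
    return np.concatenate(blocks, axis=1)[:, :cols].astype(dtype)


class LSTM(Layer):
    """Processes a (B, T, D) batch of sequences; returns the final hidden
    state (B, H).  Gate order in the stacked weights is [input, forget,
    cell-candidate, output]; the forget-gate bias starts at 1 so early
    training does not erase the cell state.
    """

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        self.hidden = hidden
        self.params = {
            "Wx": _glorot_uniform(rng, (in_dim, 4 * hidden), in_dim, hidden,
                                  dtype),
            "Wh": _orthogonal(rng, hidden, 4 * hidden, dtype),
            "b": np.zeros(4 * hidden, dtype=dtype),
        }
        self.params["b"][hidden:2 * hidden] = 1.0  # forget gate

    def forward(self, x, train=False):
        b, t, _ = x.shape
        h_dim = self.hidden
        wx, wh, bias = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((b, h_dim), dtype=x.dtype)
        c = np.zeros((b, h_dim), dtype=x.dtype)
        gates = np.empty((t, b, 4 * h_dim), dtype=x.dtype)
        cells = np.empty((t, b, h_dim), dtype=x.dtype)
        hs = np.empty((t, b, h_dim), dtype=x.dtype)
        xw = x @ wx  # (B, T, 4H), the input contribution for every step
        for step in range(t):
            a = xw[:, step] + h @ wh + bias
            i = _sigmoid(a[:, :h_dim])
            f = _sigmoid(a[:, h_dim:2 * h_dim])
            g = np.tanh(a[:, 2 * h_dim:3 * h_dim])
            o = _sigmoid(a[:, 3 * h_dim:])
            c = f * c + i * g
            h = o * np.tanh(c)
            gates[step] = np.concatenate([i, f, g, o], axis=1)
            cells[step] = c
            hs[step] = h
        self._cache = (x, gates, cells, hs)
        return h

    def backward(self, dout):
        x, gates, cells, hs = self._cache
        b, t, d = x.shape
        h_dim = self.hidden
        wx, wh = self.params["Wx"], self.params["Wh"]
        dwx = np.zeros_like(wx)
        dwh = np.zeros_like(wh)
        db = np.zeros_like(self.params["b"])
        dx = np.empty_like(x)
        dh = dout.astype(x.dtype).copy()
        dc = np.zeros((b, h_dim), dtype=x.dtype)
        for step in range(t - 1, -1, -1):
            i = gates[step, :, :h_dim]
            f = gates[step, :, h_dim:2 * h_dim]
            g = gates[step, :, 2 * h_dim:3 * h_dim]
            o = gates[step, :, 3 * h_dim:]
            c = cells[step]
            c_prev = cells[step - 1] if step > 0 else np.zeros_like(c)
            h_prev = hs[step - 1] if step > 0 else np.zeros((b, h_dim),
                                                            dtype=x.dtype)
            tanh_c = np.tanh(c)
            do = dh * tanh_c
            dc = dc + dh * o * (1.0 - tanh_c * tanh_c)
            di, df, dg = dc * g, dc * c_prev, dc * i
            da = np.concatenate([
                di * i * (1.0 - i),
                df * f * (1.0 - f),
                dg * (1.0 - g * g),
                do * o * (1.0 - o),
            ], axis=1)
            dwx += x[:, step].T @ da
            dwh += h_prev.T @ da
            db += da.sum(axis=0)
            dx[:, step] = da @ wx.T
            dh = da @ wh.T
            dc = dc * f
        self.grads = {"Wx": dwx, "Wh": dwh, "b": db}
        return dx
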