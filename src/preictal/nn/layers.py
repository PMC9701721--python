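"""Feed-forward layers with explicit backpropagation."""

from __future__ import annotations

import numpy as np

__all__ = ["Layer", "Dense", "Conv2d", "BatchNorm2d", "ReLU", "MaxPool2d",
           "Dropout"]


class Layer:
    """Base layer: parameters, gradients and (non-trained) buffers."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.buffers: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{k}": v.copy() for k, v in self.params.items()}
        state.update({f"buffer:{k}": v.copy() for k, v in self.buffers.items()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            kind, name = k.split(":", 1)
            target = self.params if kind == "param" else self.buffers
            target[name][...] = v

    @property
    def n_params(self) -> int:
        return sum(v.size for v in self.params.values())


def _he_normal(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int,
                    fan_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Dense(Layer):
    """Affine map ``x @ W + b`` on (B, in_dim) inputs."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 relu_init: bool = True, dtype=np.float32) -> None:
        super().__init__()
        if relu_init:
            w = _he_normal(rng, (in_dim, out_dim), in_dim, dtype)
        else:
            w = _glorot_uniform(rng, (in_dim, out_dim), in_dim, out_dim, dtype)
        self.params = {"W": w, "b": np.zeros(out_dim, dtype=dtype)}

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout):
        self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["W"].T


class Conv2d(Layer):
    """2-D convolution, stride 1, same padding, on (B, C, H, W) inputs."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        self.pad = kernel // 2
        fan_in = in_ch * kernel * kernel
        self.params = {
            "W": _he_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in, dtype),
            "b": np.zeros(out_ch, dtype=dtype),
        }

    def forward(self, x, train=False):
        k, p = self.kernel, self.pad
        b, c, h, w = x.shape
        xpad = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        self._xpad, self._shape = xpad, x.shape
        weight = self.params["W"]
        out = np.zeros((b, weight.shape[0], h, w), dtype=x.dtype)
        for di in range(k):
            for dj in range(k):
                # (f,c) x (b,c,h,w) -> (b,f,h,w)
                out += np.einsum("fc,bchw->bfhw", weight[:, :, di, dj],
                                 xpad[:, :, di:di + h, dj:dj + w],
                                 optimize=True)
        return out + self.params["b"][None, :, None, None]

    def backward(self, dout):
        k, p = self.kernel, self.pad
        b, c, h, w = self._shape
        weight = self.params["W"]
        dw = np.zeros_like(weight)
        dxpad = np.zeros_like(self._xpad)
        for di in range(k):
            for dj in range(k):
                patch = self._xpad[:, :, di:di + h, dj:dj + w]
                dw[:, :, di, dj] = np.einsum("bfhw,bchw->fc", dout, patch,
                                             optimize=True)
                dxpad[:, :, di:di + h, dj:dj + w] += np.einsum(
                    "fc,bfhw->bchw", weight[:, :, di, dj], dout, optimize=True)
        self.grads = {"W": dw, "b": dout.sum(axis=(0, 2, 3))}
        return dxpad[:, :, p:p + h, p:p + w] if p else dxpad


class BatchNorm2d(Layer):
    """Per-feature-map batch normalization with running statistics."""

    def __init__(self, n_ch: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(n_ch, dtype=dtype),
                       "beta": np.zeros(n_ch, dtype=dtype)}
        self.buffers = {"running_mean": np.zeros(n_ch, dtype=dtype),
                        "running_var": np.ones(n_ch, dtype=dtype)}

    def forward(self, x, train=False):
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.buffers["running_mean"][...] = (
                m * self.buffers["running_mean"] + (1 - m) * mean)
            self.buffers["running_var"][...] = (
                m * self.buffers["running_var"] + (1 - m) * var)
        else:
            mean = self.buffers["running_mean"]
            var = self.buffers["running_var"]
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        self._xhat, self._inv_std, self._train = xhat, inv_std, train
        return (self.params["gamma"][None, :, None, None] * xhat
                + self.params["beta"][None, :, None, None])

    def backward(self, dout):
        axes = (0, 2, 3)
        xhat, inv_std = self._xhat, self._inv_std
        self.grads = {"gamma": (dout * xhat).sum(axis=axes),
                      "beta": dout.sum(axis=axes)}
        dxhat = dout * self.params["gamma"][None, :, None, None]
        if not self._train:
            return dxhat * inv_std[None, :, None, None]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        term = (dxhat - dxhat.mean(axis=axes, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=axes, keepdims=True))
        return term * inv_std[None, :, None, None]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2d(Layer):
    """Non-overlapping max pooling with floor semantics on odd extents."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x, train=False):
        s = self.size
        b, c, h, w = x.shape
        ho, wo = h // s, w // s
        if ho < 1 or wo < 1:
            raise ValueError(f"spatial extent {h}x{w} too small for {s}x{s} pooling")
        xc = x[:, :, :ho * s, :wo * s]
        patches = (xc.reshape(b, c, ho, s, wo, s)
                   .transpose(0, 1, 2, 4, 3, 5)
                   .reshape(b, c, ho, wo, s * s))
        self._argmax = patches.argmax(axis=-1)
        self._in_shape = x.shape
        return patches.max(axis=-1)

    def backward(self, dout):
        s = self.size
        b, c, h, w = self._in_shape
        ho, wo = h // s, w // s
        dpatch = np.zeros((b, c, ho, wo, s * s), dtype=dout.dtype)
        np.put_along_axis(dpatch, self._argmax[..., None], dout[..., None],
                          axis=-1)
        dx = np.zeros((b, c, h, w), dtype=dout.dtype)
        dx[:, :, :ho * s, :wo * s] = (
            dpatch.reshape(b, c, ho, wo, s, s)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(b, c, ho * s, wo * s))
        return dx


class Dropout(Layer):
    """Inverted dropout; active only when ``train=True``."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.p, self.rng = p, rng

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask
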