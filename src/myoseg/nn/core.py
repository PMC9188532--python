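"""Layers with forward/backward passes on NCHW numpy arrays."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "ReLU",
    "Dropout",
    "Dense",
    "GlobalAvgPool2d",
    "glorot_normal",
    "softmax",
]


def glorot_normal(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot (Xavier) normal initialization."""
    std = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, std, shape)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


class Module:
    """Base class: leaf layers hold ``params``/``grads`` dicts, composites hold children."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        #: parameter names subject to L2 regularization (weights, not biases/BN)
        self.reg_params: set[str] = set()
        self.children: list[Module] = []

    def leaves(self):
        """All leaf layers with parameters, depth-first."""
        if self.params:
            yield self
        for c in self.children:
            yield from c.leaves()

    def n_parameters(self) -> int:
        return sum(p.size for leaf in self.leaves() for p in leaf.params.values())

    def zero_grads(self) -> None:
        for leaf in self.leaves():
            for k in leaf.params:
                leaf.grads[k] = np.zeros_like(leaf.params[k])

    def state_dict(self) -> dict:
        out = {}
        for i, leaf in enumerate(self.leaves()):
            for k, v in leaf.params.items():
                out[f"{i}.{k}"] = v.copy()
            for k, v in getattr(leaf, "buffers", {}).items():
                out[f"{i}.buf.{k}"] = np.copy(v)
        return out

    def load_state_dict(self, state: dict) -> None:
        for i, leaf in enumerate(self.leaves()):
            for k in leaf.params:
                leaf.params[k] = state[f"{i}.{k}"].copy()
            for k in getattr(leaf, "buffers", {}):
                leaf.buffers[k] = np.copy(state[f"{i}.buf.{k}"])


def _same_pads(size: int, k: int, s: int) -> tuple[int, int]:
    """TensorFlow SAME padding: output = ceil(size / s)."""
    out = -(-size // s)
    total = max(0, (out - 1) * s + k - size)
    return total // 2, total - total // 2


class Conv2d(Module):
    """2D convolution (cross-correlation) with SAME padding, im2col matmul."""

    def __init__(self, cin: int, cout: int, k: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        fan_in, fan_out = cin * k * k, cout * k * k
        self.params = {
            "W": glorot_normal(rng, (cout, cin * k * k), fan_in, fan_out),
            "b": np.zeros(cout),
        }
        self.reg_params = {"W"}
        self.zero_grads()

    def _im2col(self, x: np.ndarray):
        n, c, h, w = x.shape
        k, s = self.k, self.stride
        pt, pb = _same_pads(h, k, s)
        pl, pr = _same_pads(w, k, s)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        ho, wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * ho * wo, c * k * k
        )
        return cols, (n, c, h, w, ho, wo, pt, pb, pl, pr)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        cols, geom = self._im2col(x)
        n, _, _, _, ho, wo = geom[:6]
        out = cols @ self.params["W"].T + self.params["b"]
        self._cache = (cols, geom)
        return out.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, geom = self._cache
        n, c, h, w, ho, wo, pt, pb, pl, pr = geom
        k, s = self.k, self.stride
        dmat = dout.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.cout)
        self.grads["W"] += dmat.T @ cols
        self.grads["b"] += dmat.sum(axis=0)
        dcols = (dmat @ self.params["W"]).reshape(n, ho, wo, c, k, k).transpose(
            0, 3, 1, 2, 4, 5
        )
        dxp = np.zeros((n, c, h + pt + pb, w + pl + pr))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * (ho - 1) + 1 : s, j : j + s * (wo - 1) + 1 : s] += dcols[
                    :, :, :, :, i, j
                ]
        return dxp[:, :, pt : pt + h, pl : pl + w]


class ConvTranspose2d(Module):
    """Transposed convolution upsampling by ``stride`` (output = input * stride).

    Forward is the input-gradient of a SAME-padded Conv2d; backward is that
    convolution's forward.
    """

    def __init__(self, cin: int, cout: int, k: int, stride: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        fan_in, fan_out = cin * k * k, cout * k * k
        self.params = {
            "W": glorot_normal(rng, (cin, cout * k * k), fan_in, fan_out),
            "b": np.zeros(cout),
        }
        self.reg_params = {"W"}
        self.zero_grads()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, s = self.k, self.stride
        ho, wo = h * s, w * s  # output plays the conv-input role
        pt, pb = _same_pads(ho, k, s)
        pl, pr = _same_pads(wo, k, s)
        xmat = x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        dcols = (xmat @ self.params["W"]).reshape(n, h, w, self.cout, k, k).transpose(
            0, 3, 1, 2, 4, 5
        )
        outp = np.zeros((n, self.cout, ho + pt + pb, wo + pl + pr))
        for i in range(k):
            for j in range(k):
                outp[:, :, i : i + s * (h - 1) + 1 : s, j : j + s * (w - 1) + 1 : s] += dcols[
                    :, :, :, :, i, j
                ]
        out = outp[:, :, pt : pt + ho, pl : pl + wo] + self.params["b"][None, :, None, None]
        self._cache = (x, (n, c, h, w, ho, wo, pt, pb, pl, pr))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, geom = self._cache
        n, c, h, w, ho, wo, pt, pb, pl, pr = geom
        k, s = self.k, self.stride
        dp = np.pad(dout, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        win = sliding_window_view(dp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, self.cout * k * k
        )
        xmat = x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        self.grads["W"] += xmat.T @ cols
        self.grads["b"] += dout.sum(axis=(0, 2, 3))
        dx = (cols @ self.params["W"].T).reshape(n, h, w, c).transpose(0, 3, 1, 2)
        return dx


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params = {"gamma": np.ones(c), "beta": np.zeros(c)}
        self.buffers = {"mean": np.zeros(c), "var": np.ones(c)}
        self.zero_grads()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.buffers["mean"] = m * self.buffers["mean"] + (1 - m) * mean
            self.buffers["var"] = m * self.buffers["var"] + (1 - m) * var
        else:
            mean, var = self.buffers["mean"], self.buffers["var"]
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, train, x.shape)
        return self.params["gamma"][None, :, None, None] * xhat + self.params["beta"][
            None, :, None, None
        ]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, train, shape = self._cache
        self.grads["gamma"] += np.sum(dout * xhat, axis=(0, 2, 3))
        self.grads["beta"] += np.sum(dout, axis=(0, 2, 3))
        g = self.params["gamma"][None, :, None, None]
        if not train:
            return dout * g * inv[None, :, None, None]
        m = shape[0] * shape[2] * shape[3]
        dxhat = dout * g
        term = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        )
        return term * inv[None, :, None, None]


class ReLU(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class Dropout(Module):
    """Pixelwise inverted dropout; identity in eval mode or at rate 0."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Dense(Module):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator):
        super().__init__()
        self.params = {
            "W": glorot_normal(rng, (nin, nout), nin, nout),
            "b": np.zeros(nout),
        }
        self.reg_params = {"W"}
        self.zero_grads()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"] += self._x.T @ dout
        self.grads["b"] += dout.sum(axis=0)
        return dout @ self.params["W"].T


class GlobalAvgPool2d(Module):
    def __init__(self):
        super().__init__()

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None], self._shape) / (h * w)
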