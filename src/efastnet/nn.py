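"""Minimal convolutional-network engine (numpy, CPU).

Implements exactly the layer vocabulary the eFAST model family needs —
2-D convolution with "same" padding, ReLU, 2x2 max pooling, dense heads,
dropout — with explicit forward/backward passes so that training, early
stopping and Grad-CAM all share one code path.  Arrays are NCHW float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "Flatten",
    "Dense",
    "Dropout",
    "Sequential",
    "SGDM",
    "Adam",
    "RMSprop",
    "make_optimizer",
]


class Layer:
    """Base layer: parameters in ``params``, matching gradients in ``grads``."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _same_pad(k: int) -> tuple[int, int]:
    # total pad k-1, split left-heavy for even kernels (TF/MATLAB 'same')
    total = k - 1
    return total // 2, total - total // 2


class Conv2D(Layer):
    """2-D convolution, stride 1, 'same' padding, He-normal init."""

    def __init__(self, in_ch: int, out_ch: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.in_ch, self.out_ch, self.k = in_ch, out_ch, k
        fan_in = in_ch * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_ch))
        self.params = {"W": w.astype(np.float32),
                       "b": np.zeros(out_ch, dtype=np.float32)}
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._cache = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p0, p1 = _same_pad(self.k)
        xp = np.pad(x, ((0, 0), (0, 0), (p0, p1), (p0, p1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        # (n, c, h, w, k, k) -> (n*h*w, c*k*k)
        col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        return np.ascontiguousarray(col, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        col = self._im2col(x)
        out = col @ self.params["W"] + self.params["b"]
        self._cache = (x.shape, col)
        return out.reshape(n, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        (n, c, h, w), col = self._cache
        dflat = np.ascontiguousarray(
            dout.transpose(0, 2, 3, 1), dtype=np.float32
        ).reshape(n * h * w, self.out_ch)
        self.grads["W"][...] = col.T @ dflat
        self.grads["b"][...] = dflat.sum(axis=0)
        dcol = dflat @ self.params["W"].T  # (n*h*w, c*k*k)
        dcol = dcol.reshape(n, h, w, c, self.k, self.k)
        p0, p1 = _same_pad(self.k)
        dxp = np.zeros((n, c, h + p0 + p1, w + p0 + p1), dtype=np.float32)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i:i + h, j:j + w] += dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p0:p0 + h, p0:p0 + w]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pool, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        hh, ww = h // 2, w // 2
        xc = x[:, :, : hh * 2, : ww * 2]
        patches = xc.reshape(n, c, hh, 2, ww, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, hh, ww, 4)
        self._argmax = patches.argmax(axis=-1)
        self._in_shape = x.shape
        return np.take_along_axis(patches, self._argmax[..., None], axis=-1)[..., 0]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._in_shape
        hh, ww = h // 2, w // 2
        dpatch = np.zeros((n, c, hh, ww, 4), dtype=np.float32)
        np.put_along_axis(dpatch, self._argmax[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        dx[:, :, : hh * 2, : ww * 2] = dpatch.reshape(
            n, c, hh, ww, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, hh * 2, ww * 2)
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.params = {"W": w.astype(np.float32),
                       "b": np.zeros(n_out, dtype=np.float32)}
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["W"][...] = self._x.T @ dout
        self.grads["b"][...] = dout.sum(axis=0)
        return dout @ self.params["W"].T


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self._rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self._rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dout
        return dout * self._mask


class Sequential:
    """Layer stack with whole-network forward/backward and weight snapshots."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray, upto: int = 0) -> np.ndarray:
        """Backprop ``dout`` through layers [upto, end) in reverse.

        ``upto`` > 0 stops early and returns the gradient flowing *into*
        layer ``upto`` — used by Grad-CAM to get d(score)/d(feature map).
        """
        for layer in reversed(self.layers[upto:]):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer.params[name], layer.grads[name]

    def param_count(self) -> int:
        return int(sum(p.size for p, _ in self.parameters()))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for (p, _), w in zip(self.parameters(), weights, strict=True):
            p[...] = w

    def last_conv_index(self) -> int:
        idx = [i for i, l in enumerate(self.layers) if isinstance(l, Conv2D)]
        if not idx:
            raise ValueError("network has no convolutional layer")
        return idx[-1]


class _Optimizer:
    def __init__(self, lr: float):
        self.lr = lr
        self._state: dict[int, dict] = {}

    def _slot(self, key: int, like: np.ndarray, names: tuple[str, ...]) -> dict:
        if key not in self._state:
            self._state[key] = {n: np.zeros_like(like) for n in names}
        return self._state[key]

    def step(self, net: Sequential) -> None:
        for i, (p, g) in enumerate(net.parameters()):
            self._update(i, p, g)

    def _update(self, key: int, p: np.ndarray, g: np.ndarray) -> None:
        raise NotImplementedError


class SGDM(_Optimizer):
    """Stochastic gradient descent with momentum (0.9)."""

    def __init__(self, lr: float, momentum: float = 0.9):
        super().__init__(lr)
        self.momentum = momentum

    def _update(self, key, p, g):
        s = self._slot(key, p, ("v",))
        s["v"][...] = self.momentum * s["v"] - self.lr * g
        p += s["v"]


class Adam(_Optimizer):
    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self._t = 0

    def step(self, net: Sequential) -> None:
        self._t += 1
        super().step(net)

    def _update(self, key, p, g):
        s = self._slot(key, p, ("m", "v"))
        s["m"][...] = self.beta1 * s["m"] + (1 - self.beta1) * g
        s["v"][...] = self.beta2 * s["v"] + (1 - self.beta2) * g * g
        mhat = s["m"] / (1 - self.beta1 ** self._t)
        vhat = s["v"] / (1 - self.beta2 ** self._t)
        p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class RMSprop(_Optimizer):
    def __init__(self, lr: float, rho: float = 0.9, eps: float = 1e-8):
        super().__init__(lr)
        self.rho, self.eps = rho, eps

    def _update(self, key, p, g):
        s = self._slot(key, p, ("v",))
        s["v"][...] = self.rho * s["v"] + (1 - self.rho) * g * g
        p -= self.lr * g / (np.sqrt(s["v"]) + self.eps)


_OPTIMIZERS = {"SGDM": SGDM, "ADAM": Adam, "RMSprop": RMSprop}


def make_optimizer(name: str, lr: float) -> _Optimizer:
    try:
        cls = _OPTIMIZERS[name]
    except KeyError:
        raise ValueError(f"unknown optimizer {name!r}; choose from {sorted(_OPTIMIZERS)}")
    return cls(lr)
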