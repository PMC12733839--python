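"""Minimal CPU neural-network primitives with manual backpropagation.

Implements exactly the pieces the parameter-prediction network and the
Grad-CAM analysis need: 3x3 same-padding convolution, batch normalization,
ReLU, 2x2 max pooling, adaptive average pooling, linear layers, inverted
dropout, and an Adam optimizer.  Everything is plain numpy, seeded through
``numpy.random.Generator``, and every layer caches what its backward pass
needs so gradients with respect to both parameters and activations are
available (the latter is what Grad-CAM consumes).

Layout convention is NCHW; all computations are float64 for reproducible
gradient checks.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2",
    "AdaptiveAvgPool2d",
    "Flatten",
    "Linear",
    "Dropout",
    "Sequential",
    "Adam",
    "softmax",
    "cross_entropy_grad",
]


class Layer:
    """Base class: forward caches, backward returns grad w.r.t. the input."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_pairs(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """(parameter, gradient) pairs; gradients are overwritten per backward."""
        return []


class Conv2d(Layer):
    """3x3 convolution, stride 1, zero same-padding, via im2col."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * 9
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, fan_in))
        self.b = np.zeros(c_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        # (N, C, H, W, 3, 3) -> (N, C*9, H*W)
        win = sliding_window_view(xp, (3, 3), axis=(2, 3))
        cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * 9, h * w)
        self._cols = cols
        self._shape = (n, c, h, w)
        out = np.matmul(self.W, cols) + self.b[:, None]
        return out.reshape(n, self.c_out, h, w)

    def backward(self, gout):
        n, c, h, w = self._shape
        g2 = gout.reshape(n, self.c_out, h * w)
        self.gW[...] = np.einsum("nof,ncf->oc", g2, self._cols)
        self.gb[...] = g2.sum(axis=(0, 2))
        gcols = np.matmul(self.W.T, g2).reshape(n, c, 3, 3, h, w)
        gpad = np.zeros((n, c, h + 2, w + 2))
        for di in range(3):
            for dj in range(3):
                gpad[:, :, di:di + h, dj:dj + w] += gcols[:, :, di, dj]
        return gpad[:, :, 1:-1, 1:-1]

    def param_pairs(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.ggamma = np.zeros(c)
        self.gbeta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train=False):
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[:, None, None]) * ivar[:, None, None]
        self._xhat, self._ivar, self._train = xhat, ivar, train
        return self.gamma[:, None, None] * xhat + self.beta[:, None, None]

    def backward(self, gout):
        xhat, ivar = self._xhat, self._ivar
        self.ggamma[...] = (gout * xhat).sum(axis=(0, 2, 3))
        self.gbeta[...] = gout.sum(axis=(0, 2, 3))
        gxhat = gout * self.gamma[:, None, None]
        if not self._train:
            # running statistics are constants at inference
            return gxhat * ivar[:, None, None]
        n, _, h, w = gout.shape
        m = n * h * w
        s1 = gxhat.sum(axis=(0, 2, 3))[:, None, None]
        s2 = (gxhat * xhat).sum(axis=(0, 2, 3))[:, None, None]
        return (ivar[:, None, None] / m) * (m * gxhat - s1 - xhat * s2)

    def param_pairs(self):
        return [(self.gamma, self.ggamma), (self.beta, self.gbeta)]


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are dropped."""

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        hh, ww = h // 2, w // 2
        xt = x[:, :, : 2 * hh, : 2 * ww].reshape(n, c, hh, 2, ww, 2)
        xt = xt.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, hh, ww, 4)
        self._arg = xt.argmax(axis=-1)
        self._shape = (n, c, h, w)
        return xt.max(axis=-1)

    def backward(self, gout):
        n, c, h, w = self._shape
        hh, ww = h // 2, w // 2
        g4 = np.zeros((n, c, hh, ww, 4))
        np.put_along_axis(g4, self._arg[..., None], gout[..., None], axis=-1)
        g = g4.reshape(n, c, hh, ww, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        gin = np.zeros((n, c, h, w))
        gin[:, :, : 2 * hh, : 2 * ww] = g.reshape(n, c, 2 * hh, 2 * ww)
        return gin


class AdaptiveAvgPool2d(Layer):
    """Average pooling onto a fixed output grid (torch-style bin edges)."""

    def __init__(self, out_size: int):
        self.out_size = out_size

    @staticmethod
    def _edges(n_in: int, n_out: int):
        starts = (np.arange(n_out) * n_in) // n_out
        ends = -((-(np.arange(1, n_out + 1) * n_in)) // n_out)  # ceil
        return starts, ends

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        s = self.out_size
        rs, re = self._edges(h, s)
        cs, ce = self._edges(w, s)
        out = np.empty((n, c, s, s))
        for i in range(s):
            for j in range(s):
                out[:, :, i, j] = x[:, :, rs[i]:re[i], cs[j]:ce[j]].mean(axis=(2, 3))
        self._shape = (n, c, h, w)
        return out

    def backward(self, gout):
        n, c, h, w = self._shape
        s = self.out_size
        rs, re = self._edges(h, s)
        cs, ce = self._edges(w, s)
        gin = np.zeros((n, c, h, w))
        for i in range(s):
            for j in range(s):
                area = (re[i] - rs[i]) * (ce[j] - cs[j])
                gin[:, :, rs[i]:re[i], cs[j]:ce[j]] += gout[:, :, i, j][:, :, None, None] / area
        return gin


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, gout):
        self.gW[...] = gout.T @ self._x
        self.gb[...] = gout.sum(axis=0)
        return gout @ self.W

    def param_pairs(self):
        return [(self.W, self.gW), (self.b, self.gb)]


class Dropout(Layer):
    """Inverted dropout; identity at inference.  Draws from its own rng."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, gout):
        return gout if self._mask is None else gout * self._mask


class Sequential(Layer):
    """Layer chain that records per-layer outputs and output-gradients.

    ``activations[i]`` is the output of ``layers[i]`` from the latest
    forward pass, and ``output_grads[i]`` the gradient of the scalar being
    backpropagated with respect to that output — the two quantities
    Grad-CAM needs at its target layer.
    """

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        self.activations: list[np.ndarray] = []
        self.output_grads: list[np.ndarray | None] = []

    def forward(self, x, train=False):
        self.activations = []
        for layer in self.layers:
            x = layer.forward(x, train=train)
            self.activations.append(x)
        return x

    def backward(self, gout):
        self.output_grads = [None] * len(self.layers)
        for i in range(len(self.layers) - 1, -1, -1):
            self.output_grads[i] = gout
            gout = self.layers[i].backward(gout)
        return gout

    def param_pairs(self):
        pairs = []
        for layer in self.layers:
            pairs.extend(layer.param_pairs())
        return pairs

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable parameters plus batch-norm running statistics."""
        arrays = [p for p, _ in self.param_pairs()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm2d):
                arrays.extend([layer.running_mean, layer.running_var])
        return arrays


class Adam:
    def __init__(self, param_pairs, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.pairs = param_pairs
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p, _ in param_pairs]
        self.v = [np.zeros_like(p) for p, _ in param_pairs]
        self.t = 0

    def step(self):
        self.t += 1
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_grad(logits: np.ndarray, labels: np.ndarray):
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean()
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n
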