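"""Minimal CPU neural-network toolkit used by the CNN baselines.

Layers operate on arrays of shape ``(batch, channels, time)`` in float32 and
implement explicit forward/backward passes; :class:`Sequential` chains them and
:class:`Adam` updates the parameters. The scope is exactly what the baseline
architectures need: temporal 1-D convolutions (including grouped/depthwise and
electrode-shared variants), batch normalisation, max/average pooling, dropout,
dense layers and a softmax cross-entropy loss. Everything is deterministic
given the seeds of the generators supplied at build and training time.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Layer:
    """Base class: parameter dict, gradient dict, forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(DTYPE)


class Conv1d(Layer):
    """Temporal convolution with optional channel groups ('same' or integer padding).

    Weight shape ``(out_channels, in_channels // groups, kernel)``. With
    ``groups == in_channels`` this is a depthwise convolution.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1,
                 padding: int | str = "same", groups: int = 1, bias: bool = True):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError("in_channels and out_channels must be divisible by groups")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        self.stride, self.groups = stride, groups
        self.pad = (kernel - 1) // 2 if padding == "same" else int(padding)
        cg = in_channels // groups
        self.params["W"] = _he_init(rng, (out_channels, cg, kernel), cg * kernel)
        if bias:
            self.params["b"] = np.zeros(out_channels, dtype=DTYPE)

    def _slices(self, xp: np.ndarray, L: int):
        # generator of the k-th strided time slice, shape (B, C, L)
        for kk in range(self.k):
            yield kk, xp[:, :, kk: kk + self.stride * L: self.stride]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, T = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        if self.pad:
            x = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        xp = np.ascontiguousarray(x, dtype=DTYPE)
        Tp = xp.shape[2]
        if Tp < self.k:
            raise ValueError(
                f"input length {T} (padded {Tp}) shorter than kernel {self.k}")
        L = (Tp - self.k) // self.stride + 1
        W = self.params["W"]
        # accumulate over kernel taps: avoids materialising an im2col tensor
        out = np.zeros((B, self.cout, L), dtype=DTYPE)
        if self.groups == 1:
            for kk, xs in self._slices(xp, L):
                out += np.einsum("oc,bcl->bol", W[:, :, kk], xs)
        elif self.groups == self.cin:
            m = self.cout // self.cin
            W2 = W.reshape(self.cin, m, self.k)
            for kk, xs in self._slices(xp, L):
                out += (W2[np.newaxis, :, :, kk, np.newaxis]
                        * xs[:, :, np.newaxis, :]).reshape(B, self.cout, L)
        else:
            cg = self.cin // self.groups
            og = self.cout // self.groups
            W3 = W.reshape(self.groups, og, cg, self.k)
            for kk, xs in self._slices(xp, L):
                xg = xs.reshape(B, self.groups, cg, L)
                out += np.einsum("goc,bgcl->bgol", W3[..., kk], xg
                                 ).reshape(B, self.cout, L)
        if "b" in self.params:
            out += self.params["b"][:, np.newaxis]
        self._cache = (xp, (B, C, T, Tp, L))
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xp, (B, C, T, Tp, L) = self._cache
        W = self.params["W"]
        gW = np.zeros_like(W)
        gxp = np.zeros((B, C, Tp), dtype=DTYPE)
        if "b" in self.params:
            self.grads["b"] = gout.sum(axis=(0, 2)).astype(DTYPE)
        if self.groups == 1:
            for kk, xs in self._slices(xp, L):
                gW[:, :, kk] = np.einsum("bol,bcl->oc", gout, xs)
                gxp[:, :, kk: kk + self.stride * L: self.stride] += np.einsum(
                    "bol,oc->bcl", gout, W[:, :, kk])
        elif self.groups == self.cin:
            m = self.cout // self.cin
            W2 = W.reshape(self.cin, m, self.k)
            go2 = gout.reshape(B, self.cin, m, L)
            gW2 = gW.reshape(self.cin, m, self.k)
            for kk, xs in self._slices(xp, L):
                gW2[:, :, kk] = np.einsum("bcml,bcl->cm", go2, xs)
                gxp[:, :, kk: kk + self.stride * L: self.stride] += np.einsum(
                    "bcml,cm->bcl", go2, W2[:, :, kk])
        else:
            cg = self.cin // self.groups
            og = self.cout // self.groups
            W3 = W.reshape(self.groups, og, cg, self.k)
            gW3 = gW.reshape(self.groups, og, cg, self.k)
            go3 = gout.reshape(B, self.groups, og, L)
            for kk, xs in self._slices(xp, L):
                xg = xs.reshape(B, self.groups, cg, L)
                gW3[:, :, :, kk] = np.einsum("bgol,bgcl->goc", go3, xg)
                gxp[:, :, kk: kk + self.stride * L: self.stride] += np.einsum(
                    "bgol,goc->bgcl", go3, W3[..., kk]).reshape(B, C, L)
        self.grads["W"] = gW
        return gxp[:, :, self.pad: self.pad + T] if self.pad else gxp


class SharedTemporalConv(Layer):
    """Temporal filter bank shared across electrodes.

    Applies ``n_filters`` length-``kernel`` temporal filters to every input
    electrode with the *same* weights, emitting ``n_channels * n_filters``
    feature rows (electrode-major). This is the classic first block of
    spatio-spectral EEG CNNs: each electrode is decomposed by one common set of
    band-like filters.
    """

    def __init__(self, n_channels: int, n_filters: int, kernel: int,
                 rng: np.random.Generator, bias: bool = False):
        super().__init__()
        self.c, self.f, self.k = n_channels, n_filters, kernel
        self.pad = (kernel - 1) // 2
        self.params["W"] = _he_init(rng, (n_filters, kernel), kernel)
        if bias:
            self.params["b"] = np.zeros(n_filters, dtype=DTYPE)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, C, T = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        win = sliding_window_view(xp, self.k, axis=2)  # (B,C,L,K) with L==T for odd k... L = T+2p-k+1
        L = win.shape[2]
        out = np.einsum("bclk,fk->bcfl", win, self.params["W"], optimize=True)
        if "b" in self.params:
            out += self.params["b"][:, np.newaxis]
        self._cache = (win, (B, C, T, L))
        return np.ascontiguousarray(out.reshape(B, C * self.f, L), dtype=DTYPE)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        win, (B, C, T, L) = self._cache
        go = gout.reshape(B, C, self.f, L)
        self.grads["W"] = np.einsum("bclk,bcfl->fk", win, go, optimize=True).astype(DTYPE)
        if "b" in self.params:
            self.grads["b"] = go.sum(axis=(0, 1, 3)).astype(DTYPE)
        gwin = np.einsum("bcfl,fk->bclk", go, self.params["W"], optimize=True)
        Tp = T + 2 * self.pad
        gxp = np.zeros((B, C, Tp), dtype=DTYPE)
        for kk in range(self.k):
            gxp[:, :, kk: kk + L] += gwin[..., kk]
        return gxp[:, :, self.pad: self.pad + T]


class SpatialDepthwiseConv(Layer):
    """Per-filter spatial combination across electrodes with depth multiplier D.

    Input rows are electrode-major ``(electrode, filter)`` pairs produced by
    :class:`SharedTemporalConv`; for every temporal filter f the layer learns D
    spatial weightings over the ``n_channels`` electrodes, emitting
    ``n_filters * D`` rows. The spatial kernel spans exactly all electrodes.
    """

    def __init__(self, n_channels: int, n_filters: int, depth_mult: int,
                 rng: np.random.Generator):
        super().__init__()
        self.c, self.f, self.d = n_channels, n_filters, depth_mult
        self.params["W"] = _he_init(rng, (n_filters, depth_mult, n_channels), n_channels)
        self.params["b"] = np.zeros(n_filters * depth_mult, dtype=DTYPE)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        B, CF, L = x.shape
        if CF != self.c * self.f:
            raise ValueError(f"expected {self.c * self.f} rows, got {CF}")
        h = x.reshape(B, self.c, self.f, L)
        out = np.einsum("bcfl,fdc->bfdl", h, self.params["W"], optimize=True)
        out = out.reshape(B, self.f * self.d, L) + self.params["b"][:, np.newaxis]
        self._cache = (h, (B, L))
        return np.ascontiguousarray(out, dtype=DTYPE)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        h, (B, L) = self._cache
        go = gout.reshape(B, self.f, self.d, L)
        self.grads["W"] = np.einsum("bcfl,bfdl->fdc", h, go, optimize=True).astype(DTYPE)
        self.grads["b"] = gout.sum(axis=(0, 2)).astype(DTYPE)
        gh = np.einsum("bfdl,fdc->bcfl", go, self.params["W"], optimize=True)
        return np.ascontiguousarray(gh.reshape(B, self.c * self.f, L), dtype=DTYPE)


class BatchNorm(Layer):
    """Per-channel batch normalisation over (batch, time); running stats in eval."""

    def __init__(self, num_features: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.params["gamma"] = np.ones(num_features, dtype=DTYPE)
        self.params["beta"] = np.zeros(num_features, dtype=DTYPE)
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2)

    def _shape(self, v, x):
        return v if x.ndim == 2 else v[:, np.newaxis]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = self._axes(x)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._shape(mu, x)) * self._shape(inv, x)
        self._cache = (xhat, inv, axes, x.shape)
        return (self._shape(self.params["gamma"], x) * xhat
                + self._shape(self.params["beta"], x)).astype(DTYPE)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        xhat, inv, axes, shape = self._cache
        n = np.prod([shape[a] for a in axes])
        self.grads["gamma"] = (gout * xhat).sum(axis=axes).astype(DTYPE)
        self.grads["beta"] = gout.sum(axis=axes).astype(DTYPE)
        g = self._shape(self.params["gamma"] * inv, gout)
        m1 = self._shape(gout.mean(axis=axes), gout)
        m2 = self._shape((gout * xhat).mean(axis=axes), gout)
        return (g * (gout - m1 - xhat * m2)).astype(DTYPE)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(DTYPE)

    def backward(self, gout):
        return np.where(self._mask, gout, 0).astype(DTYPE)


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train):
        neg = self.alpha * np.expm1(np.minimum(x, 0))
        self._out_neg = neg
        self._pos = x > 0
        return np.where(self._pos, x, neg).astype(DTYPE)

    def backward(self, gout):
        return np.where(self._pos, gout,
                        gout * (self._out_neg + self.alpha)).astype(DTYPE)


class _Pool(Layer):
    def __init__(self, kernel: int, stride: int | None = None):
        super().__init__()
        self.k = kernel
        self.stride = stride if stride is not None else kernel

    def _windows(self, x):
        B, C, T = x.shape
        if T < self.k:
            raise ValueError(
                f"pooling window {self.k} exceeds input length {T}; "
                "increase n_samples")
        return sliding_window_view(x, self.k, axis=2)[:, :, ::self.stride]


class MaxPool1d(_Pool):
    def forward(self, x, train):
        win = self._windows(x)
        self._arg = win.argmax(axis=3)
        self._shape = x.shape
        return np.ascontiguousarray(win.max(axis=3), dtype=DTYPE)

    def backward(self, gout):
        B, C, T = self._shape
        gx = np.zeros((B, C, T), dtype=DTYPE)
        L = gout.shape[2]
        for kk in range(self.k):
            mask = self._arg == kk
            sel = gout * mask
            gx[:, :, kk: kk + self.stride * L: self.stride] += sel
        return gx


class AvgPool1d(_Pool):
    def forward(self, x, train):
        win = self._windows(x)
        self._shape = x.shape
        return np.ascontiguousarray(win.mean(axis=3), dtype=DTYPE)

    def backward(self, gout):
        B, C, T = self._shape
        gx = np.zeros((B, C, T), dtype=DTYPE)
        L = gout.shape[2]
        g = gout / self.k
        for kk in range(self.k):
            gx[:, :, kk: kk + self.stride * L: self.stride] += g
        return gx


class Dropout(Layer):
    """Inverted dropout; active only in training mode. RNG injected by the network."""

    def __init__(self, p: float):
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError(f"dropout rate must be in [0, 1), got {p}")
        self.p = p
        self.rng: np.random.Generator | None = None

    def forward(self, x, train):
        if not train or self.p == 0:
            self._mask = None
            return x
        if self.rng is None:
            raise RuntimeError("Dropout used in training mode without an RNG; "
                               "call network.set_rng(...) first")
        self._mask = (self.rng.uniform(size=x.shape) >= self.p) / (1 - self.p)
        return (x * self._mask).astype(DTYPE)

    def backward(self, gout):
        if self._mask is None:
            return gout
        return (gout * self._mask).astype(DTYPE)


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gout):
        return gout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        super().__init__()
        self.params["W"] = _he_init(rng, (n_in, n_out), n_in)
        if bias:
            self.params["b"] = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x, train):
        self._x = x
        out = x @ self.params["W"]
        if "b" in self.params:
            out = out + self.params["b"]
        return out.astype(DTYPE)

    def backward(self, gout):
        self.grads["W"] = (self._x.T @ gout).astype(DTYPE)
        if "b" in self.params:
            self.grads["b"] = gout.sum(axis=0).astype(DTYPE)
        return (gout @ self.params["W"].T).astype(DTYPE)


class Sequential:
    """A chain of layers with shared train/eval mode and parameter access."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=DTYPE)
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    __call__ = forward

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def set_rng(self, rng: np.random.Generator) -> None:
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def get_state(self) -> list[np.ndarray]:
        state = []
        for layer in self.layers:
            for name in sorted(layer.params):
                state.append(layer.params[name].copy())
            if isinstance(layer, BatchNorm):
                state.append(layer.running_mean.copy())
                state.append(layer.running_var.copy())
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        it = iter(state)
        for layer in self.layers:
            for name in sorted(layer.params):
                layer.params[name] = next(it).copy()
            if isinstance(layer, BatchNorm):
                layer.running_mean = next(it).copy()
                layer.running_var = next(it).copy()

    def save(self, path) -> None:
        """Store weights in an .npz checkpoint."""
        arrays = {f"arr_{i}": a for i, a in enumerate(self.get_state())}
        np.savez(path, **arrays)

    def load(self, path) -> None:
        with np.load(path) as data:
            self.set_state([data[f"arr_{i}"] for i in range(len(data.files))])


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean softmax cross-entropy and its gradient w.r.t. the logits."""
    B = logits.shape[0]
    p = softmax(logits.astype(np.float64))
    loss = float(-np.log(np.maximum(p[np.arange(B), labels], 1e-12)).mean())
    grad = p
    grad[np.arange(B), labels] -= 1.0
    return loss, (grad / B).astype(DTYPE)


class Adam:
    """Adam optimiser over a Sequential's parameters."""

    def __init__(self, net: Sequential, lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.net = net
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = {}
        self.v = {}
        for layer, name in net.parameters():
            key = (id(layer), name)
            self.m[key] = np.zeros_like(layer.params[name])
            self.v[key] = np.zeros_like(layer.params[name])

    def step(self) -> None:
        self.t += 1
        for layer, name in self.net.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            key = (id(layer), name)
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = self.m[key] / (1 - self.b1 ** self.t)
            vhat = self.v[key] / (1 - self.b2 ** self.t)
            layer.params[name] = (layer.params[name]
                                  - self.lr * mhat / (np.sqrt(vhat) + self.eps)
                                  ).astype(DTYPE)
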