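"""Layers for a small CPU neural-network engine.

All layers operate on numpy arrays in channels-last layout and implement
explicit forward/backward passes.  2-D and 1-D convolutions are realised as
im2col + GEMM so the heavy lifting stays inside BLAS; everything is float32
by default (float64 available for gradient checking).

Conventions
-----------
* ``forward(x, train=..., rng=...)`` caches whatever ``backward`` needs.
* ``backward(dy)`` returns the gradient w.r.t. the layer input and
  accumulates parameter gradients into each :class:`Param`.
* Stochastic layers (dropout) draw from the generator passed to ``forward``
  so a single seeded generator makes an entire training run reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv2D",
    "Conv1D",
    "Dense",
    "ReLU",
    "AvgPool2D",
    "MaxPool2D",
    "Dropout",
    "Flatten",
    "BatchNorm",
    "SensorToSequence",
    "LSTM",
]


class Param:
    """A trainable (or buffer) array plus its gradient and L2 coefficient."""

    __slots__ = ("value", "grad", "l2", "trainable", "name")

    def __init__(self, value, l2=0.0, trainable=True, name=""):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)
        self.l2 = float(l2)
        self.trainable = trainable
        self.name = name

    @property
    def size(self):
        return self.value.size


class Layer:
    def params(self):
        return []

    def forward(self, x, train=False, rng=None):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def output_shape(self, input_shape):
        return input_shape


def _he_init(rng, shape, fan_in, dtype):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Conv2D(Layer):
    """Size-preserving ("same") 2-D convolution with optional ReLU handled
    separately; weights stored as a (k*k*c_in, c_out) GEMM matrix."""

    def __init__(self, c_in, c_out, kernel=3, l2=0.0, rng=None, dtype=np.float32):
        self.c_in, self.c_out, self.k = int(c_in), int(c_out), int(kernel)
        self.pad = self.k // 2
        rng = rng or np.random.default_rng()
        fan_in = self.k * self.k * self.c_in
        self.W = Param(_he_init(rng, (fan_in, self.c_out), fan_in, dtype), l2=l2, name="conv_W")
        self.b = Param(np.zeros(self.c_out, dtype=dtype), name="conv_b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False, rng=None):
        b, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"Conv2D expected {self.c_in} input channels, got {c}")
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k, self.k), axis=(1, 2))
        # win: (b, h, w, c, k, k) -> cols (b*h*w, k*k*c)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(b * h * w, -1)
        self._cols = cols
        self._xshape = x.shape
        y = cols @ self.W.value
        y += self.b.value
        return y.reshape(b, h, w, self.c_out)

    def backward(self, dy):
        b, h, w, c = self._xshape
        dyf = dy.reshape(b * h * w, self.c_out)
        self.W.grad += self._cols.T @ dyf
        self.b.grad += dyf.sum(axis=0)
        dcols = (dyf @ self.W.value.T).reshape(b, h, w, self.k, self.k, c)
        p = self.pad
        dxp = np.zeros((b, h + 2 * p, w + 2 * p, c), dtype=dy.dtype)
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        self._cols = None
        return dxp[:, p : p + h, p : p + w, :]

    def output_shape(self, s):
        return (s[0], s[1], self.c_out)

    @property
    def n_params(self):
        return self.W.size + self.b.size


class Conv1D(Layer):
    """1-D convolution over the time axis of (B, T, C).

    "Same" zero padding; ``stride`` > 1 downsamples the sequence to
    floor((T + 2*(k//2) - k) / stride) + 1 steps.
    """

    def __init__(self, c_in, c_out, kernel=5, stride=1, l2=0.0, rng=None, dtype=np.float32):
        self.c_in, self.c_out, self.k = int(c_in), int(c_out), int(kernel)
        self.stride = int(stride)
        self.pad = self.k // 2
        rng = rng or np.random.default_rng()
        fan_in = self.k * self.c_in
        self.W = Param(_he_init(rng, (fan_in, self.c_out), fan_in, dtype), l2=l2, name="conv1d_W")
        self.b = Param(np.zeros(self.c_out, dtype=dtype), name="conv1d_b")

    def params(self):
        return [self.W, self.b]

    def out_len(self, t):
        return (t + 2 * self.pad - self.k) // self.stride + 1

    def forward(self, x, train=False, rng=None):
        b, t, c = x.shape
        if c != self.c_in:
            raise ValueError(f"Conv1D expected {self.c_in} input channels, got {c}")
        p = self.pad
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        win = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=1)
        win = win[:, :: self.stride, :, :]
        t_out = win.shape[1]
        # win: (b, t_out, c, k) -> cols (b*t_out, k*c)
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(b * t_out, -1)
        self._cols = cols
        self._xshape = x.shape
        self._t_out = t_out
        y = cols @ self.W.value + self.b.value
        return y.reshape(b, t_out, self.c_out)

    def backward(self, dy):
        b, t, c = self._xshape
        t_out = self._t_out
        dyf = dy.reshape(b * t_out, self.c_out)
        self.W.grad += self._cols.T @ dyf
        self.b.grad += dyf.sum(axis=0)
        dcols = (dyf @ self.W.value.T).reshape(b, t_out, self.k, c)
        p = self.pad
        dxp = np.zeros((b, t + 2 * p, c), dtype=dy.dtype)
        positions = np.arange(t_out) * self.stride
        for j in range(self.k):
            # positions + j are unique for fixed j, so += is duplicate-safe
            dxp[:, positions + j, :] += dcols[:, :, j, :]
        self._cols = None
        return dxp[:, p : p + t, :]

    def output_shape(self, s):
        return (self.out_len(s[0]), self.c_out)

    @property
    def n_params(self):
        return self.W.size + self.b.size


class Dense(Layer):
    def __init__(self, n_in, n_out, l2=0.0, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.n_in, self.n_out = int(n_in), int(n_out)
        self.W = Param(_he_init(rng, (self.n_in, self.n_out), self.n_in, dtype), l2=l2, name="dense_W")
        self.b = Param(np.zeros(self.n_out, dtype=dtype), name="dense_b")

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        self._x = None
        return dy @ self.W.value.T

    def output_shape(self, s):
        return (self.n_out,)

    @property
    def n_params(self):
        return self.W.size + self.b.size


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class AvgPool2D(Layer):
    """2x2 average pooling with floor semantics (a trailing odd row/column
    is dropped, matching 95 -> 47 -> 23 -> 11)."""

    def __init__(self, size=2):
        self.s = int(size)

    def forward(self, x, train=False, rng=None):
        b, h, w, c = x.shape
        s = self.s
        h2, w2 = (h // s) * s, (w // s) * s
        self._xshape = x.shape
        xr = x[:, :h2, :w2, :].reshape(b, h2 // s, s, w2 // s, s, c)
        return xr.mean(axis=(2, 4))

    def backward(self, dy):
        b, h, w, c = self._xshape
        s = self.s
        h2, w2 = (h // s) * s, (w // s) * s
        dx = np.zeros(self._xshape, dtype=dy.dtype)
        expanded = np.broadcast_to(
            dy[:, :, None, :, None, :] / (s * s),
            (b, h2 // s, s, w2 // s, s, c),
        ).reshape(b, h2, w2, c)
        dx[:, :h2, :w2, :] = expanded
        return dx

    def output_shape(self, sh):
        return (sh[0] // self.s, sh[1] // self.s, sh[2])


class MaxPool2D(Layer):
    def __init__(self, size=2):
        self.s = int(size)

    def forward(self, x, train=False, rng=None):
        b, h, w, c = x.shape
        s = self.s
        h2, w2 = (h // s) * s, (w // s) * s
        self._xshape = x.shape
        xr = x[:, :h2, :w2, :].reshape(b, h2 // s, s, w2 // s, s, c)
        xt = xr.transpose(0, 1, 3, 5, 2, 4).reshape(b, h2 // s, w2 // s, c, s * s)
        self._idx = xt.argmax(axis=-1)
        return np.take_along_axis(xt, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy):
        b, h, w, c = self._xshape
        s = self.s
        h2, w2 = (h // s) * s, (w // s) * s
        dxt = np.zeros((b, h2 // s, w2 // s, c, s * s), dtype=dy.dtype)
        np.put_along_axis(dxt, self._idx[..., None], dy[..., None], axis=-1)
        dxr = dxt.reshape(b, h2 // s, w2 // s, c, s, s).transpose(0, 1, 4, 2, 5, 3)
        dx = np.zeros(self._xshape, dtype=dy.dtype)
        dx[:, :h2, :w2, :] = dxr.reshape(b, h2, w2, c)
        return dx

    def output_shape(self, sh):
        return (sh[0] // self.s, sh[1] // self.s, sh[2])


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = float(rate)

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("Dropout in training mode needs an rng")
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._xshape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._xshape)

    def output_shape(self, s):
        return (int(np.prod(s)),)


class BatchNorm(Layer):
    """Batch normalisation over the batch axis of (B, F) activations.

    Trainable gamma/beta; running mean/var buffers drive inference mode, so
    prediction is deterministic for fixed weights.
    """

    def __init__(self, n, momentum=0.9, eps=1e-5, dtype=np.float32):
        self.n = int(n)
        self.momentum = float(momentum)
        self.eps = float(eps)
        self.gamma = Param(np.ones(n, dtype=dtype), name="bn_gamma")
        self.beta = Param(np.zeros(n, dtype=dtype), name="bn_beta")
        self.running_mean = Param(np.zeros(n, dtype=dtype), trainable=False, name="bn_mean")
        self.running_var = Param(np.ones(n, dtype=dtype), trainable=False, name="bn_var")

    def params(self):
        return [self.gamma, self.beta, self.running_mean, self.running_var]

    def forward(self, x, train=False, rng=None):
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            m = self.momentum
            self.running_mean.value = (m * self.running_mean.value + (1 - m) * mean).astype(x.dtype)
            self.running_var.value = (m * self.running_var.value + (1 - m) * var).astype(x.dtype)
        else:
            mean = self.running_mean.value
            var = self.running_var.value
        self._train_mode = train
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, dy):
        xhat = self._xhat
        self.gamma.grad += (dy * xhat).sum(axis=0)
        self.beta.grad += dy.sum(axis=0)
        g = self.gamma.value * self._inv_std
        if not self._train_mode:
            return dy * g
        B = dy.shape[0]
        return (g / B) * (B * dy - dy.sum(axis=0) - xhat * (dy * xhat).sum(axis=0))

    @property
    def n_params(self):
        # trainable only (gamma, beta); running stats are buffers
        return 2 * self.n


class SensorToSequence(Layer):
    """Reshape a (B, 12, T, 3) stream tensor into a (B, T, 36) sequence.

    Feature order within each step is stream-major then axis, i.e. feature
    index = stream * 3 + axis, matching the 36-channel raw-trial layout.
    """

    def forward(self, x, train=False, rng=None):
        b, s, t, a = x.shape
        self._xshape = x.shape
        return np.ascontiguousarray(x.transpose(0, 2, 1, 3)).reshape(b, t, s * a)

    def backward(self, dy):
        b, s, t, a = self._xshape
        return np.ascontiguousarray(dy.reshape(b, t, s, a).transpose(0, 2, 1, 3))

    def output_shape(self, sh):
        return (sh[1], sh[0] * sh[2])


class LSTM(Layer):
    """Single LSTM layer with standard gates (i, f, g, o) and BPTT.

    ``return_sequences=False`` emits the final hidden state only.  Forget
    gate bias initialised to 1.
    """

    def __init__(self, n_in, n_hidden, return_sequences=False, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        self.n_in, self.nh = int(n_in), int(n_hidden)
        self.return_sequences = bool(return_sequences)
        h = self.nh
        scale_x = np.sqrt(1.0 / self.n_in)
        scale_h = np.sqrt(1.0 / h)
        self.Wx = Param((rng.standard_normal((self.n_in, 4 * h)) * scale_x).astype(dtype), name="lstm_Wx")
        self.Wh = Param((rng.standard_normal((h, 4 * h)) * scale_h).astype(dtype), name="lstm_Wh")
        b = np.zeros(4 * h, dtype=dtype)
        b[h : 2 * h] = 1.0
        self.b = Param(b, name="lstm_b")

    def params(self):
        return [self.Wx, self.Wh, self.b]

    @staticmethod
    def _sigmoid(z):
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out

    def forward(self, x, train=False, rng=None):
        B, T, D = x.shape
        H = self.nh
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        self._x = x
        self._cache = []
        hs = np.empty((B, T, H), dtype=x.dtype) if self.return_sequences else None
        xW = x.reshape(B * T, D) @ self.Wx.value  # all input projections at once
        xW = xW.reshape(B, T, 4 * H)
        for t in range(T):
            z = xW[:, t, :] + h @ self.Wh.value + self.b.value
            i = self._sigmoid(z[:, :H])
            f = self._sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = self._sigmoid(z[:, 3 * H :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            self._cache.append((i, f, g, o, c_prev, tc, h_prev))
            if hs is not None:
                hs[:, t, :] = h
        self._last_h = h
        return hs if self.return_sequences else h

    def backward(self, dy):
        x = self._x
        B, T, D = x.shape
        H = self.nh
        dh = np.zeros((B, H), dtype=x.dtype)
        dc = np.zeros((B, H), dtype=x.dtype)
        dzs = np.empty((B, T, 4 * H), dtype=x.dtype)
        if not self.return_sequences:
            dh = dy.copy()
        for t in range(T - 1, -1, -1):
            if self.return_sequences:
                dh = dh + dy[:, t, :]
            i, f, g, o, c_prev, tc, h_prev = self._cache[t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc * tc)
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = dzs[:, t, :]
            dz[:, :H] = di * i * (1.0 - i)
            dz[:, H : 2 * H] = df * f * (1.0 - f)
            dz[:, 2 * H : 3 * H] = dg * (1.0 - g * g)
            dz[:, 3 * H :] = do * o * (1.0 - o)
            self.Wh.grad += h_prev.T @ dz
            dh = dz @ self.Wh.value.T
            dc = dc * f
        dzf = dzs.reshape(B * T, 4 * H)
        self.Wx.grad += x.reshape(B * T, D).T @ dzf
        self.b.grad += dzf.sum(axis=0)
        dx = (dzf @ self.Wx.value.T).reshape(B, T, D)
        self._x = None
        self._cache = None
        return dx

    def output_shape(self, s):
        return (s[0], self.nh) if self.return_sequences else (self.nh,)

    @property
    def n_params(self):
        return self.Wx.size + self.Wh.size + self.b.size
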