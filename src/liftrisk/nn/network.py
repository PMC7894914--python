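"""Sequential network container, Adam optimiser and the training loop.

The container produces *logits*; :func:`softmax` is applied by
``predict_proba`` and inside the cross-entropy loss.  Training follows the
protocol used throughout the package: Adam, categorical cross-entropy,
early stopping on the monitored training loss with ``min_delta``/``patience``
semantics and restoration of the best-loss weights.
"""

from __future__ import annotations

import numpy as np

from .layers import Dropout, Layer, Param

__all__ = [
    "Sequential",
    "Adam",
    "EarlyStopping",
    "TrainingDivergedError",
    "softmax",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite (unstable learning
    rate regime)."""


def softmax(logits):
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class Sequential:
    def __init__(self, layers, input_shape=None):
        self.layers: list[Layer] = list(layers)
        self.input_shape = tuple(input_shape) if input_shape is not None else None

    # -- introspection ---------------------------------------------------
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def n_trainable_params(self):
        return sum(p.size for p in self.params() if p.trainable)

    def zero_grad(self):
        for p in self.params():
            p.grad[...] = 0.0

    def get_weights(self):
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights):
        ps = self.params()
        if len(weights) != len(ps):
            raise ValueError("weight list length mismatch")
        for p, w in zip(ps, weights):
            p.value = w.copy()

    # -- passes ----------------------------------------------------------
    def forward(self, x, train=False, rng=None):
        if self.input_shape is not None and tuple(x.shape[1:]) != self.input_shape:
            raise ValueError(
                f"expected input of shape {self.input_shape}, got {tuple(x.shape[1:])}"
            )
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def predict_proba(self, x, batch_size=64):
        out = []
        for i in range(0, len(x), batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.concatenate(out, axis=0)

    # -- loss ------------------------------------------------------------
    def l2_penalty(self):
        pen = 0.0
        for p in self.params():
            if p.l2:
                pen += p.l2 * float(np.sum(p.value.astype(np.float64) ** 2))
        return pen

    def loss_and_backward(self, x, y_onehot, rng):
        """One training step: returns (loss, n_correct) and runs the full
        backward pass.  Loss = categorical cross-entropy + L2 penalty;
        gradients of the L2 terms are added by the optimiser."""
        logits = self.forward(x, train=True, rng=rng)
        p = softmax(logits)
        eps = 1e-12
        ce = -float(np.mean(np.sum(y_onehot * np.log(p + eps), axis=-1)))
        n_correct = int(np.sum(p.argmax(axis=-1) == y_onehot.argmax(axis=-1)))
        dlogits = (p - y_onehot) / x.shape[0]
        self.backward(dlogits.astype(logits.dtype))
        return ce + self.l2_penalty(), n_correct

    def input_gradient(self, x, class_idx, post_softmax=False):
        """Gradient of the class score w.r.t. the input at ``x``.

        The score is the pre-softmax logit of ``class_idx`` by default; with
        ``post_softmax=True`` the softmax probability is differentiated
        instead.  Inference mode throughout (no dropout, batch-norm running
        stats), so the map is deterministic for fixed weights.
        """
        logits = self.forward(x, train=False)
        n_classes = logits.shape[-1]
        if not 0 <= class_idx < n_classes:
            raise ValueError(f"class index {class_idx} outside 0..{n_classes - 1}")
        if post_softmax:
            p = softmax(logits)
            dy = -p[:, class_idx : class_idx + 1] * p
            dy[:, class_idx] += p[:, class_idx]
        else:
            dy = np.zeros_like(logits)
            dy[:, class_idx] = 1.0
        self.zero_grad()
        return self.backward(dy.astype(logits.dtype))

    def has_dropout(self):
        return any(isinstance(l, Dropout) for l in self.layers)


class Adam:
    """Adam with the standard published moment defaults."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = [p for p in params if p.trainable]
        self.lr = float(lr)
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if p.l2:
                g = g + 2.0 * p.l2 * p.value
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= (self.lr / bias1) * m / (np.sqrt(v / bias2) + self.eps)


class EarlyStopping:
    """Patience-based stopping on a monitored loss.

    ``update`` returns True when training should stop: the loss has failed
    to improve by more than ``min_delta`` for ``patience`` consecutive
    epochs.  ``best_epoch`` indexes the epoch with the lowest monitored
    loss seen so far (0-based).
    """

    def __init__(self, patience=10, min_delta=0.0):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = int(patience)
        self.min_delta = float(min_delta)
        self.best = np.inf
        self.best_epoch = -1
        self.wait = 0
        self.n_seen = 0

    def update(self, loss):
        epoch = self.n_seen
        self.n_seen += 1
        if loss < self.best - self.min_delta:
            self.best = loss
            self.best_epoch = epoch
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience
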