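"""Gradient saliency maps and per-sensor importance.

The saliency of an input element is the magnitude of the derivative of the
class score with respect to that element, evaluated at the input itself —
the first-order answer to "how much would the class score move if this
value changed".  The score is the *pre-softmax* logit of the class by
default (the standard construction; post-softmax is available but can
saturate).  For the image model the three axis channels are reduced to a
single 95x95 map, by default with the maximum of absolute values; the
sequence model yields a 36x750 map (rows ordered as the 36 raw channels:
placement-major, then sensor type, then axis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Sequential
from .preprocessing import IMAGE_SIDE, MAX_FRAMES
from .simulate import N_CHANNELS, PLACEMENTS

__all__ = [
    "SaliencyMap",
    "saliency_single",
    "saliency_class_average",
    "sensor_importance",
]


@dataclass
class SaliencyMap:
    """Non-negative importance weights in the model's input layout.

    ``weights`` is 95x95 for the image model (after channel reduction) or
    36x750 for the sequence model; ``class_idx`` is the risk level whose
    score was differentiated; ``n_inputs`` the number of trials averaged.
    """

    weights: np.ndarray
    class_idx: int
    n_inputs: int = 1

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if (self.weights < 0).any():
            raise ValueError("saliency weights must be non-negative")


def _magnitude_map(grad: np.ndarray, reduce: str) -> np.ndarray:
    """Reduce one input gradient to its 2-D magnitude layout."""
    mag = np.abs(grad)
    if grad.shape == (IMAGE_SIDE, IMAGE_SIDE, 3):
        if reduce == "max_abs":
            return mag.max(axis=-1)
        if reduce == "sum":
            return mag.sum(axis=-1)
        raise ValueError("reduce must be 'max_abs' or 'sum'")
    if grad.ndim == 3 and grad.shape[2] == 3:  # (12, 750, 3) stream tensor
        s, t, a = grad.shape
        # row = stream*3 + axis, matching the 36-column raw layout
        return mag.transpose(0, 2, 1).reshape(s * a, t)
    raise ValueError(f"unsupported input layout {grad.shape}")


def saliency_single(
    model: Sequential,
    x: np.ndarray,
    class_idx: int,
    post_softmax: bool = False,
    reduce: str = "max_abs",
) -> SaliencyMap:
    """Saliency map of one preprocessed input."""
    grad = model.input_gradient(x[None, ...], class_idx, post_softmax=post_softmax)[0]
    if not np.isfinite(grad).all():
        raise ValueError("non-finite gradient; is the model trained/initialised?")
    return SaliencyMap(weights=_magnitude_map(grad, reduce), class_idx=class_idx)


def saliency_class_average(
    model: Sequential,
    x: np.ndarray,
    labels: np.ndarray,
    class_idx: int,
    post_softmax: bool = False,
    reduce: str = "max_abs",
    batch_size: int = 32,
) -> SaliencyMap:
    """Mean magnitude map over all inputs whose *true* class is ``class_idx``.

    Averaging is over per-input magnitude maps (not signed gradients), so
    the result is order-invariant and non-negative.
    """
    labels = np.asarray(labels)
    members = np.flatnonzero(labels == class_idx)
    if members.size == 0:
        raise ValueError(f"no trials with true class {class_idx}")
    total = None
    for start in range(0, members.size, batch_size):
        idx = members[start : start + batch_size]
        grads = model.input_gradient(x[idx], class_idx, post_softmax=post_softmax)
        for g in grads:
            m = _magnitude_map(g, reduce)
            total = m if total is None else total + m
    return SaliencyMap(
        weights=total / members.size, class_idx=class_idx, n_inputs=int(members.size)
    )


def sensor_importance(smap: SaliencyMap):
    """Rank the six placements by total saliency mass (sequence model).

    Each placement's importance sums its 6 rows (accelerometer + gyroscope
    x three axes) over all frames.  Returns (name, importance) pairs in
    descending order; ties keep placement order (stable sort).
    """
    w = smap.weights
    if w.shape != (N_CHANNELS, MAX_FRAMES):
        raise ValueError(
            f"sensor importance needs a ({N_CHANNELS}, {MAX_FRAMES}) map, got {w.shape}"
        )
    per_placement = w.reshape(len(PLACEMENTS), 6, MAX_FRAMES).sum(axis=(1, 2))
    order = np.argsort(-per_placement, kind="stable")
    return [(PLACEMENTS[i], float(per_placement[i])) for i in order]
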