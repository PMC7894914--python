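"""Signal preprocessing: bandpass filtering, padding, scaling, image encoding.

The pipeline order is fixed: **filter -> pad -> scale -> encode**.  Scaling
per axis-channel is only expressible on the 12x750x3 stream layout; because
the image encoding is a pure position bijection, scaling the tensor and then
encoding is identical to encoding and then scaling each cell by its source
channel's parameters.  After scaling, padding cells are reset to exactly 0 —
the neutral value under z-scoring — so padded regions render as a uniform
block.

Layouts
-------
LiftTensor : 12 x 750 x 3 — rows are the 12 sensor streams (6 placements x
  {accelerometer, gyroscope}, placement-major), columns are frames (25 Hz,
  30 s ceiling), depth is the x/y/z axis.  12 x 750 x 3 = 27,000 values.
LiftImage : 95 x 95 x 3 — per axis, the 12 x 750 slice is flattened
  time-major (all 12 streams at frame 0, then frame 1, ...) and the
  9,000-value sequence wrapped row-by-row into a 95 x 95 grid; the final
  25 cells of each channel are padding.  Row-major wrapping of a time-major
  flattening keeps temporally adjacent samples spatially close.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .simulate import N_CHANNELS, RawTrial

__all__ = [
    "N_STREAMS",
    "MAX_FRAMES",
    "IMAGE_SIDE",
    "N_PAD_CELLS",
    "FilterSpec",
    "LiftTensor",
    "LiftImage",
    "ChannelScaler",
    "bandpass_filter",
    "pad_trial",
    "encode_image",
    "decode_image",
    "rezero_padding",
]

N_STREAMS = 12  # 6 placements x {acc, gyro}
N_AXES = 3
MAX_FRAMES = 750  # 30 s at 25 Hz
IMAGE_SIDE = 95
N_PAD_CELLS = IMAGE_SIDE * IMAGE_SIDE - N_STREAMS * MAX_FRAMES  # 25 per channel


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass design: order-2 Butterworth, 2-12 Hz at 25 Hz sampling."""

    order: int = 2
    low_cut: float = 2.0
    high_cut: float = 12.0
    sample_rate: float = 25.0

    def validate(self) -> None:
        if self.order < 1:
            raise ValueError("order must be a positive integer")
        nyquist = self.sample_rate / 2.0
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError("need 0 < low_cut < high_cut")
        if self.high_cut >= nyquist:
            raise ValueError(
                f"high_cut ({self.high_cut} Hz) must be below Nyquist ({nyquist} Hz)"
            )

    def sos(self) -> np.ndarray:
        self.validate()
        return sps.butter(
            self.order,
            [self.low_cut, self.high_cut],
            btype="bandpass",
            fs=self.sample_rate,
            output="sos",
        )


def bandpass_filter(trial: RawTrial, spec: FilterSpec, zero_phase: bool = True) -> RawTrial:
    """Filter each of the 36 channels independently.

    Zero-phase (forward-backward) by default: trials are processed offline,
    and zero phase keeps burst positions unshifted.  ``zero_phase=False``
    gives the causal single-pass filter for streaming-style use.
    """
    if trial.sample_rate != spec.sample_rate:
        raise ValueError(
            f"trial sample rate {trial.sample_rate} != filter design {spec.sample_rate}"
        )
    if trial.n_frames <= 3 * spec.order:
        raise ValueError("trial too short for the filter's warm-up")
    sos = spec.sos()
    if zero_phase:
        filtered = sps.sosfiltfilt(sos, trial.frames, axis=0)
    else:
        filtered = sps.sosfilt(sos, trial.frames, axis=0)
    return RawTrial(
        subject_id=trial.subject_id,
        zone=trial.zone,
        frames=np.ascontiguousarray(filtered),
        sample_rate=trial.sample_rate,
        meta=dict(trial.meta),
    )


@dataclass
class LiftTensor:
    """Preprocessed 12 x 750 x 3 stream tensor with padding bookkeeping."""

    data: np.ndarray
    pad_start: int
    label: int | None = None
    zone: int | None = None
    subject_id: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.shape != (N_STREAMS, MAX_FRAMES, N_AXES):
            raise ValueError(
                f"LiftTensor data must be {(N_STREAMS, MAX_FRAMES, N_AXES)}, "
                f"got {self.data.shape}"
            )
        if not 0 <= self.pad_start <= MAX_FRAMES:
            raise ValueError("pad_start outside 0..750")


@dataclass
class LiftImage:
    """95 x 95 x 3 image-style encoding of a LiftTensor."""

    data: np.ndarray
    n_pad_cells: int = N_PAD_CELLS
    label: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.shape != (IMAGE_SIDE, IMAGE_SIDE, N_AXES):
            raise ValueError(
                f"LiftImage data must be {(IMAGE_SIDE, IMAGE_SIDE, N_AXES)}, "
                f"got {self.data.shape}"
            )


def pad_trial(trial: RawTrial, max_frames: int = MAX_FRAMES) -> LiftTensor:
    """Rearrange an F x 36 trial into 12 x F x 3 and zero-extend to 750 frames.

    Refuses trials longer than the window rather than silently truncating.
    """
    f = trial.n_frames
    if f > max_frames:
        raise ValueError(
            f"trial has {f} frames, exceeding the {max_frames}-frame window; "
            "refusing to truncate"
        )
    # column c = stream*3 + axis  ->  tensor[stream, frame, axis]
    tensor = trial.frames.reshape(f, N_STREAMS, N_AXES).transpose(1, 0, 2)
    data = np.zeros((N_STREAMS, max_frames, N_AXES), dtype=trial.frames.dtype)
    data[:, :f, :] = tensor
    from .dataset import zone_to_risk

    return LiftTensor(
        data=data,
        pad_start=f,
        label=zone_to_risk(trial.zone),
        zone=trial.zone,
        subject_id=trial.subject_id,
        meta=dict(trial.meta),
    )


class ChannelScaler:
    """Per-axis-channel affine scaler fitted on training data only.

    ``zscore`` maps each of the 36 channels (12 streams x 3 axes) to mean 0,
    sd 1 over the training set; ``minmax`` maps the training range to
    [-1, 1].  Held-out data transformed with the fitted parameters may fall
    outside those bounds.  Parameters are immutable once fitted.
    """

    MODES = ("zscore", "minmax")

    def __init__(self, mode: str = "zscore"):
        if mode not in self.MODES:
            raise ValueError(f"mode must be one of {self.MODES}")
        self.mode = mode
        self._loc = None
        self._scale = None

    @property
    def fitted(self) -> bool:
        return self._loc is not None

    def fit(self, tensors) -> "ChannelScaler":
        if self.fitted:
            raise RuntimeError("scaler already fitted; parameters are immutable")
        stack = np.stack([t.data for t in tensors])  # (N, 12, 750, 3)
        values = stack.transpose(0, 2, 1, 3).reshape(-1, N_STREAMS * N_AXES)
        if self.mode == "zscore":
            loc = values.mean(axis=0)
            scale = values.std(axis=0)
        else:
            vmin = values.min(axis=0)
            vmax = values.max(axis=0)
            loc = (vmax + vmin) / 2.0
            scale = (vmax - vmin) / 2.0
        # relative threshold: a numerically-zero spread on a constant channel
        degenerate = scale <= 1e-12 * np.maximum(1.0, np.abs(loc))
        if degenerate.any():
            warnings.warn(
                f"{int(degenerate.sum())} zero-variance channel(s); scale forced to 1",
                RuntimeWarning,
                stacklevel=2,
            )
            scale = np.where(degenerate, 1.0, scale)
        self._loc = loc.reshape(N_STREAMS, 1, N_AXES)
        self._scale = scale.reshape(N_STREAMS, 1, N_AXES)
        return self

    def transform(self, tensor: LiftTensor) -> LiftTensor:
        if not self.fitted:
            raise RuntimeError("scaler not fitted")
        return LiftTensor(
            data=(tensor.data - self._loc) / self._scale,
            pad_start=tensor.pad_start,
            label=tensor.label,
            zone=tensor.zone,
            subject_id=tensor.subject_id,
            meta=dict(tensor.meta),
        )

    def transform_all(self, tensors) -> list[LiftTensor]:
        return [self.transform(t) for t in tensors]


def rezero_padding(tensor: LiftTensor) -> LiftTensor:
    """Reset frames beyond ``pad_start`` to exactly 0 (post-scaling step)."""
    data = tensor.data.copy()
    data[:, tensor.pad_start :, :] = 0.0
    return LiftTensor(
        data=data,
        pad_start=tensor.pad_start,
        label=tensor.label,
        zone=tensor.zone,
        subject_id=tensor.subject_id,
        meta=dict(tensor.meta),
    )


def encode_image(tensor: LiftTensor) -> LiftImage:
    """Flatten each 12 x 750 axis slice time-major and wrap into 95 x 95.

    Sequence index i = stream + 12 * frame; image cell (i // 95, i mod 95).
    The 25 trailing cells of each channel hold the pad value 0.
    """
    flat = np.zeros((IMAGE_SIDE * IMAGE_SIDE, N_AXES), dtype=tensor.data.dtype)
    # (12, 750, 3) -> time-major sequence: stream varies fastest
    flat[: N_STREAMS * MAX_FRAMES, :] = tensor.data.transpose(1, 0, 2).reshape(
        N_STREAMS * MAX_FRAMES, N_AXES
    )
    return LiftImage(
        data=flat.reshape(IMAGE_SIDE, IMAGE_SIDE, N_AXES), label=tensor.label
    )


def decode_image(image: LiftImage, pad_start: int = MAX_FRAMES) -> LiftTensor:
    """Exact inverse of :func:`encode_image` (padding cells discarded)."""
    flat = image.data.reshape(IMAGE_SIDE * IMAGE_SIDE, N_AXES)
    seq = flat[: N_STREAMS * MAX_FRAMES, :].reshape(MAX_FRAMES, N_STREAMS, N_AXES)
    return LiftTensor(
        data=np.ascontiguousarray(seq.transpose(1, 0, 2)),
        pad_start=pad_start,
        label=image.label,
    )
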