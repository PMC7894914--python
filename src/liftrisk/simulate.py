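"""Synthetic lifting-trial generator.

Emulates the structure of multi-IMU manual-lifting recordings: six sensor
placements (upper back at T12, left wrist, right wrist, dominant upper arm,
waist/side, dominant thigh), each carrying a tri-axial accelerometer and
gyroscope sampled at 25 Hz.  A trial consists of baseline sensor noise plus
two Gaussian-windowed oscillatory bursts — the object pickup near the start
of the lift and the acceleration back to an upright posture near the end.
Burst amplitude scales with the risk class of the lift's ACGIH zone, most
strongly on the back and wrist channels, so that class identity is carried
by the channel-energy profile with a controllable separation.

The generator is the test bed for every downstream stage; it makes no
attempt at biomechanically faithful kinematics.

Channel layout (36 columns, placement-major):
    for placement in (back, wrist_left, wrist_right, upper_arm, waist, thigh):
        for sensor in (acc, gyro):
            for axis in (x, y, z):
so column index = placement*6 + sensor*3 + axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PLACEMENTS",
    "SENSOR_TYPES",
    "AXES",
    "CHANNEL_NAMES",
    "N_CHANNELS",
    "N_ZONES",
    "SimConfig",
    "RawTrial",
    "simulate_dataset",
    "simulate_trial",
    "burst_frame_windows",
    "write_trials",
    "read_trials",
]

PLACEMENTS = ("back", "wrist_left", "wrist_right", "upper_arm", "waist", "thigh")
SENSOR_TYPES = ("acc", "gyro")
AXES = ("x", "y", "z")
CHANNEL_NAMES = tuple(
    f"{p}_{s}_{a}" for p in PLACEMENTS for s in SENSOR_TYPES for a in AXES
)
N_CHANNELS = len(CHANNEL_NAMES)  # 36
N_ZONES = 12

# Relative burst loading per placement: back and wrists dominate, the other
# placements carry weaker signal.
_PLACEMENT_WEIGHTS = np.array([1.0, 0.85, 0.85, 0.5, 0.4, 0.3])
# How strongly each placement's loading grows with the risk class: the class
# signature lives mainly on the back and wrist channels; the remaining
# placements respond only weakly, so the discriminative information is the
# *pattern* across placements, not just overall energy.
_CLASS_SENSITIVITY = np.array([1.0, 1.0, 1.0, 0.3, 0.2, 0.1])
# Accelerometer bursts slightly stronger than gyroscope bursts.
_SENSOR_WEIGHTS = np.array([1.0, 0.8])
# Mild anisotropy across the x/y/z axes.
_AXIS_WEIGHTS = np.array([1.0, 0.8, 0.6])
# Burst carrier frequencies (Hz), inside the 2-12 Hz analysis band so the
# bandpass preprocessing preserves them.
_CARRIER_HZ = {"acc": 5.0, "gyro": 4.0}
_BURST_SIGMA_S = 0.4  # Gaussian envelope width (seconds)
_PICKUP_FRAC = 0.12  # burst centres as fractions of trial duration
_RETURN_FRAC = 0.88


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults mirror the benchmark design this package targets: 10 subjects,
    6 trials per subject in each of the 12 ACGIH zones (720 trials), 25 Hz
    sampling, a 30 s ceiling with most lifts lasting 10-15 s.
    """

    n_subjects: int = 10
    trials_per_zone_per_subject: int = 6
    sample_rate: float = 25.0
    max_duration: float = 30.0
    duration_range: tuple[float, float] = (10.0, 15.0)
    noise_sd: float = 0.25
    class_separation: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be a positive integer")
        if self.trials_per_zone_per_subject < 1:
            raise ValueError("trials_per_zone_per_subject must be a positive integer")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.max_duration <= 0:
            raise ValueError("max_duration must be positive")
        lo, hi = self.duration_range
        if not (0 < lo <= hi <= self.max_duration):
            raise ValueError(
                "duration_range must satisfy 0 < low <= high <= max_duration"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.class_separation < 0:
            raise ValueError("class_separation must be non-negative")


@dataclass
class RawTrial:
    """One lifting trial: an F x 36 signal block plus labels.

    ``meta`` records ground truth the simulator knows (burst centres in
    seconds), used by tests and by saliency diagnostics; trials read from
    disk may have an empty meta.
    """

    subject_id: str
    zone: int
    frames: np.ndarray  # (F, 36)
    sample_rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if not 1 <= int(self.zone) <= N_ZONES:
            raise ValueError(f"zone must be in 1..{N_ZONES}, got {self.zone}")
        if self.frames.ndim != 2 or self.frames.shape[1] != N_CHANNELS:
            raise ValueError(
                f"frames must be (F, {N_CHANNELS}), got {self.frames.shape}"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("trial must contain at least one frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.sample_rate


def _zone_class_index(zone: int) -> int:
    # local import keeps this module free of a circular dependency
    from .dataset import zone_to_risk

    return zone_to_risk(zone)


def channel_amplitudes(zone: int, class_separation: float) -> np.ndarray:
    """Deterministic per-channel burst amplitude for a zone's risk class.

    Per-placement gain = 1 + class_index * class_separation * sensitivity,
    with sensitivity 1 on back/wrists and small elsewhere, so each class has
    a distinct loading profile across the six placements.
    """
    gains = 1.0 + _zone_class_index(zone) * class_separation * _CLASS_SENSITIVITY
    amp = (
        (gains * _PLACEMENT_WEIGHTS)[:, None, None]
        * _SENSOR_WEIGHTS[None, :, None]
        * _AXIS_WEIGHTS[None, None, :]
    ).reshape(N_CHANNELS)
    return amp


def burst_frame_windows(
    duration: float, sample_rate: float, n_sigma: float = 3.0
) -> list[tuple[int, int]]:
    """Frame ranges [start, stop) covering the two bursts of a trial."""
    windows = []
    n = int(round(duration * sample_rate))
    half = n_sigma * _BURST_SIGMA_S * sample_rate
    for frac in (_PICKUP_FRAC, _RETURN_FRAC):
        centre = frac * duration * sample_rate
        windows.append((max(0, int(centre - half)), min(n, int(centre + half) + 1)))
    return windows


def simulate_trial(
    subject_id: str, zone: int, duration: float, config: SimConfig, rng: np.random.Generator
) -> RawTrial:
    n = int(round(duration * config.sample_rate))
    t = np.arange(n) / config.sample_rate
    amps = channel_amplitudes(zone, config.class_separation)
    signal = rng.normal(0.0, config.noise_sd, size=(n, N_CHANNELS))
    centres = (_PICKUP_FRAC * duration, _RETURN_FRAC * duration)
    for c, name in enumerate(CHANNEL_NAMES):
        sensor = name.split("_")[-2]
        f_carrier = _CARRIER_HZ[sensor]
        for centre in centres:
            phase = rng.uniform(0.0, 2.0 * np.pi)
            envelope = np.exp(-0.5 * ((t - centre) / _BURST_SIGMA_S) ** 2)
            signal[:, c] += amps[c] * envelope * np.sin(
                2.0 * np.pi * f_carrier * (t - centre) + phase
            )
    return RawTrial(
        subject_id=subject_id,
        zone=zone,
        frames=signal,
        sample_rate=config.sample_rate,
        meta={"burst_centres_s": list(centres), "duration_s": duration},
    )


def simulate_dataset(config: SimConfig) -> list[RawTrial]:
    """Generate the full factorial set of trials.

    Returns ``n_subjects * 12 * trials_per_zone_per_subject`` trials with
    durations drawn uniformly from ``duration_range``, fully reproducible
    from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    trials = []
    for s in range(config.n_subjects):
        subject_id = f"S{s + 1:02d}"
        for zone in range(1, N_ZONES + 1):
            for _ in range(config.trials_per_zone_per_subject):
                duration = rng.uniform(*config.duration_range)
                trials.append(simulate_trial(subject_id, zone, duration, config, rng))
    return trials


# ---------------------------------------------------------------------------
# CSV round trip: one file per trial plus a manifest.
# ---------------------------------------------------------------------------

MANIFEST_NAME = "manifest.csv"


def write_trials(trials, directory) -> pd.DataFrame:
    """Write one CSV per trial plus a manifest; returns the manifest frame."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, trial in enumerate(trials):
        fname = f"trial_{i:04d}.csv"
        df = pd.DataFrame(trial.frames, columns=list(CHANNEL_NAMES))
        df.to_csv(directory / fname, index=False, float_format="%.17g")
        rows.append(
            {
                "trial_id": i,
                "subject_id": trial.subject_id,
                "zone": trial.zone,
                "duration_s": trial.duration,
                "sample_rate": trial.sample_rate,
                "path": fname,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(directory / MANIFEST_NAME, index=False)
    return manifest


class TrialParseError(ValueError):
    """Raised when a trial file or manifest row fails validation."""


def read_trials(directory) -> list[RawTrial]:
    """Read back trials written by :func:`write_trials`.

    Raises :class:`TrialParseError` naming the offending file for missing
    channels, non-numeric cells or out-of-range zones.
    """
    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.exists():
        raise TrialParseError(f"no manifest found at {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    trials = []
    for row in manifest.itertuples():
        path = directory / row.path
        zone = int(row.zone)
        if not 1 <= zone <= N_ZONES:
            raise TrialParseError(
                f"{manifest_path}: trial {row.trial_id} has zone {zone}, "
                f"expected 1..{N_ZONES}"
            )
        df = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in CHANNEL_NAMES if c not in df.columns]
        if missing:
            raise TrialParseError(f"{path}: missing channel columns {missing}")
        block = df[list(CHANNEL_NAMES)]
        values = block.apply(pd.to_numeric, errors="coerce").to_numpy()
        if np.isnan(values).any():
            bad_row = int(np.argwhere(np.isnan(values))[0, 0]) + 2  # header + 1-based
            raise TrialParseError(f"{path}: non-numeric cell near line {bad_row}")
        trials.append(
            RawTrial(
                subject_id=str(row.subject_id),
                zone=zone,
                frames=values,
                sample_rate=float(row.sample_rate),
            )
        )
    return trials


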