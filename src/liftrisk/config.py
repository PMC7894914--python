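"""Experiment configuration: one YAML file drives a full run.

Every stage seed is derived deterministically from the global seed via
``numpy.random.SeedSequence`` spawning, so a single integer reproduces the
simulated data, fold assignments, weight initialisation and training
shuffles of an entire experiment.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .models import ModelSpec, TrainingConfig
from .preprocessing import FilterSpec
from .simulate import SimConfig

__all__ = ["ExperimentConfig", "stage_seeds"]

_STAGES = ("simulate", "folds", "train")


def stage_seeds(global_seed: int) -> dict[str, int]:
    """Deterministic per-stage seeds (kept below 2**31)."""
    children = np.random.SeedSequence(global_seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(_STAGES, children)
    }


@dataclass
class ExperimentConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    model: ModelSpec = field(default_factory=ModelSpec)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    scaler_mode: str = "zscore"
    n_folds: int = 4
    test_fraction: float = 0.25
    seed: int = 0
    compute_saliency: bool = False
    pooled_test_size: int | None = None  # None: mean fold test size

    def __post_init__(self):
        # stage seeds override whatever the nested configs carried
        seeds = stage_seeds(self.seed)
        self.sim = dataclasses.replace(self.sim, seed=seeds["simulate"])
        self.training = dataclasses.replace(self.training, seed=seeds["train"])
        self.fold_seed = seeds["folds"]

    # -- (de)serialisation ----------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "sim": dataclasses.asdict(self.sim),
            "filter": dataclasses.asdict(self.filter),
            "model": dataclasses.asdict(self.model),
            "training": dataclasses.asdict(self.training),
            "scaler_mode": self.scaler_mode,
            "n_folds": self.n_folds,
            "test_fraction": self.test_fraction,
            "seed": self.seed,
            "compute_saliency": self.compute_saliency,
            "pooled_test_size": self.pooled_test_size,
        }
        d["sim"]["duration_range"] = list(self.sim.duration_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        sim = dict(d.pop("sim", {}))
        if "duration_range" in sim:
            sim["duration_range"] = tuple(sim["duration_range"])
        return cls(
            sim=SimConfig(**sim),
            filter=FilterSpec(**d.pop("filter", {})),
            model=ModelSpec(**d.pop("model", {})),
            training=TrainingConfig(**d.pop("training", {})),
            **d,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
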