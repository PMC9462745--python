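"""Run configuration: YAML blocks, validation and hashing.

A run is exactly reproducible from its configuration file and the package
version; every stochastic component derives its stream from the single
``seed`` in the ``[training]`` block (task noise, read-out noise, action
sampling and mu sampling are separate child streams).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .integrators import TimescaleGrid, make_grid
from .learning import TrainingConfig
from .task import TaskParams

__all__ = ["RunConfig"]

_DEFAULT_EVALUATION = {"n_episodes": 10_000, "coherence_episodes": 2_000, "seed": 777}
_DEFAULT_INTEGRATORS = {"n_tau": 10, "tau_min": 0.1, "tau_max": 10.0, "spacing": "log"}
_DEFAULT_EXPERIMENT = {"variant": "full", "tau": None, "sigma_I_scale": 1.0}


@dataclass
class RunConfig:
    """Validated configuration for a train/evaluate/metrics run."""

    task: TaskParams = field(default_factory=TaskParams)
    integrators: dict = field(default_factory=lambda: dict(_DEFAULT_INTEGRATORS))
    training: TrainingConfig = field(default_factory=TrainingConfig)
    evaluation: dict = field(default_factory=lambda: dict(_DEFAULT_EVALUATION))
    experiment: dict = field(default_factory=lambda: dict(_DEFAULT_EXPERIMENT))

    def grid(self) -> TimescaleGrid:
        g = {**_DEFAULT_INTEGRATORS, **self.integrators}
        return make_grid(g["n_tau"], g["tau_min"], g["tau_max"], g["spacing"])

    def to_dict(self) -> dict:
        return {
            "task": dataclasses.asdict(self.task),
            "integrators": {**_DEFAULT_INTEGRATORS, **self.integrators},
            "training": {
                **dataclasses.asdict(self.training),
                "coherences": list(self.training.coherences),
            },
            "evaluation": {**_DEFAULT_EVALUATION, **self.evaluation},
            "experiment": {**_DEFAULT_EXPERIMENT, **self.experiment},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        task = TaskParams(**d.get("task", {}))
        training_d = dict(d.get("training", {}))
        if "coherences" in training_d:
            training_d["coherences"] = tuple(training_d["coherences"])
        training = TrainingConfig(**training_d)
        return cls(
            task=task,
            integrators={**_DEFAULT_INTEGRATORS, **d.get("integrators", {})},
            training=training,
            evaluation={**_DEFAULT_EVALUATION, **d.get("evaluation", {})},
            experiment={**_DEFAULT_EXPERIMENT, **d.get("experiment", {})},
        )

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def hash(self) -> str:
        """Stable content hash recorded in run manifests."""
        canon = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
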