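"""Pipeline configuration: explicit seeds everywhere, lossless round-trips.

The master seed is split into per-stage seeds with
:class:`numpy.random.SeedSequence` (``spawn_key`` by stage name hash), so
adding a stage never perturbs another stage's stream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .crp import Hyperparameters
from .model import FitConfig

__all__ = ["PipelineConfig", "stage_seed"]


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Derive a reproducible 31-bit seed for one pipeline stage."""
    key = np.frombuffer(stage.encode(), dtype=np.uint8)
    ss = np.random.SeedSequence([master_seed, index, *key.tolist()])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    """Everything needed to re-run simulate -> fit -> analyze end to end."""

    experiments: list = field(default_factory=lambda: ["exp1", "exp2", "exp3"])
    design_overrides: dict = field(default_factory=dict)  # per experiment id
    n_subjects: int = 14
    master_seed: int = 0
    responder: str = "ideal_observer"
    response_noise_sd: float = 2.0
    n_particles_simulate: int = 300
    hyperparameters: dict = field(default_factory=lambda: asdict(Hyperparameters()))
    fit: dict = field(default_factory=lambda: asdict(FitConfig()))
    output_dir: str = "results"

    def hp(self) -> Hyperparameters:
        return Hyperparameters(**self.hyperparameters)

    def fit_config(self) -> FitConfig:
        return FitConfig(**self.fit)

    def to_dict(self) -> dict:
        # JSON-canonical (tuples -> lists) so round-trips compare equal
        return json.loads(json.dumps(asdict(self)))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; expected a subset of "
                f"{sorted(known)}")
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        text = yaml.safe_dump(self.to_dict(), sort_keys=False) \
            if path.suffix in (".yaml", ".yml") else json.dumps(self.to_dict(), indent=2)
        path.write_text(text)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
            else json.loads(text)
        return cls.from_dict(d)
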