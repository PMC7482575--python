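"""Experiment configuration: a validated, YAML-round-trippable record of
everything needed to regenerate an experiment bit for bit (model, topology
family, grids, run counts, seed)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .exceptions import InvalidSpecError


@dataclass
class ExperimentConfig:
    model: str                      # "vn" | "ae"
    L: int
    family: str                     # "nn2er" | "nn2sf"
    p_grid: list[float]
    eta_grid: list[float]
    runs: int
    steps: int
    seed: int
    b: float = -2.0
    b_grid: list[float] | None = None   # only for exponent sweeps (p = 1)
    burn_in: float = 0.5
    threshold: float = 0.5
    var_how: str = "pooled"
    out_dir: str = "."
    name: str = "experiment"

    def __post_init__(self):
        if self.model not in ("vn", "ae"):
            raise InvalidSpecError(f"unknown model {self.model!r}")
        if self.family not in ("nn2er", "nn2sf"):
            raise InvalidSpecError(f"unknown family {self.family!r}")
        for grid, nm in ((self.p_grid, "p_grid"), (self.eta_grid, "eta_grid")):
            arr = np.asarray(grid, dtype=float)
            if arr.size == 0 or np.any(np.diff(arr) <= 0):
                raise InvalidSpecError(f"{nm} must be non-empty and strictly increasing")
        if self.runs < 1 or self.steps < 1:
            raise InvalidSpecError("runs and steps must be >= 1")
        if self.family == "nn2sf" and self.b >= 0:
            raise InvalidSpecError("b must be negative for the nn2sf family")
        if not 0.0 <= self.burn_in < 1.0:
            raise InvalidSpecError("burn_in must lie in [0, 1)")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)
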