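"""File formats and run configuration.

XYZ here is the plain multi-record dialect: an atom-count line, a free-text
comment line, then ``element x y z`` rows in Å printed at 1e-6 precision;
records concatenate back to back.  The run configuration is a strict
(unknown keys rejected) YAML/JSON schema with documented defaults, hashed so
every run can be reproduced from its logged config and seeds.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .diffusion import (
    DEFAULT_BETA_END,
    DEFAULT_BETA_START,
    DEFAULT_KIND,
    DEFAULT_T,
    NoiseSchedule,
    make_schedule,
)

__all__ = [
    "XYZParseError",
    "read_xyz",
    "write_xyz",
    "RunConfig",
    "load_config",
    "SYMBOL_TO_Z",
    "Z_TO_SYMBOL",
]

Z_TO_SYMBOL = {1: "H", 6: "C", 7: "N", 8: "O", 9: "F", 16: "S", 17: "Cl"}
SYMBOL_TO_Z = {v: k for k, v in Z_TO_SYMBOL.items()}


class XYZParseError(ValueError):
    """Malformed XYZ input; the message carries the offending line number."""


def read_xyz(path) -> list[tuple[np.ndarray, list[str], str]]:
    """Read a (multi-record) XYZ file into ``[(coords, elements, comment)]``."""
    records = []
    lines = Path(path).read_text().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():  # trailing blank lines
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError:
            raise XYZParseError(f"line {pos + 1}: expected atom count, got {lines[pos]!r}")
        if pos + 2 + n > len(lines):
            raise XYZParseError(f"line {pos + 1}: record of {n} atoms is truncated")
        comment = lines[pos + 1] if pos + 1 < len(lines) else ""
        coords = np.zeros((n, 3))
        elements: list[str] = []
        for k in range(n):
            lineno = pos + 2 + k
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise XYZParseError(f"line {lineno + 1}: expected 'element x y z'")
            elements.append(parts[0])
            try:
                coords[k] = [float(v) for v in parts[1:4]]
            except ValueError:
                raise XYZParseError(f"line {lineno + 1}: bad coordinate in {parts[1:4]}")
        records.append((coords, elements, comment))
        pos += 2 + n
    return records


def write_xyz(path, records: list[tuple[np.ndarray, list[str], str]]) -> None:
    """Write records as concatenated XYZ; lossless round-trip at 1e-6 Å."""
    out = []
    for coords, elements, comment in records:
        coords = np.asarray(coords, dtype=np.float64)
        if coords.shape != (len(elements), 3):
            raise ValueError("coordinate/element length mismatch")
        out.append(str(len(elements)))
        out.append(comment.replace("\n", " "))
        for el, (x, y, z) in zip(elements, coords):
            out.append(f"{el} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(out) + ("\n" if out else ""))


# -- run configuration --------------------------------------------------------


class ScheduleSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    T: int = DEFAULT_T
    kind: str = DEFAULT_KIND
    beta_start: float = DEFAULT_BETA_START
    beta_end: float = DEFAULT_BETA_END
    sigma_mode: str = "beta"

    @field_validator("T")
    @classmethod
    def _t_positive(cls, v: int) -> int:
        if v < 1:
            raise ValueError("schedule.T must be >= 1")
        return v


class ModelSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    hidden: int = 256
    n_layers: int = 7
    n_rbf: int = 64
    rbf_max: float = 10.0
    cutoff: float = 10.0
    time_dim: int = 16


class SamplerSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    rounds: int = 8
    ensemble_size: int = 1
    combine: str = "mean"  # per-step eps averaging across the ensemble


class TrainSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    optimizer: str = "adam"
    lr: float = 1e-3
    batch_size: int = 32
    n_steps: int = 1000


class SeedsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    train: int = 0
    sample: int = 1


class PathsSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    checkpoint: str | None = None
    out_dir: str | None = None


class RunConfig(BaseModel):
    """Top-level run configuration; unknown keys are rejected with their path."""

    model_config = ConfigDict(extra="forbid")
    schedule: ScheduleSection = Field(default_factory=ScheduleSection)
    model: ModelSection = Field(default_factory=ModelSection)
    sampler: SamplerSection = Field(default_factory=SamplerSection)
    train: TrainSection = Field(default_factory=TrainSection)
    seeds: SeedsSection = Field(default_factory=SeedsSection)
    paths: PathsSection = Field(default_factory=PathsSection)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def make_schedule(self, prior_tol: float | None = None) -> NoiseSchedule:
        s = self.schedule
        return make_schedule(
            s.T, s.kind, s.beta_start, s.beta_end, s.sigma_mode, prior_tol=prior_tol
        )


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run config; an empty file means defaults."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    return RunConfig.model_validate(data)
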