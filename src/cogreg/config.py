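"""Run configuration: schema validation, defaults, and run manifests."""

from __future__ import annotations

import hashlib
import json
import platform
import time
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, field_validator


class SamplerSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_chains: int = 2
    n_iterations: int = 3000
    n_burnin: int = 1000
    thin: int = 1
    target_accept: float = 0.25

    @field_validator("n_chains", "n_iterations", "thin")
    @classmethod
    def _positive(cls, v):
        if v < 1:
            raise ValueError("must be >= 1")
        return v


#: The full-scale simulation protocol (2 chains x 45,000 iterations,
#: 5,000 burn-in, thin 5).
PAPER_SCALE_SAMPLER = dict(n_chains=2, n_iterations=45_000, n_burnin=5_000,
                           thin=5)


class ScenarioSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_participants: int = 150
    n_trials: int = 200
    rho: float = 0.0
    n_datasets: int = 50
    sigma_as: str = "sd"

    @field_validator("rho")
    @classmethod
    def _valid_rho(cls, v):
        if not -1.0 < v < 1.0:
            raise ValueError("covariate correlation must satisfy |rho| < 1")
        return v

    @field_validator("sigma_as")
    @classmethod
    def _valid_sigma(cls, v):
        if v not in ("sd", "var"):
            raise ValueError("sigma_as must be 'sd' or 'var'")
        return v


class PriorSection(BaseModel):
    model_config = ConfigDict(extra="forbid")

    cauchy_scale: float = 1.0

    @field_validator("cauchy_scale")
    @classmethod
    def _positive_scale(cls, v):
        if v <= 0:
            raise ValueError("Cauchy scale must be positive")
        return v


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    sampler: SamplerSection = SamplerSection()
    scenario: ScenarioSection = ScenarioSection()
    prior: PriorSection = PriorSection()


def validate_config(document) -> RunConfig:
    """Validate a config mapping (or YAML/JSON text); fill defaults,
    reject unknown keys with a path-to-key message."""
    if document is None:
        document = {}
    if isinstance(document, (str, bytes)):
        document = yaml.safe_load(document) or {}
    return RunConfig.model_validate(document)


def load_config(path) -> RunConfig:
    return validate_config(Path(path).read_text())


def file_digest(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class RunManifest:
    """Record of one CLI run: config, seeds, inputs, timings, flags."""

    def __init__(self, command: str, config: dict, seed):
        from . import __version__

        self.data = {
            "command": command,
            "config": config,
            "seed": seed,
            "version": __version__,
            "python": platform.python_version(),
            "inputs": {},
            "stages": {},
            "convergence": {},
        }
        self._t0 = {}

    def add_input(self, name, path):
        self.data["inputs"][name] = {
            "path": str(path), "sha256": file_digest(path)}

    def start(self, stage):
        self._t0[stage] = time.perf_counter()

    def stop(self, stage):
        self.data["stages"][stage] = round(
            time.perf_counter() - self._t0.pop(stage), 3)

    def flag_convergence(self, name, max_rhat, ok):
        self.data["convergence"][name] = {
            "max_rhat": float(max_rhat), "converged": bool(ok)}

    def write(self, path):
        Path(path).write_text(json.dumps(self.data, indent=2, default=str))
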