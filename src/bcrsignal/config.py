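"""Run configuration: validated, serializable, with deterministic stage seeds."""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import pydantic
import yaml
from pydantic import BaseModel, Field

from .errors import ConfigurationError
from .model import ParameterSet
from .nominal import nominal_parameters


class _Block(BaseModel, extra="forbid", validate_assignment=True):
    pass


class SimulateBlock(_Block):
    rtol: float = 1e-8
    atol: float = 1e-10
    eps_basal: float = Field(1e-6, gt=0)
    horizon: int = Field(30, ge=1)              # minutes
    t_obs_erkp: float = Field(5.0, ge=0)        # minutes
    t_obs_ikb: float = Field(15.0, ge=0)
    doses: list[float] = [5.5, 16.5, 50.0, 150.0]   # ug/mL
    oi_levels: list[float] = [0.0, 0.5, 1.0]        # uM


class SensitivityBlock(_Block):
    group: int = Field(1, ge=1, le=7)
    n_samples: int = Field(32, ge=2)
    range_decades: float = Field(1.0, gt=0)
    stimulus_dose: float = Field(20.0, gt=0)


class ScreeningBlock(_Block):
    n_candidates: int = Field(100, ge=1)
    decades: float = Field(2.0, gt=0)
    eta_default: float = Field(1.0, gt=0)
    thresholds: dict[str, float] = {"healy_erkp": 1.0, "healy_ikb": 2.0}
    budget_per_candidate: float = Field(20.0, gt=0)   # seconds
    rtol: float = 1e-6
    atol: float = 1e-9


class ContourBlock(_Block):
    n_per_axis: int = Field(6, ge=2)
    log_kf: tuple[float, float] = (-2.0, 2.0)
    log_kr: tuple[float, float] = (-2.0, 2.0)
    oi_dose: float = Field(1.0, ge=0)
    dose: float = Field(20.0, gt=0)
    budget_per_point: float = Field(30.0, gt=0)       # seconds
    log10_kr_split: float = -0.5


class SyntheticBlock(_Block):
    shape: str = "healy_like"
    noise: str = "linear_sigma"
    replicates: int = Field(3, ge=1)
    perturbation_decades: float = Field(0.2, ge=0)


class RunConfig(_Block):
    """Top-level configuration for the staged workflow."""

    outdir: str = "results"
    parameter_file: str | None = None
    scenario: str = "WT"
    seed: int = Field(0, ge=0)
    data_path: str | None = None
    simulate: SimulateBlock = SimulateBlock()
    sensitivity: SensitivityBlock = SensitivityBlock()
    screening: ScreeningBlock = ScreeningBlock()
    contour: ContourBlock = ContourBlock()
    synthetic: SyntheticBlock = SyntheticBlock()

    def parameters(self) -> ParameterSet:
        if self.parameter_file:
            return ParameterSet.load(self.parameter_file)
        return nominal_parameters()

    def to_dict(self) -> dict:
        return json.loads(self.model_dump_json())


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed (< 2**31) derived from the global seed."""
    return zlib.crc32(f"{stage}:{global_seed}".encode()) % (2 ** 31)


def load_config(path) -> RunConfig:
    """Parse and validate a YAML or JSON config; unknown keys are rejected."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    data = (yaml.safe_load(text) if path.suffix in (".yaml", ".yml")
            else json.loads(text)) or {}
    try:
        return RunConfig(**data)
    except pydantic.ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in exc.errors())
        raise ConfigurationError(f"invalid config {path}: {details}") from exc


def save_config(config: RunConfig, path) -> None:
    path = Path(path)
    payload = config.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=True))
    else:
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
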