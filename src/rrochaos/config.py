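"""Run configuration: YAML parsing, validation, and lossless round-trips.

A run config has flat sections (``model``, ``control``, ``drive``, ``sim``,
``grids``) plus the experiment name, output directory, master seed and log
level.  Unknown sections or keys are rejected; parameter invariants are
enforced by the dataclasses in :mod:`rrochaos.params`.  Every CLI run writes
its resolved config beside its outputs so that results are reproducible from
the sidecar alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .exceptions import ConfigError
from .params import ControlParams, DriveParams, ModelParams, SimulationConfig

EXPERIMENTS = ("sweep-a", "sweep-k", "resonance", "forced", "timeseries",
               "lyapunov", "bifpoint")

_SECTION_TYPES = {
    "model": ModelParams,
    "control": ControlParams,
    "drive": DriveParams,
    "sim": SimulationConfig,
}
_TOP_KEYS = {"experiment", "model", "control", "drive", "sim", "grids",
             "out_dir", "seed", "log_level"}
_GRID_KEYS = {"a_min", "a_max", "a_step", "k_min", "k_max", "k_step",
              "alpha_min", "alpha_max", "alpha_step", "k_hi",
              "reference_corr", "x0"}


@dataclass
class RunConfig:
    experiment: str
    model: ModelParams
    control: ControlParams = ControlParams()
    drive: DriveParams = DriveParams()
    sim: SimulationConfig = SimulationConfig()
    grids: dict = field(default_factory=dict)
    out_dir: str = "."
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ConfigError(f"unknown experiment {self.experiment!r}; "
                              f"expected one of {EXPERIMENTS}")
        unknown = set(self.grids) - _GRID_KEYS
        if unknown:
            raise ConfigError(f"unknown grid keys: {sorted(unknown)}")
        # the master seed propagates into the simulation settings
        self.sim = SimulationConfig(**{**self.sim.to_dict(), "seed": self.seed,
                                       "x0_interval": self.sim.x0_interval})

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "model": asdict(self.model),
            "control": asdict(self.control),
            "drive": asdict(self.drive),
            "sim": self.sim.to_dict(),
            "grids": dict(self.grids),
            "out_dir": str(self.out_dir),
            "seed": self.seed,
            "log_level": self.log_level,
        }

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


def _build_section(name: str, data: dict):
    cls = _SECTION_TYPES[name]
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    if name == "sim" and "x0_interval" in data:
        data = {**data, "x0_interval": tuple(data["x0_interval"])}
    try:
        return cls(**data)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid section {name!r}: {e}") from e


def config_from_dict(raw: dict) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
    if "experiment" not in raw:
        raise ConfigError("config must name an experiment")
    if "model" not in raw or "A" not in raw.get("model", {}):
        raise ConfigError("config must provide model.A (the bifurcation parameter)")
    kw: dict = {"experiment": raw["experiment"]}
    for name in _SECTION_TYPES:
        if name in raw:
            kw[name] = _build_section(name, dict(raw[name]))
    for key in ("grids", "out_dir", "seed", "log_level"):
        if key in raw:
            kw[key] = raw[key]
    return RunConfig(**kw)


def parse_config(path) -> RunConfig:
    """Load and validate a YAML run config, filling documented defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ConfigError(f"malformed YAML in {path}: {e}") from e
    return config_from_dict(raw or {})
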