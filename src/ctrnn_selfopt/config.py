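"""Run configuration: TOML file loading, validation and hashing.

A run config is a nested key-value table whose sections mirror the
library's parameter objects (condition, network, learning, experiment,
output).  Unknown sections or keys are rejected so typos fail loudly, and
every output file records the config's SHA-256 hash together with the
master seed, which is enough to reproduce the run bitwise.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .experiment_protocol import ExperimentPlan
from .self_optimization import DEFAULT_STATE_BOUNDS, LearningConfig
from .weight_conditions import ConditionSpec

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending key."""


_SCHEMA: dict[str, dict[str, type | tuple]] = {
    "condition": {
        "family": str,
        "n_nodes": int,
        "module_size": int,
        "p_positive": float,
        "q_magnitude": float,
    },
    "network": {
        "dt": float,
        "duration": float,
        "tau_range": list,
        "gain_range": list,
    },
    "learning": {
        "delta": float,
        "n_learning_relaxations": int,
        "state_bounds": list,
        "mode": str,
    },
    "experiment": {
        "n_weight_configs": int,
        "n_repetitions_per_config": int,
        "n_before": int,
        "n_after": int,
        "master_seed": int,
    },
    "output": {
        "directory": str,
        "log_level": str,
    },
}


@dataclass
class RunConfig:
    """Validated flat view of a run configuration file."""

    condition: dict[str, Any] = field(default_factory=dict)
    network: dict[str, Any] = field(default_factory=dict)
    learning: dict[str, Any] = field(default_factory=dict)
    experiment: dict[str, Any] = field(default_factory=dict)
    output: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        for section, keys in data.items():
            if section not in _SCHEMA:
                raise ConfigError(f"unknown config section [{section}]")
            for key, value in keys.items():
                if key not in _SCHEMA[section]:
                    raise ConfigError(f"unknown config key {section}.{key}")
                expected = _SCHEMA[section][key]
                if expected is float and isinstance(value, int):
                    keys[key] = float(value)
                elif not isinstance(value, expected):
                    raise ConfigError(
                        f"config key {section}.{key} expects {expected.__name__}, "
                        f"got {type(value).__name__}"
                    )
        return cls(**{s: data.get(s, {}) for s in _SCHEMA})

    def to_dict(self) -> dict[str, Any]:
        return {
            s: dict(getattr(self, s)) for s in _SCHEMA if getattr(self, s)
        }

    @property
    def hash(self) -> str:
        """SHA-256 of the canonical JSON form (sorted keys)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    # -- object builders ------------------------------------------------

    def condition_spec(self, seed: int | None = None) -> ConditionSpec:
        kwargs = dict(self.condition)
        if "family" not in kwargs:
            raise ConfigError("missing required key condition.family")
        return ConditionSpec(seed=seed, **kwargs)

    def learning_config(self, default_delta: float | None = None) -> LearningConfig:
        kwargs = dict(self.learning)
        if "state_bounds" in kwargs:
            kwargs["state_bounds"] = tuple(kwargs["state_bounds"])
        if "delta" not in kwargs and default_delta is not None:
            kwargs["delta"] = default_delta
        return LearningConfig(**kwargs)

    def experiment_plan(self, master_seed: int | None = None) -> ExperimentPlan:
        spec = self.condition_spec()
        kwargs: dict[str, Any] = dict(self.experiment)
        if master_seed is not None:
            kwargs["master_seed"] = master_seed
        for key in ("dt", "duration"):
            if key in self.network:
                kwargs[key] = self.network[key]
        for key in ("tau_range", "gain_range"):
            if key in self.network:
                kwargs[key] = tuple(self.network[key])
        if "delta" in self.learning:
            kwargs["delta"] = self.learning["delta"]
        if "n_learning_relaxations" in self.learning:
            kwargs["n_learning"] = self.learning["n_learning_relaxations"]
        if "state_bounds" in self.learning:
            kwargs["state_bounds"] = tuple(self.learning["state_bounds"])
        if "mode" in self.learning:
            kwargs["mode"] = self.learning["mode"]
        return ExperimentPlan(condition=spec, **kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a TOML run-configuration file."""
    with Path(path).open("rb") as fh:
        try:
            data = tomllib.load(fh)
        except tomllib.TOMLDecodeError as err:
            raise ConfigError(f"malformed config file {path}: {err}") from err
    return RunConfig.from_dict(data)
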