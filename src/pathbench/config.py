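"""Versioned YAML run-configuration schema.

A run config describes everything a benchmark needs: where the network comes
from (a file or a synthetic model), how FG/BG gold standards are generated,
which expression model and signal-strength grid to simulate, and which
method adapters to sweep over which internal-parameter (IP) grids. All
randomness flows from the single ``seed``. Unknown keys are schema errors,
so typos fail before any work starts.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .adapters import (
    BUILTIN_ADAPTERS,
    ExternalCommandAdapter,
    MethodAdapter,
    get_builtin_adapter,
)
from .expression_sim import DEFAULT_VM_GRID, DEFAULT_VV_GRID

__all__ = ["RunConfig", "load_config", "ConfigError"]

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """A run configuration failed schema validation."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticNetworkSpec(_Strict):
    model: Literal["preferential_attachment", "ring_lattice", "erdos_renyi"]
    n_nodes: int = Field(ge=2)
    params: dict[str, float] = Field(default_factory=dict)


class NetworkSpec(_Strict):
    path: str | None = None
    format: Literal["tsv", "sif"] | None = None
    synthetic: SyntheticNetworkSpec | None = None
    #: Restricting to the largest connected component is an explicit, logged
    #: choice; shortest-path-based FG selection needs a connected substrate.
    restrict_to_lcc: bool = True

    @model_validator(mode="after")
    def _one_source(self):
        if (self.path is None) == (self.synthetic is None):
            raise ValueError("network needs exactly one of 'path' or 'synthetic'")
        return self


class FgSelectionSpec(_Strict):
    generator: Literal["SAE", "AVDk"]
    n: int = Field(default=20, ge=1)
    k: float | None = Field(default=None, gt=0)
    alpha: float = Field(default=1.0, ge=0)
    count: int = Field(default=1, ge=1)
    max_restarts: int = Field(default=50, ge=1)

    @model_validator(mode="after")
    def _k_for_avdk(self):
        if self.generator == "AVDk" and self.k is None:
            raise ValueError("AVDk requires a target average distance 'k'")
        return self

    def params(self) -> dict:
        if self.generator == "SAE":
            return {"n": self.n}
        return {
            "n": self.n,
            "k": self.k,
            "alpha": self.alpha,
            "max_restarts": self.max_restarts,
        }


class SimulationSpec(_Strict):
    model: Literal["VM", "VV"]
    n_cases: int = Field(default=100, ge=2)
    n_controls: int = Field(default=10, ge=2)
    signal_strengths: list[float] | None = None

    def grid(self) -> list[float]:
        if self.signal_strengths is not None:
            return list(self.signal_strengths)
        return list(DEFAULT_VM_GRID if self.model == "VM" else DEFAULT_VV_GRID)


class AdapterSpec(_Strict):
    name: str
    builtin: str | None = None
    command: str | None = None
    timeout: float | None = Field(default=None, gt=0)
    #: Each key maps to a list of values; the IP grid is the Cartesian
    #: product over keys (one dict per grid point).
    ip_grid: dict[str, list] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _one_kind(self):
        if (self.builtin is None) == (self.command is None):
            raise ValueError(f"adapter {self.name!r} needs exactly one of 'builtin' or 'command'")
        if self.builtin is not None and self.builtin not in BUILTIN_ADAPTERS:
            raise ValueError(
                f"unknown builtin adapter {self.builtin!r}; "
                f"available: {sorted(BUILTIN_ADAPTERS)}"
            )
        return self

    def build(self) -> MethodAdapter:
        if self.builtin is not None:
            adapter = get_builtin_adapter(self.builtin)
            adapter.name = self.name
            return adapter
        return ExternalCommandAdapter(self.name, self.command, timeout=self.timeout)

    def grid_points(self) -> list[dict]:
        if not self.ip_grid:
            return [{}]
        keys = sorted(self.ip_grid)
        return [
            dict(zip(keys, values))
            for values in itertools.product(*(self.ip_grid[k] for k in keys))
        ]


class RunConfig(_Strict):
    """Top-level, schema-checked description of one benchmark run."""

    schema_version: int = SCHEMA_VERSION
    seed: int = 0
    network: NetworkSpec
    fg_selection: FgSelectionSpec
    simulation: SimulationSpec | None = None
    adapters: list[AdapterSpec] = Field(default_factory=list)

    @model_validator(mode="after")
    def _version(self):
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(
                f"unsupported schema_version {self.schema_version}; "
                f"this release reads version {SCHEMA_VERSION}"
            )
        return self

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha1(blob.encode()).hexdigest()


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Raises :class:`ConfigError` with the offending key path on schema
    violations (unknown keys included).
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    try:
        return RunConfig.model_validate(raw)
    except Exception as exc:  # pydantic.ValidationError
        raise ConfigError(f"{path}: {exc}") from exc
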