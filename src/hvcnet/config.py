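"""Run configuration: schema-validated settings with shipped defaults.

``RunConfig()`` reproduces the default study conditions; a YAML file given
to :func:`load_config` may override any subset of keys.  Unknown keys are
rejected with an error naming every offending field.
"""

from __future__ import annotations

from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, field_validator

from .params import ConfigurationError, load_defaults

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class NetworkConfig(_Strict):
    pools: dict[str, int]
    n_circuits: int
    ra_per_circuit: tuple[int, int]
    int_per_circuit: tuple[int, int]
    x_per_circuit: tuple[int, int]
    ra_to_int_in: tuple[int, int]
    int_to_ra_out: tuple[int, int]
    x_to_int_out: tuple[int, int]
    int_to_x_out: tuple[int, int]
    max_retries: int = 1000
    cell_overrides: dict[str, dict[str, float]] = {}

    @field_validator("pools")
    @classmethod
    def _pools_ok(cls, v):
        if set(v) != {"RA", "INT", "X"}:
            raise ValueError("pools must have exactly the keys RA, INT, X")
        if any(n <= 0 for n in v.values()):
            raise ValueError("pool sizes must be positive")
        return v


class SynapseRange(_Strict):
    lo: float
    hi: float
    default: float

    @field_validator("hi")
    @classmethod
    def _ordered(cls, v, info):
        if "lo" in info.data and v < info.data["lo"]:
            raise ValueError("hi must be >= lo")
        return v


class SolverSection(_Strict):
    method: str = "fixed_rk4_em"
    dt: float = 0.01
    record_stride: int = 10
    duration: float = 1000.0
    rel_tol: float = 1e-6
    abs_tol: float = 1e-8

    @field_validator("dt", "duration")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"solver.{info.field_name} must be > 0")
        return v


class NoiseSection(_Strict):
    sigma_percent: float = 0.0
    reference_driving_force_mV: float = 60.0

    @field_validator("sigma_percent")
    @classmethod
    def _nonneg(cls, v):
        if v < 0:
            raise ValueError("noise.sigma_percent must be >= 0")
        return v


class StimulusSection(_Strict):
    kick_amplitude_nA: float = 0.25
    kick_width_ms: float = 20.0
    kick_onset_ms: float = 5.0


class AnalysisSection(_Strict):
    spike_threshold: float = -20.0
    refractory: float = 1.0
    isi_threshold: float = 15.0
    min_burst_spikes: int = 2
    ra_spikes_per_burst: tuple[int, int] = (3, 6)
    ra_max_burst_duration: float = 10.0
    x_bursts: tuple[int, int] = (1, 4)
    x_spikes_per_burst: tuple[int, int] = (4, 9)
    int_window_ms: float = 100.0
    int_min_bursts: int = 2


class ExperimentSection(_Strict):
    x_variation_ranges: dict[str, tuple[float, float]]
    perturbation_fold_default: float = 15.0


class SeedSection(_Strict):
    network: int = 0
    noise: int = 0


class RunConfig(_Strict):
    network: NetworkConfig
    synapse_conductances: dict[str, SynapseRange]
    solver: SolverSection = SolverSection()
    noise: NoiseSection = NoiseSection()
    stimulus: StimulusSection = StimulusSection()
    analysis: AnalysisSection = AnalysisSection()
    experiments: ExperimentSection
    seeds: SeedSection = SeedSection()

    def __init__(self, **overrides):
        base = _defaults_as_config_dict()
        merged = _deep_merge(base, overrides)
        super().__init__(**merged)

    @property
    def synaptic_ranges(self) -> dict[str, tuple[float, float]]:
        return {k: (v.lo, v.hi) for k, v in self.synapse_conductances.items()}

    def network_dict(self) -> dict:
        return self.network.model_dump()

    def dump(self) -> dict:
        return self.model_dump()

    def echo(self, path) -> None:
        """Write the fully resolved configuration next to run outputs."""
        with open(path, "w") as f:
            yaml.safe_dump(self.dump(), f, sort_keys=True)


def _defaults_as_config_dict() -> dict:
    raw = load_defaults()
    return {
        "network": raw["network"],
        "synapse_conductances": raw["synapses"]["conductances"],
        "solver": raw["solver"],
        "noise": raw["noise"],
        "stimulus": {
            "kick_amplitude_nA": raw["stimulus"]["kick_amplitude_nA"],
            "kick_width_ms": raw["stimulus"]["kick_width_ms"],
            "kick_onset_ms": raw["stimulus"]["kick_onset_ms"],
        },
        "analysis": raw["analysis"],
        "experiments": raw["experiments"],
        "seeds": {"network": 0, "noise": 0},
    }


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> RunConfig:
    """Load a YAML config file, filling unset keys from the defaults.

    An empty file yields the full default configuration.  Schema
    violations raise :class:`ConfigurationError` listing every offending
    key.
    """
    with open(path) as f:
        user = yaml.safe_load(f) or {}
    if not isinstance(user, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    try:
        return RunConfig(**user)
    except ValidationError as e:
        lines = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in e.errors()
        ]
        raise ConfigurationError(
            "invalid configuration:\n  " + "\n  ".join(lines)
        ) from None
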