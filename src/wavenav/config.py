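"""Structured run configuration: defaults, validation, hashing.

One master seed deterministically derives independent per-stage streams
(field assignment, exploration, planning noise, navigation), so any stage
can be reproduced in isolation.  Units follow the package convention
(seconds, metres, nA, mV); the file format accepts the same.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import numpy as np

from .exploration import ExplorationConfig
from .navigation import AgentParams
from .network import InhibitionParams, NeuronParams, STDPConfig

__all__ = ["RunConfig", "validate_config", "derive_seeds"]


@dataclass
class EnvironmentConfig:
    shape: str = "open"             # open | T | ring | A | inf
    n_cells: int = 2000
    grid_pitch: float | None = None
    jitter_sd: float | None = None  # default pitch/4
    footprint_target: float = 36.0  # cells within 2 sigma
    amplitude: float = 20.0         # nA, exploration-phase sensory peak


@dataclass
class RunConfig:
    environment: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    neuron: NeuronParams = field(default_factory=NeuronParams)
    inhibition: InhibitionParams = field(default_factory=InhibitionParams)
    stdp: STDPConfig = field(default_factory=STDPConfig)
    exploration: ExplorationConfig = field(default_factory=ExplorationConfig)
    agent: AgentParams = field(default_factory=AgentParams)
    seed: int = 0
    scenario: str = ""

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        kwargs = {}
        section_types = {
            "environment": EnvironmentConfig,
            "neuron": NeuronParams,
            "inhibition": InhibitionParams,
            "stdp": STDPConfig,
            "exploration": ExplorationConfig,
            "agent": AgentParams,
        }
        for name, typ in section_types.items():
            section = data.pop(name, {}) or {}
            valid = {f.name for f in fields(typ)}
            unknown = set(section) - valid
            if unknown:
                raise ValueError(f"unknown keys in [{name}]: {sorted(unknown)}")
            kwargs[name] = typ(**section)
        for key in ("seed", "scenario"):
            if key in data:
                kwargs[key] = data.pop(key)
        if data:
            raise ValueError(f"unknown top-level config keys: {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def summary_table(self) -> str:
        lines = []
        for name, section in sorted(self.to_dict().items()):
            if isinstance(section, dict):
                for k, v in sorted(section.items()):
                    lines.append(f"{name}.{k} = {v}")
            else:
                lines.append(f"{name} = {section}")
        return "\n".join(lines)


def validate_config(data: dict | RunConfig) -> RunConfig:
    """Normalise and range-check a configuration; raises ValueError with
    every violation collected."""
    cfg = data if isinstance(data, RunConfig) else RunConfig.from_dict(data)
    errors = []
    e = cfg.environment
    if e.n_cells < 4:
        errors.append("environment.n_cells must be at least 4")
    elif e.n_cells < 500:
        import warnings

        warnings.warn(
            f"n_cells = {e.n_cells}: receptive-field footprints cannot reach "
            "the intended 25-50 cell range at this size",
            stacklevel=2,
        )
    if e.footprint_target <= 0:
        errors.append("environment.footprint_target must be positive")
    # dataclass __post_init__ already guards the per-section invariants;
    # re-run them in case the object was mutated after construction
    for section in (cfg.neuron, cfg.stdp, cfg.exploration):
        try:
            section.__post_init__()
        except ValueError as err:
            errors.append(str(err))
    if cfg.inhibition.tau_e <= 0 or cfg.inhibition.a_e < 0:
        errors.append("inhibition.tau_e must be > 0 and a_e >= 0")
    if cfg.agent.mass <= 0 or cfg.agent.damping < 0:
        errors.append("agent.mass must be > 0 and damping >= 0")
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg


def derive_seeds(master_seed: int, names=("fields", "explore", "plan", "navigate")):
    """Independent child seeds (below 2**31) for each pipeline stage."""
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(names))
    return {
        name: int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for name, child in zip(names, children)
    }
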