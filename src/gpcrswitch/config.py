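"""Run configuration: a declarative YAML file validated before any computation.

Unknown keys are rejected so typos fail fast.  Defaults are the study values
where the study states them (9.5 / 5 / 3 / 2 Å cutoffs, γ = 10, hill 0.1
kcal/mol with 0.1 Å widths every 4 ps at 300 K); everything else is a
package decision documented in the methods note.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    topology: str = ""
    bw_table: str = ""
    trajectories: list = field(default_factory=list)
    receptor: str = ""
    reference: str = ""  # reference/crystal structure PDB (defaults to topology)
    outdir: str = "gpcrswitch_out"
    seed: int = 0
    stride: int = 1
    equilibration_frames: int = 0
    activation_threshold: float = 9.5
    ionic_lock_threshold: float = 5.0
    salt_bridge_threshold: float = 4.0
    contact_cutoff: float = 3.0
    water_cutoff: float = 2.0
    rotation_span: str = "6.44-6.50"
    gamma: "float | None" = None
    temperature: float = 300.0
    grid_min: float = 6.0
    grid_max: float = 14.0
    grid_nodes: int = 120
    hills_files: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.stride < 1:
            raise ConfigError("stride must be >= 1")
        if self.equilibration_frames < 0:
            raise ConfigError("equilibration_frames must be >= 0")
        for name in ("activation_threshold", "ionic_lock_threshold",
                     "salt_bridge_threshold", "contact_cutoff", "water_cutoff"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.grid_nodes < 2 or self.grid_max <= self.grid_min:
            raise ConfigError("invalid FES grid specification")

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def with_overrides(self, **overrides) -> "RunConfig":
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig.from_dict(data)

    def config_hash(self) -> str:
        """Short hash of the scientific configuration, for output audit headers.

        The output directory is excluded: it cannot influence any computed
        number, and identical analyses written to different places must carry
        the same fingerprint.
        """
        data = asdict(self)
        data.pop("outdir")
        payload = json.dumps(data, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
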