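"""Run configuration: serializable settings echoed alongside every run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Settings for a reproducible analysis run.

    Every CLI run echoes its effective configuration (plus seed and
    package version) into the output directory so the run can be
    repeated bit-identically for the deterministic stages.
    """

    # baseline-median extraction
    baseline_fraction: float = 0.15
    baseline_min_points: int = 8
    # synthetic melts
    sim_dH: float = -70.0
    sim_dS: float = -0.21186
    sim_noise_sd: float = 0.0
    sim_n_concentrations: int = 12
    sim_ct_min: float = 2e-6
    sim_ct_max: float = 2e-4
    seed: int = 0
    # statistical layer
    dg_exclusions: list[str] = field(default_factory=lambda: ["1a", "1b", "8a", "8b"])
    tm_exclusions: list[str] = field(default_factory=lambda: ["1a", "1b", "8a", "8b", "15"])
    grid_a_min: float = 0.5
    grid_a_max: float = 0.8
    grid_b_min: float = -0.3
    grid_b_max: float = 0.5
    grid_step: float = 5e-4
    # table comparisons
    round_decimals: int = 1

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
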