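"""Run configuration shared by the CLI subcommands."""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .exceptions import ValidationError


@dataclass
class RunConfig:
    """Defaults for temperature, seeding, bootstrapping and thresholds.

    The defaults mirror the recommended standard protocol: 300 K, 1000
    bootstrap iterations, 0.5 kcal/mol standard-error threshold, zero
    distance threshold and the 1000 kcal/mol extreme-work cutoff.
    """

    temperature: float = 300.0
    seed: int = 2024
    n_boot: int = 1000
    se_threshold: float = 0.5
    distance_threshold: float = 0.0
    extreme_cutoff: float = 1000.0
    escalation_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if self.n_boot < 100:
            raise ValidationError("n_boot must be >= 100")
        if self.extreme_cutoff <= 0:
            raise ValidationError("extreme_cutoff must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "temperature": self.temperature,
            "seed": self.seed,
            "n_boot": self.n_boot,
            "se_threshold": self.se_threshold,
            "distance_threshold": self.distance_threshold,
            "extreme_cutoff": self.extreme_cutoff,
        }
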