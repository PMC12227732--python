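"""Run configuration: every threshold and seed in one validated object."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Consolidated thresholds for an end-to-end run.

    Defaults are the documented cut-offs: species clustering at 95% ANI /
    85% AF, breadth filter at 0.75, minimum contig length 1000 bp, strain
    identity at popANI >= 99.999% with a 75% comparable-fraction rule
    (waived in decontamination mode), variant calling at min_cov 1.
    """

    seed: int = 0
    ani_min: float = 95.0
    af_min: float = 85.0
    breadth_min: float = 0.75
    min_length: int = 1000
    popani_min: float = 99.999
    min_fraction: float = 0.75
    min_cov: int = 1
    mode: str = "strain"  # strain | species
    scope: str = "own_study"  # own_study | external
    linkage: str = "complete"
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    def __post_init__(self) -> None:
        if not 0 < self.ani_min <= 100 or not 0 < self.af_min <= 100:
            raise ValueError("ani_min/af_min must lie in (0, 100]")
        if not 0 <= self.breadth_min <= 1 or not 0 <= self.min_fraction <= 1:
            raise ValueError("breadth_min/min_fraction must lie in [0, 1]")
        if not 0 < self.popani_min <= 100:
            raise ValueError("popani_min must lie in (0, 100]")
        if self.min_length < 1 or self.min_cov < 1:
            raise ValueError("min_length and min_cov must be >= 1")
        if self.mode not in {"strain", "species"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.scope not in {"own_study", "external"}:
            raise ValueError(f"unknown scope {self.scope!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()
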