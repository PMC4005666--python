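"""Shared tolerance and run configuration.

All geometric thresholds used by base-pair detection, helix-segment
assembly and motif scanning live here so that a single config object (or
JSON file) reproduces a run exactly.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PairingConfig:
    """Geometric criteria for Watson-Crick / wobble pair detection.

    Distances in angstrom, angles in degrees.
    """

    c1_c1_min: float = 8.9
    c1_c1_max: float = 11.9
    hbond_min: float = 2.4          # below this a contact is a clash, not a bond
    hbond_max: float = 3.5          # heavy-atom donor-acceptor cutoff
    normal_angle_max: float = 65.0  # max angle between base-plane normals
    min_hbonds: int = 2


@dataclass
class StackingConfig:
    """Criteria for two stacked pairs to form a minimal helix segment."""

    max_pair_separation: float = 5.5  # between pair C1'-midpoints, angstrom
    twist_min: float = 10.0           # inter-pair twist window, degrees
    twist_max: float = 60.0


@dataclass
class SearchConfig:
    """Tolerances for matching a candidate segment pair against a pattern."""

    translation_tol: float = 4.0  # angstrom
    rotation_tol: float = 25.0    # degrees


@dataclass
class RunConfig:
    """Top-level configuration: every subcommand draws from one of these."""

    pairing: PairingConfig = field(default_factory=PairingConfig)
    stacking: StackingConfig = field(default_factory=StackingConfig)
    search: SearchConfig = field(default_factory=SearchConfig)
    energy_unit: str = "kJ/mol"
    seed: int | None = None
    verbosity: int = 1

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        return cls(
            pairing=PairingConfig(**raw.get("pairing", {})),
            stacking=StackingConfig(**raw.get("stacking", {})),
            search=SearchConfig(**raw.get("search", {})),
            energy_unit=raw.get("energy_unit", "kJ/mol"),
            seed=raw.get("seed"),
            verbosity=raw.get("verbosity", 1),
        )


DEFAULT_CONFIG = RunConfig()
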