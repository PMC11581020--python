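"""Run configuration: defaults, YAML loading, CLI overrides."""
from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from .features.contacts import DEFAULT_BOND_EXCLUSION, DEFAULT_OVERLAP_CUTOFF


@dataclass
class RunConfig:
    overlap_cutoff: float = DEFAULT_OVERLAP_CUTOFF  # Å, signed vdW overlap cutoff
    bond_exclusion: int = DEFAULT_BOND_EXCLUSION
    vif_threshold: float = 10.0
    alpha: float = 0.05
    dv: str = "os"  # {"os", "fi"}
    log_dv: bool = False
    radii_path: Optional[str] = None  # YAML override for vdW radii
    ss_energy_cutoff: float = -0.5  # kcal/mol H-bond acceptance threshold
    exit_angle_projected: bool = True
    combined: bool = True
    family: str = "family"
    seed: int = 0
    out_dir: str = "recepstruct_out"
    skip_errors: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.vif_threshold <= 1.0:
            raise ValueError(f"vif_threshold must be > 1, got {self.vif_threshold}")
        if self.dv not in ("os", "fi"):
            raise ValueError(f"dv must be 'os' or 'fi', got {self.dv!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def load(cls, path: Optional[str | Path] = None, **overrides) -> "RunConfig":
        """Build from an optional YAML file; keyword overrides win."""
        values: dict = {}
        if path is not None:
            with open(path) as fh:
                values.update(yaml.safe_load(fh) or {})
        values.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**values)
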