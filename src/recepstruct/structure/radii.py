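"""Van der Waals and covalent radius tables (Å), user-overridable."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

# Viewer-compatible vdW set; overridable via config (key: vdw_radii).
DEFAULT_VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "H": 1.20,
}
DEFAULT_VDW_FALLBACK = 1.70

# Single-bond covalent radii (Cordero 2008), used for bond inference.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31,
    "C": 0.76,
    "N": 0.71,
    "O": 0.66,
    "S": 1.05,
    "P": 1.07,
    "SE": 1.20,
}
COVALENT_FALLBACK = 0.77


@dataclass
class VdwRadiusTable:
    radii: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_VDW_RADII))
    fallback: float = DEFAULT_VDW_FALLBACK

    def __post_init__(self) -> None:
        bad = {el: r for el, r in self.radii.items() if r <= 0}
        if bad or self.fallback <= 0:
            raise ValueError(f"all radii must be > 0 (offending: {bad or self.fallback})")
        self.radii = {el.upper(): r for el, r in self.radii.items()}

    def __getitem__(self, element: str) -> float:
        return self.radii.get(element.upper(), self.fallback)

    @classmethod
    def from_config(cls, path: str | Path) -> "VdwRadiusTable":
        """Load overrides from a YAML file with a top-level ``vdw_radii`` mapping."""
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        radii = dict(DEFAULT_VDW_RADII)
        radii.update({str(k): float(v) for k, v in (cfg.get("vdw_radii") or {}).items()})
        fallback = float(cfg.get("vdw_fallback", DEFAULT_VDW_FALLBACK))
        return cls(radii=radii, fallback=fallback)


def covalent_radius(element: str) -> float:
    return COVALENT_RADII.get(element.upper(), COVALENT_FALLBACK)
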