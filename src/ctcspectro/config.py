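"""Run configuration shared by the command-line workflows."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .characterization import DEFAULT_MOLAR_MASS

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Physical and algorithmic settings for an analysis run.

    ``temperature_k`` feeds the free-energy computation; ``path_cm`` is the
    optical path; ``molar_mass`` converts between ug/mL and mol/L for the
    analyte.  The remaining fields tune band detection, the Tauc linear-
    region scan and Job's-ratio snapping.  ``seed`` drives every stochastic
    generator so a run is reproducible end to end.
    """

    temperature_k: float = 298.0
    path_cm: float = 1.0
    molar_mass: float = DEFAULT_MOLAR_MASS
    prominence_frac: float = 0.05
    tauc_window_min_points: int = 5
    tauc_r2_min: float = 0.99
    job_snap_tolerance: float = 0.1
    min_shift_nm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("temperature_k", "path_cm", "molar_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.tauc_r2_min <= 1:
            raise ValueError("tauc_r2_min must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
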