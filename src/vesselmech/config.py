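"""Run configuration: one YAML document controls geometry, resolution,
materials and pressures for the pipeline and the CLI."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .geometry import DEFAULT_PARAMS
from .materials import PP1_PA, PP2_PA, pressure_levels
from .meshing import DEFAULT_RESOLUTION


@dataclass
class RunConfig:
    """All tunable knobs of a sweep run, with study defaults."""

    geometry: dict = field(default_factory=dict)    # overrides of DEFAULT_PARAMS, mm
    resolution: tuple = DEFAULT_RESOLUTION          # (n_circ, n_axial_per_mm, n_radial)
    case_table: str = "uniform"                     # uniform | regional
    backend: str = "fem"                            # fem | reduced
    integration_scheme: str = "selective_reduced"
    pp1_pa: float = PP1_PA
    pp2_pa: float = PP2_PA
    diastolic_baseline_pa: float = 0.0
    reference_case: int = 1
    seed: int = 0                                   # geometry jitter only
    jitter_mm: float = 0.0

    def pressures(self):
        return list(pressure_levels(self.pp1_pa, self.pp2_pa,
                                    self.diastolic_baseline_pa))

    def to_yaml(self) -> str:
        d = asdict(self)
        d["resolution"] = list(self.resolution)
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(
                f"unknown config keys {sorted(unknown)}; known: {sorted(known)}")
        if "resolution" in data:
            data["resolution"] = tuple(data["resolution"])
        return cls(**data)


def dump_defaults() -> str:
    """YAML document of every resolved default: run settings plus the
    full geometric parameter set in millimetres."""
    cfg = RunConfig()
    doc = {
        "run": yaml.safe_load(cfg.to_yaml()),
        "geometry_defaults_mm": dict(DEFAULT_PARAMS),
    }
    return yaml.safe_dump(doc, sort_keys=False)
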