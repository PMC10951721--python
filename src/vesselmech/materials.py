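"""Material cases and pulse-pressure loading specifications.

Two sweep families over the aortic Young's modulus, both with the
carotid (and other branch) wall fixed at 1.0 MPa and a Poisson ratio of
0.45 (nearly incompressible arterial tissue):

* **uniform** — one modulus for the whole aorta, 0.8 to 1.6 MPa in five
  steps of 0.2 MPa;
* **regional** — separate moduli for ascending aorta, arch and
  descending aorta, five cases from (0.8, 0.9, 1.0) MPa up to
  (1.6, 1.7, 1.8) MPa.  Two of the printed descending-aorta values
  (cases 3 and 4) break monotonicity with respect to the arch; they are
  encoded exactly as printed, not smoothed.

Pulse pressures: PP1 — normal, default 5594 Pa (42 mmHg); PP2 —
elevated, default 7639 Pa (57 mmHg).  The sources for these levels
disagree internally at the ±400 Pa level (5594 vs 5994, 7639 vs 7369);
the defaults here follow the self-consistent mmHg conversions and all
four values are selectable through configuration.

Brachiocephalic and subclavian moduli are not separately tabulated and
default to the carotid value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .geometry import REGION_LABELS

MPA = 1.0e6
PA_PER_MMHG = 133.322

AORTIC_REGIONS = ("ascending_aorta", "aortic_arch", "descending_aorta")
CAROTID_REGIONS = tuple(r for r in REGION_LABELS if "carotid" in r)
BRANCH_REGIONS = tuple(r for r in REGION_LABELS
                       if r not in AORTIC_REGIONS)

#: Uniform-aorta sweep: one aortic modulus per case, MPa.
UNIFORM_AORTA_E_MPA = (0.8, 1.0, 1.2, 1.4, 1.6)

#: Regional sweep: (ascending, arch, descending) moduli per case, MPa.
REGIONAL_AORTA_E_MPA = (
    (0.8, 0.9, 1.0),
    (1.0, 1.1, 1.2),
    (1.2, 1.3, 1.2),
    (1.4, 1.5, 1.4),
    (1.6, 1.7, 1.8),
)

CAROTID_E_MPA = 1.0
POISSON_RATIO = 0.45

PP1_PA = 5594.0
PP2_PA = 7639.0


@dataclass(frozen=True)
class MaterialCase:
    """Per-region Young's modulus (Pa) and Poisson ratio for one case."""

    case_id: int
    E_by_region: dict[str, float]
    poisson_ratio: float = POISSON_RATIO

    def __post_init__(self) -> None:
        if not (0.0 < self.poisson_ratio < 0.5):
            raise ValueError(
                f"poisson_ratio must lie in (0, 0.5), got {self.poisson_ratio}")
        for region, E in self.E_by_region.items():
            if E <= 0:
                raise ValueError(f"Young's modulus for {region!r} must be > 0")

    def modulus(self, region: str) -> float:
        try:
            return self.E_by_region[region]
        except KeyError:
            raise KeyError(
                f"material case {self.case_id} has no Young's modulus for "
                f"region {region!r}") from None

    def scaled(self, factor: float) -> "MaterialCase":
        """Every modulus multiplied by ``factor`` (linearity checks)."""
        return MaterialCase(self.case_id,
                            {r: E * factor for r, E in self.E_by_region.items()},
                            self.poisson_ratio)


def _with_branches(aortic: dict[str, float],
                   branch_E: float = CAROTID_E_MPA * MPA) -> dict[str, float]:
    E = {r: branch_E for r in BRANCH_REGIONS}
    E.update(aortic)
    return E


def uniform_aorta_cases(branch_modulus_pa: float = CAROTID_E_MPA * MPA
                        ) -> list[MaterialCase]:
    """The five uniform-aorta stiffness cases (carotids held at 1.0 MPa)."""
    cases = []
    for i, e in enumerate(UNIFORM_AORTA_E_MPA, start=1):
        aortic = {r: e * MPA for r in AORTIC_REGIONS}
        cases.append(MaterialCase(i, _with_branches(aortic, branch_modulus_pa)))
    return cases


def regional_aorta_cases(branch_modulus_pa: float = CAROTID_E_MPA * MPA
                         ) -> list[MaterialCase]:
    """The five regional stiffness cases (ascending/arch/descending moduli)."""
    cases = []
    for i, (e_asc, e_arch, e_desc) in enumerate(REGIONAL_AORTA_E_MPA, start=1):
        aortic = {"ascending_aorta": e_asc * MPA,
                  "aortic_arch": e_arch * MPA,
                  "descending_aorta": e_desc * MPA}
        cases.append(MaterialCase(i, _with_branches(aortic, branch_modulus_pa)))
    return cases


def case_table(name: str) -> list[MaterialCase]:
    if name == "uniform":
        return uniform_aorta_cases()
    if name == "regional":
        return regional_aorta_cases()
    raise ValueError(f"unknown case table {name!r}; expected 'uniform' or 'regional'")


def _raised_cosine(t: np.ndarray | float) -> np.ndarray | float:
    """Normalized pulse waveform on one cycle: 0 at t=0, 1 at t=0.5, 0 at t=1."""
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.asarray(t)))


@dataclass(frozen=True)
class PressureSpec:
    """A pulse-pressure load level.

    ``pulse_pressure`` is the systolic-diastolic amplitude ΔP in Pa;
    ``diastolic_baseline`` an optional pre-load (in a linear model it
    cancels out of every ΔV and compliance, which the tests verify).
    ``waveform`` maps normalized cycle time t ∈ [0, 1] to [0, 1].
    """

    label: str
    pulse_pressure: float
    diastolic_baseline: float = 0.0
    waveform: Callable[[np.ndarray], np.ndarray] = field(
        default=_raised_cosine, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.pulse_pressure <= 0:
            raise ValueError("pulse_pressure must be > 0")
        if self.diastolic_baseline < 0:
            raise ValueError("diastolic_baseline must be >= 0")
        w = np.asarray(self.waveform(np.linspace(0, 1, 513)))
        if not (np.isclose(w.min(), 0.0, atol=1e-9)
                and np.isclose(w.max(), 1.0, atol=1e-9)):
            raise ValueError("waveform must attain 0 and 1 on [0, 1]")

    def pressure_at(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.diastolic_baseline + self.pulse_pressure * self.waveform(t)

    @property
    def systolic(self) -> float:
        return self.diastolic_baseline + self.pulse_pressure

    @property
    def diastolic(self) -> float:
        return self.diastolic_baseline


def pressure_levels(pp1_pa: float = PP1_PA, pp2_pa: float = PP2_PA,
                    diastolic_baseline_pa: float = 0.0
                    ) -> tuple[PressureSpec, PressureSpec]:
    """The two study pulse-pressure levels (PP1 normal, PP2 elevated)."""
    return (PressureSpec("PP1", pp1_pa, diastolic_baseline_pa),
            PressureSpec("PP2", pp2_pa, diastolic_baseline_pa))
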